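"""Synthetic data generation, the pseudo-count baseline, and evaluation.

The generator draws data from the linear-model hierarchy itself (truth
included), so simulation studies measure pure inferential error: sample
Σ_true ~ IW(I, D+10), Λ_true ~ N(0, Σ_true, I), standard-normal covariates,
η ~ N(Λ_true X, Σ_true, I) and multinomial counts with fixed per-sample
totals (default 5000; log-normal totals available).  The pseudo-count
linear model (PCLM) baseline fixes η at a pseudo-count log-ratio transform
and ignores multinomial count variation entirely — the standard shortcut
this package's full treatment is measured against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .collapse import GMCLPrior, collapse_gmcl
from .collapsed_inference import (
    laplace_error_bound,
    mh_oracle_sampler,
    sparsity,
)
from .link import CountMatrix, alr, alr_inverse
from .models import PosteriorDraws, default_gmcl_prior, fit_pibble
from .uncollapse import uncollapse_gmcl

__all__ = [
    "SimScenario",
    "simulate_pibble_data",
    "pclm_baseline",
    "rmse_lambda",
    "rmse_sd",
    "posterior_sd",
    "run_grid",
]

DEFAULT_TOTAL = 5000


@dataclass(frozen=True)
class SimScenario:
    """One simulated dataset with its generating truth."""

    N: int
    D: int
    Q: int
    seed: int
    Lambda_true: np.ndarray   # (D-1) x Q
    Sigma_true: np.ndarray    # (D-1) x (D-1)
    eta_true: np.ndarray      # (D-1) x N
    Y: CountMatrix
    X: np.ndarray             # Q x N


def simulate_pibble_data(
    N: int,
    D: int,
    Q: int,
    seed: int = 0,
    n_total: int | str = DEFAULT_TOTAL,
    intercept: bool = False,
    prior: Optional[GMCLPrior] = None,
) -> SimScenario:
    """Draw one dataset from the multinomial logistic-normal linear model.

    ``n_total`` is either a fixed per-sample total or ``"lognormal"`` for
    totals exp(N(log 5000, 0.5²)); ``intercept`` pins the first covariate
    row at 1.  Deterministic given ``seed``.
    """
    if N < 1 or D < 2 or Q < 1:
        raise ValueError("need N>=1, D>=2, Q>=1")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    P = D - 1
    if prior is None:
        prior = default_gmcl_prior(D, Q)
    from .distributions import (
        InvWishartParams,
        MatrixNormalParams,
        sample_inv_wishart,
        sample_matrix_normal,
    )

    Sigma = sample_inv_wishart(InvWishartParams(prior.Xi, prior.v), rng)
    Lam = sample_matrix_normal(
        MatrixNormalParams(prior.Theta, Sigma, prior.Gamma), rng
    )
    X = rng.standard_normal((Q, N))
    if intercept:
        X[0, :] = 1.0
    eta = sample_matrix_normal(
        MatrixNormalParams(Lam @ X, Sigma, np.eye(N)), rng
    )
    pi = alr_inverse(eta).pi
    if isinstance(n_total, str):
        if n_total != "lognormal":
            raise ValueError("n_total must be an integer or 'lognormal'")
        totals = np.maximum(
            1, rng.lognormal(np.log(DEFAULT_TOTAL), 0.5, size=N).astype(int)
        )
    else:
        totals = np.full(N, int(n_total))
    Y = np.column_stack(
        [rng.multinomial(totals[j], pi[:, j]) for j in range(N)]
    )
    return SimScenario(
        N=N, D=D, Q=Q, seed=int(seed),
        Lambda_true=Lam, Sigma_true=Sigma, eta_true=eta,
        Y=CountMatrix(Y=Y), X=X,
    )


def pclm_baseline(
    Y: CountMatrix,
    X: np.ndarray,
    prior: Optional[GMCLPrior] = None,
    pseudo_count: float = 0.5,
    S: int = 2000,
    seed: int = 0,
) -> PosteriorDraws:
    """Pseudo-count linear model: fix eta at alr((Y+c)/colsum) and draw
    (Λ, Σ) from the conjugate conditional, ignoring count variation."""
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if prior is None:
        prior = default_gmcl_prior(Y.D, X.shape[0])
    shifted = Y.Y + pseudo_count
    eta_fixed = alr(shifted / shifted.sum(axis=0, keepdims=True))
    seqs = np.random.SeedSequence(int(seed)).spawn(S)
    P, Q = prior.P, prior.Q
    Lam = np.empty((S, P, Q))
    Sig = np.empty((S, P, P))
    for s, sq in enumerate(seqs):
        d = uncollapse_gmcl(eta_fixed, X, prior, np.random.default_rng(sq))
        Lam[s], Sig[s] = d.Lambda, d.Sigma
    eta = np.broadcast_to(eta_fixed, (S, *eta_fixed.shape)).copy()
    return PosteriorDraws(
        eta=eta, Sigma=Sig, Lambda=Lam,
        coord_system="alr", alr_ref_index=P,
        meta={"model": "pclm", "pseudo_count": pseudo_count, "seed": int(seed)},
    )


def rmse_lambda(est: np.ndarray, truth: np.ndarray) -> float:
    """Elementwise root-mean-squared error of a point estimate."""
    est, truth = np.asarray(est, float), np.asarray(truth, float)
    if est.shape != truth.shape:
        raise ValueError(f"shape mismatch {est.shape} vs {truth.shape}")
    return float(np.sqrt(np.mean((est - truth) ** 2)))


def posterior_sd(draws: np.ndarray) -> np.ndarray:
    """Per-entry posterior standard deviation over the draw axis."""
    return np.asarray(draws, float).std(axis=0, ddof=1)


def rmse_sd(draws_a: np.ndarray, draws_b: np.ndarray) -> float:
    """RMSE between the per-entry posterior sds of two draw sets."""
    sa, sb = posterior_sd(draws_a), posterior_sd(draws_b)
    if sa.shape != sb.shape:
        raise ValueError(f"shape mismatch {sa.shape} vs {sb.shape}")
    return float(np.sqrt(np.mean((sa - sb) ** 2)))


def _oracle_lambda_draws(
    scn: SimScenario, prior: GMCLPrior, n_steps: int, n_keep: int, seed: int
) -> np.ndarray:
    """Collapsed-MH + uncollapse reference Λ draws on a small instance."""
    params = collapse_gmcl(scn.X, prior)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    res = mh_oracle_sampler(scn.Y, params, n_steps=n_steps, rng=rng)
    take = np.linspace(0, res.draws.shape[0] - 1, n_keep).astype(int)
    Lam = np.empty((n_keep, prior.P, prior.Q))
    for i, s in enumerate(take):
        Lam[i] = uncollapse_gmcl(res.draws[s], scn.X, prior, rng).Lambda
    return Lam


def run_grid(
    base: dict,
    vary: Optional[dict] = None,
    replicates: int = 3,
    seed: int = 0,
    S: int = 500,
    n_total: int | str = DEFAULT_TOTAL,
    oracle_steps: int = 40000,
    out_path=None,
) -> pd.DataFrame:
    """Run the simulation-study harness over a scenario grid.

    ``base`` holds {N, D, Q}; ``vary`` maps one or more of those keys to a
    list of values tried one axis at a time (the base value fills the other
    axes).  Each scenario is fit with the Laplace CU sampler and the PCLM
    baseline, plus the collapsed-MH oracle when the problem is small enough
    ((D-1)·N ≤ 60); per-scenario failures are recorded and the grid
    continues.  Returns (and optionally writes) a tidy table with one row
    per scenario × method.
    """
    scenarios = []
    if not vary:
        scenarios = [dict(base)]
    else:
        for axis, values in vary.items():
            for val in values:
                cond = dict(base)
                cond[axis] = val
                scenarios.append(cond)

    root = np.random.SeedSequence(int(seed))
    rows = []
    for cond in scenarios:
        for rep in range(replicates):
            scn_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
            common = {
                "N": cond["N"], "D": cond["D"], "Q": cond["Q"],
                "replicate": rep, "seed": scn_seed,
            }
            try:
                scn = simulate_pibble_data(
                    cond["N"], cond["D"], cond["Q"], seed=scn_seed,
                    n_total=n_total,
                )
                prior = default_gmcl_prior(scn.D, scn.Q)
                common["sparsity"] = sparsity(scn.Y)
                common["error_bound"] = laplace_error_bound(scn.Y)

                oracle_lam = None
                if (scn.D - 1) * scn.N <= 60:
                    oracle_lam = _oracle_lambda_draws(
                        scn, prior, oracle_steps, min(S, 500), scn_seed + 1
                    )

                fits = {
                    "pibble": fit_pibble(scn.Y, scn.X, prior, S=S, seed=scn_seed),
                    "pclm": pclm_baseline(scn.Y, scn.X, prior, S=S, seed=scn_seed),
                }
                for method, dr in fits.items():
                    row = dict(common, method=method)
                    row["rmse_lambda"] = rmse_lambda(
                        dr.Lambda.mean(axis=0), scn.Lambda_true
                    )
                    if oracle_lam is not None:
                        row["rmse_sd_vs_oracle"] = rmse_sd(dr.Lambda, oracle_lam)
                    rows.append(row)
            except Exception as exc:  # keep the grid going
                rows.append(dict(common, method="failed", error=str(exc)))
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df
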