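"""User-facing model fits, posterior summaries and file I/O.

``fit_pibble`` (linear), ``fit_gmdlm`` (dynamic linear) and ``fit_basset``
(Gaussian process) each run the same pipeline: collapse the family to its
matrix-t form, fit the collapsed posterior by MAP + Laplace, draw S
independent eta samples, and uncollapse every draw through the family's
conjugate conditional.  Each (eta, Ψ) pair is one joint posterior sample.

Counts are categories × samples (D×N), covariates Q×N.  Results are
reported in centered log-ratio (CLR) coordinates by default; additive
log-ratio (ALR, last category as reference) is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .collapse import (
    GMCLPrior,
    GMDLMSpec,
    GMGPSpec,
    collapse_gmcl,
    collapse_gmdlm,
    collapse_gmgp,
)
from .collapsed_inference import laplace_fit, sample_collapsed
from .distributions import (
    InvWishartParams,
    MatrixNormalParams,
    sample_inv_wishart,
    sample_matrix_normal,
)
from .link import CountMatrix, alr_inverse, alr_to_clr
from .uncollapse import uncollapse_gmcl, uncollapse_gmdlm, uncollapse_gmgp

__all__ = [
    "PosteriorDraws",
    "default_gmcl_prior",
    "fit_pibble",
    "fit_gmdlm",
    "fit_basset",
    "summarize",
    "read_counts",
    "read_covariates",
    "write_draws",
    "read_draws",
]

DEFAULT_DRAWS = 2000


@dataclass
class PosteriorDraws:
    """Stacked posterior samples with coordinate-system metadata.

    eta: S×P×N latent log-ratio samples; Lambda: S×P×Q regression
    coefficients (S×P×M predicted function values for the GP model;
    absent for the dynamic model, which stores the state path instead);
    Sigma: S×P×P; pi: S×D×N compositions.  ``coord_system`` records the
    coordinates the arrays are expressed in ("alr" with the reference
    index, or "clr" after conversion).
    """

    eta: np.ndarray
    Sigma: np.ndarray
    Lambda: Optional[np.ndarray] = None
    Theta_path: Optional[np.ndarray] = None   # S x (T+1) x Q x P (dynamic)
    pi: Optional[np.ndarray] = None
    coord_system: str = "alr"
    alr_ref_index: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        S = self.eta.shape[0]
        for name in ("Sigma", "Lambda", "Theta_path", "pi"):
            arr = getattr(self, name)
            if arr is not None and arr.shape[0] != S:
                raise ValueError(f"{name} has {arr.shape[0]} draws, eta has {S}")

    @property
    def S(self) -> int:
        return self.eta.shape[0]


def default_gmcl_prior(D: int, Q: int, v: Optional[float] = None) -> GMCLPrior:
    """Default weakly-informative prior: Θ=0, Γ=I, Ξ=I, v=D+10."""
    P = D - 1
    return GMCLPrior(
        Theta=np.zeros((P, Q)),
        Gamma=np.eye(Q),
        Xi=np.eye(P),
        v=float(D + 10 if v is None else v),
    )


def _spawn(seed: int, n: int):
    return np.random.SeedSequence(int(seed)).spawn(n)


def fit_pibble(
    Y: Optional[CountMatrix],
    X: np.ndarray,
    prior: Optional[GMCLPrior] = None,
    S: int = DEFAULT_DRAWS,
    seed: int = 0,
    grad_tol: float = 1e-4,
    max_iter: int = 2000,
) -> PosteriorDraws:
    """Multinomial logistic-normal linear regression via the CU sampler.

    With ``Y=None`` the prior hierarchy is sampled directly (prior-only
    mode).  Draws are deterministic given ``seed``; uncollapsing uses
    per-draw RNG substreams so the result is independent of execution
    order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Q, N = X.shape
    if prior is None:
        if Y is None:
            raise ValueError("prior-only mode requires an explicit prior")
        prior = default_gmcl_prior(Y.D, Q)
    P = prior.P

    if Y is None:
        # prior-only: sample the full hierarchy forward
        seqs = _spawn(seed, S)
        eta = np.empty((S, P, N))
        Lam = np.empty((S, P, prior.Q))
        Sig = np.empty((S, P, P))
        for s, sq in enumerate(seqs):
            rng = np.random.default_rng(sq)
            Sig[s] = sample_inv_wishart(InvWishartParams(prior.Xi, prior.v), rng)
            Lam[s] = sample_matrix_normal(
                MatrixNormalParams(prior.Theta, Sig[s], prior.Gamma), rng
            )
            eta[s] = sample_matrix_normal(
                MatrixNormalParams(Lam[s] @ X, Sig[s], np.eye(N)), rng
            )
        fit_meta = {"mode": "prior"}
    else:
        Y.require_positive_totals()
        if Y.D - 1 != P:
            raise ValueError(f"prior has P={P} but counts imply P={Y.D - 1}")
        params = collapse_gmcl(X, prior)
        fit = laplace_fit(Y, params, grad_tol=grad_tol, max_iter=max_iter)
        seqs = _spawn(seed, S + 1)
        eta = sample_collapsed(fit, S, np.random.default_rng(seqs[0]))
        Lam = np.empty((S, P, prior.Q))
        Sig = np.empty((S, P, P))
        for s in range(S):
            rng = np.random.default_rng(seqs[s + 1])
            d = uncollapse_gmcl(eta[s], X, prior, rng)
            Lam[s], Sig[s] = d.Lambda, d.Sigma
        fit_meta = {
            "mode": "posterior",
            "converged": fit.converged,
            "n_iter": fit.n_iter,
            "final_grad_norm": fit.final_grad_norm,
            "jitter": fit.jitter,
        }

    pi = np.stack([alr_inverse(eta[s]).pi for s in range(S)])
    meta = {
        "model": "pibble",
        "seed": int(seed),
        "S": int(S),
        "grad_tol": grad_tol,
        "prior": {
            "Theta": prior.Theta.tolist(),
            "Gamma": prior.Gamma.tolist(),
            "Xi": prior.Xi.tolist(),
            "v": prior.v,
        },
        **fit_meta,
    }
    return PosteriorDraws(
        eta=eta, Sigma=Sig, Lambda=Lam, pi=pi,
        coord_system="alr", alr_ref_index=P, meta=meta,
    )


def fit_gmdlm(
    Y: CountMatrix,
    spec: GMDLMSpec,
    S: int = DEFAULT_DRAWS,
    seed: int = 0,
    grad_tol: float = 1e-4,
    max_iter: int = 2000,
) -> PosteriorDraws:
    """Multinomial logistic-normal dynamic linear model via the CU sampler."""
    Y.require_positive_totals()
    if Y.D - 1 != spec.P or Y.N != spec.T:
        raise ValueError(
            f"counts {Y.D}x{Y.N} incompatible with spec P={spec.P}, T={spec.T}"
        )
    params = collapse_gmdlm(spec)
    fit = laplace_fit(Y, params, grad_tol=grad_tol, max_iter=max_iter)
    seqs = _spawn(seed, S + 1)
    eta = sample_collapsed(fit, S, np.random.default_rng(seqs[0]))
    P, T, Q = spec.P, spec.T, spec.Q
    Theta = np.empty((S, T + 1, Q, P))
    Sig = np.empty((S, P, P))
    for s in range(S):
        d = uncollapse_gmdlm(eta[s], spec, np.random.default_rng(seqs[s + 1]))
        Theta[s] = np.stack(d.Theta_path)
        Sig[s] = d.Sigma
    pi = np.stack([alr_inverse(eta[s]).pi for s in range(S)])
    meta = {
        "model": "gmdlm", "seed": int(seed), "S": int(S),
        "converged": fit.converged, "final_grad_norm": fit.final_grad_norm,
    }
    return PosteriorDraws(
        eta=eta, Sigma=Sig, Theta_path=Theta, pi=pi,
        coord_system="alr", alr_ref_index=P, meta=meta,
    )


def fit_basset(
    Y: CountMatrix,
    locations: Sequence,
    spec: GMGPSpec,
    new_locations: Optional[Sequence] = None,
    S: int = DEFAULT_DRAWS,
    seed: int = 0,
    grad_tol: float = 1e-4,
    max_iter: int = 2000,
) -> PosteriorDraws:
    """Multinomial logistic-normal Gaussian-process regression via the CU
    sampler; Lambda draws are function values at ``new_locations``
    (defaults to the observed locations)."""
    Y.require_positive_totals()
    locations = list(locations)
    new_locations = locations if new_locations is None else list(new_locations)
    if Y.D - 1 != spec.P or Y.N != len(locations):
        raise ValueError(
            f"counts {Y.D}x{Y.N} incompatible with spec P={spec.P} and "
            f"{len(locations)} locations"
        )
    params = collapse_gmgp(locations, spec)
    fit = laplace_fit(Y, params, grad_tol=grad_tol, max_iter=max_iter)
    seqs = _spawn(seed, S + 1)
    eta = sample_collapsed(fit, S, np.random.default_rng(seqs[0]))
    P, M = spec.P, len(new_locations)
    Lam = np.empty((S, P, M))
    Sig = np.empty((S, P, P))
    for s in range(S):
        rng = np.random.default_rng(seqs[s + 1])
        Lam[s], Sig[s] = uncollapse_gmgp(eta[s], locations, new_locations, spec, rng)
    pi = np.stack([alr_inverse(eta[s]).pi for s in range(S)])
    meta = {
        "model": "basset", "seed": int(seed), "S": int(S),
        "converged": fit.converged, "final_grad_norm": fit.final_grad_norm,
    }
    return PosteriorDraws(
        eta=eta, Sigma=Sig, Lambda=Lam, pi=pi,
        coord_system="alr", alr_ref_index=P, meta=meta,
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def summarize(
    draws: PosteriorDraws,
    levels: Sequence[float] = (0.5, 0.95),
    coord: str = "clr",
    component: str = "Lambda",
) -> pd.DataFrame:
    """Equal-tailed credible intervals per (coordinate, covariate).

    ``coord='clr'`` converts each draw's columns from ALR to CLR before
    summarizing (valid because the map is linear).  ``excludes_zero_<pct>``
    flags coordinates whose interval at that level does not cover zero.
    """
    if draws.S < 2:
        raise ValueError("need at least 2 draws to summarize")
    arr = getattr(draws, component, None)
    if arr is None:
        raise ValueError(f"draws have no component {component!r}")
    if arr.ndim == 4:
        # dynamic-model state path S x (T+1) x Q x P: put the ALR
        # coordinate axis second and flatten (time, state-dim)
        S4, T1, Q4, P4 = arr.shape
        arr = arr.transpose(0, 3, 1, 2).reshape(S4, P4, T1 * Q4)
    if coord == "clr" and draws.coord_system == "alr":
        arr = np.stack([alr_to_clr(a) for a in arr])
    elif coord not in ("clr", "alr"):
        raise ValueError("coord must be 'clr' or 'alr'")

    levels = sorted(levels)
    S, P, Q = arr.shape
    rows = []
    for i in range(P):
        for j in range(Q):
            x = arr[:, i, j]
            row = {"coordinate": i, "covariate": j, "mean": float(x.mean())}
            for lv in levels:
                lo, hi = np.quantile(x, [(1 - lv) / 2, (1 + lv) / 2])
                pct = f"{100 * lv:g}"
                row[f"lower_{pct}"] = float(lo)
                row[f"upper_{pct}"] = float(hi)
                row[f"excludes_zero_{pct}"] = bool(lo > 0 or hi < 0)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    # check header duplicates before pandas mangles them (s1 -> s1.1)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate sample labels {dup}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row labels {dup}")
    if df.isna().any().any():
        bad = int(np.argmax(df.isna().any(axis=1).to_numpy())) + 2
        raise ValueError(f"{path}: missing/ragged values near line {bad}")
    return df


def read_counts(path) -> CountMatrix:
    """Read a D×N tab-delimited count table (row labels in the first
    column, sample labels in the header)."""
    df = _read_table(path)
    vals = df.to_numpy()
    fl = vals.astype(float)
    if np.any(fl != np.round(fl)) or np.any(fl < 0):
        bad = np.argwhere((fl != np.round(fl)) | (fl < 0))[0]
        raise ValueError(
            f"{path}: entry at line {bad[0] + 2}, column {df.columns[bad[1]]!r} "
            "is not a nonnegative integer"
        )
    return CountMatrix(
        Y=fl.astype(np.int64),
        row_labels=tuple(map(str, df.index)),
        col_labels=tuple(map(str, df.columns)),
    )


def read_covariates(path, counts: Optional[CountMatrix] = None) -> pd.DataFrame:
    """Read a Q×N covariate table; when ``counts`` is given, validate and
    align the sample labels against it."""
    df = _read_table(path)
    if counts is not None and counts.col_labels is not None:
        want = list(counts.col_labels)
        missing = sorted(set(want) - set(map(str, df.columns)))
        extra = sorted(set(map(str, df.columns)) - set(want))
        if missing or extra:
            raise ValueError(
                f"sample labels differ between counts and covariates: "
                f"missing from covariates {missing}, unmatched {extra}"
            )
        df = df[want]
    return df


def write_draws(draws: PosteriorDraws, path) -> None:
    """Serialize draws as a long-format TSV plus a JSON metadata sidecar."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    blocks = {}
    for name in ("eta", "Lambda", "Sigma", "pi", "Theta_path"):
        arr = getattr(draws, name)
        if arr is not None:
            blocks[name] = arr
    recs = []
    for name, arr in blocks.items():
        flat = arr.reshape(arr.shape[0], -1)
        S, K = flat.shape
        idx = [np.unravel_index(k, arr.shape[1:]) for k in range(K)]
        for s in range(S):
            for k in range(K):
                recs.append(
                    (s, name, "x".join(map(str, idx[k][:-1])) or "0",
                     str(idx[k][-1]), flat[s, k])
                )
    df = pd.DataFrame(recs, columns=["draw", "block", "row_label", "col_label", "value"])
    df.to_csv(out / "draws.tsv", sep="\t", index=False, float_format="%.17g")
    meta = {
        "version": _version,
        "coord_system": draws.coord_system,
        "alr_ref_index": draws.alr_ref_index,
        "shapes": {k: list(v.shape) for k, v in blocks.items()},
        "meta": draws.meta,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1, default=str))


def read_draws(path) -> PosteriorDraws:
    """Round-trip reader for :func:`write_draws` output; fails loudly when
    the metadata sidecar is missing."""
    out = Path(path)
    meta_path = out / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(
            f"metadata sidecar {meta_path} is missing; draws cannot be "
            "interpreted without it"
        )
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(out / "draws.tsv", sep="\t", float_precision="round_trip")
    arrays = {}
    for name, shape in meta["shapes"].items():
        sub = df[df["block"] == name]
        arr = np.empty(shape)
        flat = arr.reshape(shape[0], -1)
        # rows are written in draw-major, flat-index order
        flat[:, :] = sub["value"].to_numpy().reshape(shape[0], -1)
        arrays[name] = arr
    return PosteriorDraws(
        eta=arrays["eta"],
        Sigma=arrays["Sigma"],
        Lambda=arrays.get("Lambda"),
        Theta_path=arrays.get("Theta_path"),
        pi=arrays.get("pi"),
        coord_system=meta["coord_system"],
        alr_ref_index=meta["alr_ref_index"],
        meta=meta.get("meta", {}),
    )
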