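"""MAP + Laplace inference for the collapsed posterior p(eta | Y).

The collapsed posterior of every model family in this package has the same
form: a multinomial likelihood in ALR coordinates times a matrix-t prior,

    -log p(eta | Y) = -log f(Y | alr^{-1}(eta)) - log T(eta | v, B, K, A) + const.

Because the logit-parameterized multinomial is globally log-concave and the
matrix-t is log-concave around its mode, a Gaussian (Laplace) approximation
centered at the MAP estimate with covariance H^{-1} is accurate whenever
per-sample totals are not tiny; the ``laplace_error_bound`` diagnostic
quantifies when to worry.  An adaptive random-walk Metropolis sampler is
included as a small-instance oracle for validating the approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg as sla
from scipy import optimize

from .distributions import (
    MatrixTParams,
    PositiveDefiniteError,
    log_density_matrix_t,
    matrix_t_grad_neglog,
    matrix_t_hess_neglog,
)
from .link import CountMatrix, multinomial_grad, multinomial_hess, multinomial_loglik, alr

__all__ = [
    "LaplaceFit",
    "MHResult",
    "neg_log_posterior",
    "neg_log_posterior_grad",
    "neg_log_posterior_hess",
    "map_estimate",
    "laplace_fit",
    "sample_collapsed",
    "laplace_error_bound",
    "sparsity",
    "mh_oracle_sampler",
]

JITTER_LADDER = (1e-8, 1e-6, 1e-4)
DEFAULT_GRAD_TOL = 1e-4


@dataclass
class MapResult:
    eta_hat: np.ndarray
    converged: bool
    n_iter: int
    final_grad_norm: float


@dataclass
class LaplaceFit:
    """MAP estimate with a Cholesky factorization of the Hessian at it.

    ``hess_factor`` is the lower-triangular L with L Lᵀ = H(vec eta_hat)
    (plus any recorded jitter); ``logdet`` is log|H|.
    """

    eta_hat: np.ndarray
    hess_factor: np.ndarray
    logdet: float
    converged: bool
    n_iter: int
    final_grad_norm: float
    jitter: float = 0.0
    params: Optional[MatrixTParams] = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.eta_hat.shape


def _combine(Y: Optional[CountMatrix], eta, p: MatrixTParams):
    eta = np.asarray(eta, dtype=float)
    if eta.shape != p.shape:
        raise ValueError(f"eta must be {p.shape}, got {eta.shape}")
    if Y is not None and (Y.D - 1, Y.N) != p.shape:
        raise ValueError(
            f"count matrix {Y.D}x{Y.N} implies eta shape {(Y.D - 1, Y.N)}, "
            f"but matrix-t parameters have shape {p.shape}"
        )
    return eta


def neg_log_posterior(eta, Y: Optional[CountMatrix], p: MatrixTParams) -> float:
    """-log multinomial - log matrix-t (Y=None drops the data term)."""
    eta = _combine(Y, eta, p)
    out = -log_density_matrix_t(eta, p)
    if Y is not None:
        out -= multinomial_loglik(Y, eta)
    return float(out)


def neg_log_posterior_grad(eta, Y: Optional[CountMatrix], p: MatrixTParams) -> np.ndarray:
    eta = _combine(Y, eta, p)
    g = matrix_t_grad_neglog(eta, p)
    if Y is not None:
        g = g - multinomial_grad(Y, eta)
    return g


def neg_log_posterior_hess(eta, Y: Optional[CountMatrix], p: MatrixTParams) -> np.ndarray:
    eta = _combine(Y, eta, p)
    H = matrix_t_hess_neglog(eta, p)
    if Y is not None:
        H = H + multinomial_hess(Y, eta)
    return H


def default_init(Y: CountMatrix, pseudo_count: float = 0.5) -> np.ndarray:
    """Pseudo-count ALR of the counts: a cheap start near the likelihood mode."""
    props = (Y.Y + pseudo_count) / (Y.Y + pseudo_count).sum(axis=0, keepdims=True)
    return alr(props)


def map_estimate(
    Y: Optional[CountMatrix],
    p: MatrixTParams,
    init: Optional[np.ndarray] = None,
    grad_tol: float = DEFAULT_GRAD_TOL,
    max_iter: int = 2000,
) -> MapResult:
    """MAP estimate of the collapsed posterior by L-BFGS + Newton polish.

    Quasi-Newton minimization with the analytic gradient, followed by damped
    Newton steps using the analytic Hessian until the gradient sup-norm
    drops below ``grad_tol``.  Non-convergence warns and flags rather than
    raising; the best iterate found is returned either way.
    """
    P, N = p.shape
    if init is None:
        init = default_init(Y) if Y is not None else np.array(p.B, copy=True)
    x0 = np.asarray(init, dtype=float).reshape(-1, order="F")

    def fun(x):
        e = x.reshape(P, N, order="F")
        return (
            neg_log_posterior(e, Y, p),
            neg_log_posterior_grad(e, Y, p).reshape(-1, order="F"),
        )

    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": min(grad_tol, 1e-6), "ftol": 1e-14},
    )
    x = res.x
    n_iter = int(res.nit)

    # Newton polish to the stated gradient tolerance
    f_cur, g = fun(x)
    for _ in range(50):
        if np.max(np.abs(g)) < grad_tol:
            break
        eta = x.reshape(P, N, order="F")
        H = neg_log_posterior_hess(eta, Y, p)
        L, _ = _chol_with_jitter(H)
        step = sla.cho_solve((L, True), -g)
        t = 1.0
        for _ls in range(30):
            f_new, g_new = fun(x + t * step)
            if f_new <= f_cur + 1e-4 * t * float(g @ step):
                x = x + t * step
                f_cur, g = f_new, g_new
                break
            t *= 0.5
        else:
            break
        n_iter += 1

    gnorm = float(np.max(np.abs(g)))
    converged = gnorm < grad_tol
    if not converged:
        warnings.warn(
            f"MAP estimation did not reach gradient sup-norm {grad_tol:g} "
            f"(final {gnorm:.3g}); returning best iterate",
            RuntimeWarning,
        )
    return MapResult(
        eta_hat=x.reshape(P, N, order="F"),
        converged=converged,
        n_iter=n_iter,
        final_grad_norm=gnorm,
    )


def _chol_with_jitter(H: np.ndarray):
    """Cholesky with an escalating diagonal jitter ladder; returns (L, jitter)."""
    scale = float(np.mean(np.diag(H)))
    for jit in (0.0,) + tuple(j * scale for j in JITTER_LADDER):
        try:
            L = sla.cholesky(H + jit * np.eye(H.shape[0]), lower=True)
            if jit > 0:
                warnings.warn(
                    f"Hessian required jitter {jit:.3g} to factorize",
                    RuntimeWarning,
                )
            return L, jit
        except sla.LinAlgError:
            continue
    raise PositiveDefiniteError(
        "Hessian at the MAP estimate",
        "not positive definite even after maximal jitter; the Laplace "
        "approximation is unreliable here (this typically occurs under "
        "extreme count sparsity)",
    )


def laplace_fit(
    Y: Optional[CountMatrix],
    p: MatrixTParams,
    init: Optional[np.ndarray] = None,
    grad_tol: float = DEFAULT_GRAD_TOL,
    max_iter: int = 2000,
) -> LaplaceFit:
    """MAP estimate plus Hessian factorization: the Laplace approximation
    q(eta|Y) = N(vec eta_hat, H^{-1})."""
    mp = map_estimate(Y, p, init=init, grad_tol=grad_tol, max_iter=max_iter)
    H = neg_log_posterior_hess(mp.eta_hat, Y, p)
    L, jit = _chol_with_jitter(H)
    return LaplaceFit(
        eta_hat=mp.eta_hat,
        hess_factor=L,
        logdet=2.0 * float(np.sum(np.log(np.diag(L)))),
        converged=mp.converged,
        n_iter=mp.n_iter,
        final_grad_norm=mp.final_grad_norm,
        jitter=jit,
        params=p,
    )


def sample_collapsed(
    fit: LaplaceFit, S: int, rng: np.random.Generator
) -> np.ndarray:
    """S independent Gaussian draws of eta from the Laplace approximation.

    eta^(s) = eta_hat + unvec(L^{-T} z),  z ~ N(0, I), so that
    cov(vec eta) = (L L^T)^{-1} = H^{-1}.  Returns S×P×N.
    """
    P, N = fit.shape
    z = rng.standard_normal((P * N, S))
    dev = sla.solve_triangular(fit.hess_factor.T, z, lower=False)
    return fit.eta_hat[None, :, :] + dev.T.reshape(S, N, P).transpose(0, 2, 1)


def laplace_error_bound(Y: CountMatrix) -> float:
    """Diagnostic (D-1)·Σ_j 1/n_j: the Laplace error scale, up to
    proportionality.  Grows with categories and shrinks with counts."""
    Y.require_positive_totals()
    return float((Y.D - 1) * np.sum(1.0 / Y.n))


def sparsity(Y: CountMatrix) -> float:
    """Fraction of zero entries in the count matrix."""
    return Y.sparsity


# ---------------------------------------------------------------------------
# adaptive Metropolis oracle (small instances)
# ---------------------------------------------------------------------------

@dataclass
class MHResult:
    draws: np.ndarray        # S x P x N, post burn-in
    accept_rate: float
    ess: np.ndarray          # per-coordinate effective sample sizes (vec order)

    @property
    def min_ess(self) -> float:
        return float(np.min(self.ess))


def _ess_autocorr(x: np.ndarray) -> float:
    """Initial-positive-sequence ESS estimate for a 1-D chain."""
    n = x.size
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (n * var)
    s = 0.0
    for k in range(1, min(n, 1000)):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def mh_oracle_sampler(
    Y: Optional[CountMatrix],
    p: MatrixTParams,
    n_steps: int,
    rng: np.random.Generator,
    init: Optional[np.ndarray] = None,
    burn_frac: float = 0.33,
    thin: int = 1,
    target_accept: float = 0.234,
) -> MHResult:
    """Adaptive random-walk Metropolis on vec(eta).

    Intended as a brute-force oracle on small instances (PN ≲ 60).  The
    global proposal scale adapts by Robbins-Monro toward ``target_accept``;
    after an initial phase the proposal covariance tracks the empirical
    chain covariance (Haario-style adaptive Metropolis).  Pass ``Y=None``
    to target the matrix-t prior alone.
    """
    P, N = p.shape
    d = P * N
    if init is None:
        init = default_init(Y) if Y is not None else np.array(p.B, copy=True)
    x = np.asarray(init, dtype=float).reshape(-1, order="F")

    def logpost(xv):
        return -neg_log_posterior(xv.reshape(P, N, order="F"), Y, p)

    lp = logpost(x)
    log_s = np.log(2.38 / np.sqrt(d))
    chol_prop = np.eye(d)
    burn = int(burn_frac * n_steps)
    keep = np.empty(((n_steps - burn - 1) // thin + 1, d))
    n_accept = 0
    accept_window = 0
    # running moments for covariance adaptation
    mean_run = x.copy()
    cov_run = np.eye(d)
    cov_count = 1

    k_out = 0
    for step in range(n_steps):
        z = rng.standard_normal(d)
        prop = x + np.exp(log_s) * (chol_prop @ z)
        lp_prop = logpost(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            n_accept += 1
            accept_window += 1

        # running covariance
        cov_count += 1
        delta = x - mean_run
        mean_run += delta / cov_count
        cov_run += (np.outer(delta, x - mean_run) - cov_run) / cov_count

        if step < burn:
            # Robbins-Monro on the log scale
            if (step + 1) % 50 == 0:
                rate = accept_window / 50.0
                log_s += (rate - target_accept) / np.sqrt(1 + step / 50.0)
                accept_window = 0
            if step + 1 == burn // 2 and cov_count > 2 * d:
                try:
                    chol_prop = sla.cholesky(
                        cov_run + 1e-10 * np.eye(d), lower=True
                    )
                    log_s = np.log(2.38 / np.sqrt(d))
                except sla.LinAlgError:
                    pass
        else:
            if (step - burn) % thin == 0:
                keep[k_out] = x
                k_out += 1

    draws = keep[:k_out]
    ess = np.array([_ess_autocorr(draws[:, j]) for j in range(d)])
    return MHResult(
        draws=draws.reshape(-1, N, P).transpose(0, 2, 1),
        accept_rate=n_accept / n_steps,
        ess=ess,
    )
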