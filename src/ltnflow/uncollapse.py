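"""Uncollapse: sample Ψ from p(Ψ | eta) for each collapsed draw.

Given a draw of eta from the collapsed posterior, Ψ is conditionally
independent of the data, so uncollapsing reduces to conjugate Bayesian
Gaussian updates: matrix-normal/inverse-Wishart regression for the linear
and GP families, and forward-filtering backward-sampling for the dynamic
linear family.  Each call consumes its own RNG, so draws can be processed
in any order (or in parallel) with per-draw substreams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .collapse import GMCLPrior, GMDLMSpec, GMGPSpec, gram_matrix, identity_gram
from .distributions import (
    InvWishartParams,
    MatrixNormalParams,
    _cholesky,
    sample_inv_wishart,
    sample_matrix_normal,
)

__all__ = [
    "GMCLConditionalDraw",
    "GMDLMConditionalDraw",
    "uncollapse_gmcl",
    "uncollapse_gmdlm",
    "uncollapse_gmgp",
]


@dataclass(frozen=True)
class GMCLConditionalDraw:
    Lambda: np.ndarray  # P x Q
    Sigma: np.ndarray   # P x P PD


@dataclass(frozen=True)
class GMDLMConditionalDraw:
    Theta_path: list    # T+1 state matrices Q x P (Θ_0 .. Θ_T)
    Sigma: np.ndarray   # P x P PD


def _psd_sqrt(mat: np.ndarray, name: str) -> np.ndarray:
    """Symmetric square root tolerant of PSD (rank-deficient) matrices."""
    m = 0.5 * (mat + mat.T)
    w, V = np.linalg.eigh(m)
    scale = max(float(w.max()), 1e-300)
    if w.min() < -1e-8 * scale:
        warnings.warn(
            f"{name} has negative eigenvalue {w.min():.3g}; clipped to zero",
            RuntimeWarning,
        )
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def uncollapse_gmcl(
    eta_draw: np.ndarray,
    X: np.ndarray,
    prior: GMCLPrior,
    rng: np.random.Generator,
) -> GMCLConditionalDraw:
    """Conjugate matrix-normal/inverse-Wishart regression update.

    Γ_N = (XXᵀ + Γ⁻¹)⁻¹, Λ_N = (ηXᵀ + ΘΓ⁻¹)Γ_N,
    Ξ_N = Ξ + ηηᵀ + ΘΓ⁻¹Θᵀ - Λ_N Γ_N⁻¹ Λ_Nᵀ, v_N = v + N;
    draw Σ ~ IW(Ξ_N, v_N) then Λ | Σ ~ N(Λ_N, Σ, Γ_N).
    """
    eta = np.atleast_2d(np.asarray(eta_draw, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Q, N = X.shape
    if Q != prior.Q or eta.shape != (prior.P, N):
        raise ValueError(
            f"shape mismatch: eta {eta.shape}, X {X.shape}, "
            f"prior P={prior.P} Q={prior.Q}"
        )
    LG = _cholesky(prior.Gamma, "Gamma")
    Gamma_inv = sla.cho_solve((LG, True), np.eye(Q))
    prec_N = X @ X.T + Gamma_inv          # Γ_N^{-1}
    prec_N = 0.5 * (prec_N + prec_N.T)
    Lp = _cholesky(prec_N, "XXᵀ + Γ⁻¹")
    Gamma_N = sla.cho_solve((Lp, True), np.eye(Q))
    Gamma_N = 0.5 * (Gamma_N + Gamma_N.T)
    Lambda_N = (eta @ X.T + prior.Theta @ Gamma_inv) @ Gamma_N
    Xi_N = (
        prior.Xi
        + eta @ eta.T
        + prior.Theta @ Gamma_inv @ prior.Theta.T
        - Lambda_N @ prec_N @ Lambda_N.T
    )
    Xi_N = 0.5 * (Xi_N + Xi_N.T)
    Sigma = sample_inv_wishart(InvWishartParams(Xi=Xi_N, v=prior.v + N), rng)
    Lambda = sample_matrix_normal(
        MatrixNormalParams(M=Lambda_N, U=Sigma, V=Gamma_N), rng
    )
    return GMCLConditionalDraw(Lambda=Lambda, Sigma=Sigma)


def _dlm_forward_filter(eta: np.ndarray, spec: GMDLMSpec):
    """Σ-free Kalman recursions for the matrix DLM.

    Returns filtered means M_t (Q×P), left covariances C_t, the prediction
    errors e_t (columns of eta minus one-step forecasts) and the scalar
    forecast variances q_t.  All covariances here are left factors of a
    ⊗Σ-separable covariance, which is why the gains are Σ-free.
    """
    T, Q, P = spec.T, spec.Q, spec.P
    M = spec.M0.copy()
    C = spec.C0.copy()
    Ms, Cs, Rs, preds = [M], [C], [None], []
    errors, qs = [], []
    for t in range(T):
        G, F, W, g = spec.G[t], spec.F[t], spec.W[t], spec.gamma[t]
        M_pred = G @ M
        R = G @ C @ G.T + W
        R = 0.5 * (R + R.T)
        f = M_pred.T @ F                      # P-vector forecast of eta_t
        q = float(g + F @ R @ F)
        e = eta[:, t] - f
        Again = (R @ F) / q                    # Q-vector
        M = M_pred + np.outer(Again, e)
        C = R - q * np.outer(Again, Again)
        C = 0.5 * (C + C.T)
        Ms.append(M)
        Cs.append(C)
        Rs.append(R)
        preds.append(M_pred)
        errors.append(e)
        qs.append(q)
    return Ms, Cs, Rs, preds, errors, qs


def uncollapse_gmdlm(
    eta_draw: np.ndarray,
    spec: GMDLMSpec,
    rng: np.random.Generator,
) -> GMDLMConditionalDraw:
    """Conjugate conditional for the dynamic linear family.

    Σ | eta ~ IW(Ξ + Σ_t e_t e_tᵀ / q_t, v + T) via the one-step-ahead
    prediction decomposition (the gains are Σ-free under the ⊗Σ-separable
    structure); the state path Θ_0..Θ_T is then drawn by forward filtering
    / backward sampling with the drawn Σ as the shared right covariance.
    """
    eta = np.atleast_2d(np.asarray(eta_draw, dtype=float))
    if eta.shape != (spec.P, spec.T):
        raise ValueError(f"eta must be {spec.P}x{spec.T}, got {eta.shape}")
    Ms, Cs, Rs, preds, errors, qs = _dlm_forward_filter(eta, spec)

    Xi_T = spec.Xi + sum(np.outer(e, e) / q for e, q in zip(errors, qs))
    Xi_T = 0.5 * (Xi_T + Xi_T.T)
    Sigma = sample_inv_wishart(InvWishartParams(Xi=Xi_T, v=spec.v + spec.T), rng)
    L_Sigma = _cholesky(Sigma, "Sigma draw")

    # backward sampling: Θ_T ~ N(M_T, C_T, Σ); then condition on Θ_{t+1}
    T, Q, P = spec.T, spec.Q, spec.P

    def draw_state(mean: np.ndarray, left_cov: np.ndarray) -> np.ndarray:
        LU = _psd_sqrt(left_cov, "filter covariance")
        Z = rng.standard_normal((Q, P))
        return mean + LU @ Z @ L_Sigma.T

    theta = draw_state(Ms[T], Cs[T])
    path = [theta]
    for t in range(T - 1, -1, -1):
        G_next = spec.G[t]          # transition from Θ_t to Θ_{t+1}
        R_next = Rs[t + 1]
        C_t = Cs[t]
        # gain J = C_t G^T R^{-1} with PSD-safe solve
        R_reg = R_next + 1e-12 * np.trace(R_next) / max(Q, 1) * np.eye(Q)
        J = C_t @ G_next.T @ np.linalg.solve(R_reg, np.eye(Q))
        mean = Ms[t] + J @ (path[-1] - G_next @ Ms[t])
        cov = C_t - J @ R_next @ J.T
        path.append(draw_state(mean, cov))
    path.reverse()  # Θ_0 .. Θ_T
    return GMDLMConditionalDraw(Theta_path=path, Sigma=Sigma)


def uncollapse_gmgp(
    eta_draw: np.ndarray,
    locations,
    new_locations,
    spec: GMGPSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """GP conditional: draw Σ, then Λ at ``new_locations`` given eta and Σ.

    Σ | eta ~ IW(Ξ + Δ A⁻¹ Δᵀ, v + N) with A = I + Γ over the observed
    locations and Δ = eta - Θ(locations); Λ_new | eta, Σ is the standard
    GP posterior with row covariance Σ.
    """
    locations = list(locations)
    new_locations = list(new_locations)
    eta = np.atleast_2d(np.asarray(eta_draw, dtype=float))
    N = len(locations)
    if eta.shape != (spec.P, N):
        raise ValueError(f"eta must be {spec.P}x{N}, got {eta.shape}")

    Theta_obs = np.atleast_2d(np.asarray(spec.mean_fn(locations), dtype=float))
    Theta_new = np.atleast_2d(np.asarray(spec.mean_fn(new_locations), dtype=float))
    G_oo = gram_matrix(spec.kernel_fn, locations)
    A = np.eye(N) + G_oo  # per-sample noise: diagonal identity term
    A = 0.5 * (A + A.T)
    if not np.all(np.isfinite(A)):
        raise ValueError("kernel produced non-finite Gram entries")
    G_on = gram_matrix(spec.kernel_fn, locations, new_locations)   # N x M
    G_nn = gram_matrix(spec.kernel_fn, new_locations)

    LA = _cholesky(A, "I + Γ (observed locations)")
    delta = eta - Theta_obs
    Ainv_deltaT = sla.cho_solve((LA, True), delta.T)               # N x P
    Xi_N = spec.Xi + delta @ Ainv_deltaT
    Xi_N = 0.5 * (Xi_N + Xi_N.T)
    Sigma = sample_inv_wishart(InvWishartParams(Xi=Xi_N, v=spec.v + N), rng)
    L_Sigma = _cholesky(Sigma, "Sigma draw")

    Ainv_Gon = sla.cho_solve((LA, True), G_on)                     # N x M
    mean = Theta_new + delta @ Ainv_Gon
    V_cond = G_nn - G_on.T @ Ainv_Gon
    LV = _psd_sqrt(V_cond, "GP conditional covariance")
    Z = rng.standard_normal((spec.P, len(new_locations)))
    Lambda = mean + L_Sigma @ Z @ LV.T
    return Lambda, Sigma
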