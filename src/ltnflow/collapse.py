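"""Collapse model-family hyperparameters to canonical matrix-t parameters.

Three latent-Gaussian families share a matrix-t marginal for eta once the
conjugate layers (regression coefficients / state paths and the covariance
Sigma) are integrated out:

* conjugate linear regression (GMCL):    B = Θ X,  K = Ξ,  A = I_N + XᵀΓX
* dynamic linear / state-space (GMDLM):  B, A from the state recursion
* Gaussian-process regression (GMGP):    B = Θ(x), K = Ξ,  A = I + Γ(x, x')

The collapsed form is what the Laplace machinery in
:mod:`ltnflow.collapsed_inference` operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .distributions import MatrixTParams, _cholesky

__all__ = [
    "GMCLPrior",
    "GMDLMSpec",
    "GMGPSpec",
    "collapse_gmcl",
    "collapse_gmdlm",
    "collapse_gmgp",
    "kernel_se",
    "kernel_block",
    "kernel_product",
    "gram_matrix",
    "identity_gram",
]


@dataclass(frozen=True)
class GMCLPrior:
    """Conjugate linear-model prior: Λ ~ N(Θ, Σ, Γ), Σ ~ IW(Ξ, v)."""

    Theta: np.ndarray  # P x Q prior mean for the coefficients
    Gamma: np.ndarray  # Q x Q covariate-side covariance
    Xi: np.ndarray     # P x P inverse-Wishart scale
    v: float

    def __post_init__(self):
        object.__setattr__(self, "Theta", np.atleast_2d(np.asarray(self.Theta, dtype=float)))
        object.__setattr__(self, "Gamma", np.atleast_2d(np.asarray(self.Gamma, dtype=float)))
        object.__setattr__(self, "Xi", np.atleast_2d(np.asarray(self.Xi, dtype=float)))
        object.__setattr__(self, "v", float(self.v))
        P, Q = self.Theta.shape
        if self.Gamma.shape != (Q, Q):
            raise ValueError(f"Gamma must be {Q}x{Q}, got {self.Gamma.shape}")
        if self.Xi.shape != (P, P):
            raise ValueError(f"Xi must be {P}x{P}, got {self.Xi.shape}")
        _cholesky(self.Gamma, "Gamma")
        _cholesky(self.Xi, "Xi")
        if self.v <= P - 1:
            raise ValueError(f"v={self.v} must exceed P-1={P - 1}")

    @property
    def P(self) -> int:
        return self.Theta.shape[0]

    @property
    def Q(self) -> int:
        return self.Theta.shape[1]


@dataclass(frozen=True)
class GMDLMSpec:
    """Dynamic linear model hyperparameters over a horizon of T steps.

    Observation: η_tᵀ = F_tᵀ Θ_t + ν_tᵀ,  ν_t ~ N(0, γ_t Σ)
    Evolution:   Θ_t = G_t Θ_{t-1} + Ω_t,  Ω_t ~ N(0, W_t, Σ)
    Initial:     Θ_0 ~ N(M0, C0, Σ),       Σ ~ IW(Ξ, v)
    """

    F: Sequence[np.ndarray]     # T vectors of length Q
    G: Sequence[np.ndarray]     # T matrices Q x Q
    W: Sequence[np.ndarray]     # T PSD matrices Q x Q
    gamma: Sequence[float]      # T positive scalars
    M0: np.ndarray              # Q x P
    C0: np.ndarray              # Q x Q PD
    Xi: np.ndarray              # P x P PD
    v: float
    T: int = field(init=False)

    def __post_init__(self):
        F = [np.asarray(f, dtype=float).reshape(-1) for f in self.F]
        T = len(F)
        if T < 1:
            raise ValueError("horizon T must be at least 1")
        M0 = np.atleast_2d(np.asarray(self.M0, dtype=float))
        Q, P = M0.shape
        G = [np.atleast_2d(np.asarray(g, dtype=float)) for g in self.G]
        W = [np.atleast_2d(np.asarray(w, dtype=float)) for w in self.W]
        gamma = [float(g) for g in self.gamma]
        if not (len(G) == len(W) == len(gamma) == T):
            raise ValueError(
                f"F, G, W, gamma must all have length T={T}, got "
                f"{len(F)}, {len(G)}, {len(W)}, {len(gamma)}"
            )
        for t, (f, g, w) in enumerate(zip(F, G, W), start=1):
            if f.shape != (Q,):
                raise ValueError(f"F[{t}] must have length Q={Q}")
            if g.shape != (Q, Q) or w.shape != (Q, Q):
                raise ValueError(f"G[{t}] and W[{t}] must be {Q}x{Q}")
            ew = np.linalg.eigvalsh(0.5 * (w + w.T))
            if ew.min() < -1e-10 * max(1.0, ew.max()):
                raise ValueError(f"W[{t}] is not positive semi-definite")
        if any(g <= 0 for g in gamma):
            raise ValueError("observation weights gamma must be positive")
        C0 = np.atleast_2d(np.asarray(self.C0, dtype=float))
        Xi = np.atleast_2d(np.asarray(self.Xi, dtype=float))
        if C0.shape != (Q, Q):
            raise ValueError(f"C0 must be {Q}x{Q}")
        if Xi.shape != (P, P):
            raise ValueError(f"Xi must be {P}x{P}")
        _cholesky(C0, "C0")
        _cholesky(Xi, "Xi")
        if float(self.v) <= P - 1:
            raise ValueError(f"v={self.v} must exceed P-1={P - 1}")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "M0", M0)
        object.__setattr__(self, "C0", C0)
        object.__setattr__(self, "Xi", Xi)
        object.__setattr__(self, "v", float(self.v))
        object.__setattr__(self, "T", T)

    @property
    def Q(self) -> int:
        return self.M0.shape[0]

    @property
    def P(self) -> int:
        return self.M0.shape[1]


@dataclass(frozen=True)
class GMGPSpec:
    """Gaussian-process family: Λ ~ GP(Θ, Σ, Γ), Σ ~ IW(Ξ, v).

    ``mean_fn(locations)`` returns the P×N prior mean of eta at the given
    locations; ``kernel_fn(x, x')`` is the sample-side kernel Γ.  Ξ is the
    category-side scale evaluated on the P observed categories.
    """

    mean_fn: Callable[[Sequence], np.ndarray]
    kernel_fn: Callable[[object, object], float]
    Xi: np.ndarray
    v: float

    def __post_init__(self):
        Xi = np.atleast_2d(np.asarray(self.Xi, dtype=float))
        _cholesky(Xi, "Xi")
        if float(self.v) <= Xi.shape[0] - 1:
            raise ValueError(f"v={self.v} must exceed P-1={Xi.shape[0] - 1}")
        object.__setattr__(self, "Xi", Xi)
        object.__setattr__(self, "v", float(self.v))

    @property
    def P(self) -> int:
        return self.Xi.shape[0]


# ---------------------------------------------------------------------------
# collapse operations
# ---------------------------------------------------------------------------

def collapse_gmcl(X: np.ndarray, prior: GMCLPrior) -> MatrixTParams:
    """Collapsed matrix-t for the linear family: (v, ΘX, Ξ, I_N + XᵀΓX)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != prior.Q:
        raise ValueError(
            f"design matrix must have Q={prior.Q} rows, got {X.shape[0]}"
        )
    N = X.shape[1]
    A = np.eye(N) + X.T @ prior.Gamma @ X
    A = 0.5 * (A + A.T)
    return MatrixTParams(v=prior.v, B=prior.Theta @ X, K=prior.Xi, A=A)


def collapse_gmdlm(spec: GMDLMSpec) -> MatrixTParams:
    """Collapsed matrix-t for the dynamic linear family.

    Column t of B is M0ᵀ 𝒢_{t:1}ᵀ F_t with 𝒢_{t:1} = G_t ⋯ G_1.  A is built
    by propagating the state prior covariance P_t = G_t P_{t-1} G_tᵀ + W_t
    (P_0 = C0):  A[t,s] = γ_t δ_{ts} + F_tᵀ 𝒢_{t:s+1} P_s F_s  for t ≥ s.
    Cost O(T² Q³), acceptable at desk scale.
    """
    T, Q, P = spec.T, spec.Q, spec.P
    B = np.zeros((P, T))
    Gcum = np.eye(Q)  # 𝒢_{t:1}
    for t in range(T):
        Gcum = spec.G[t] @ Gcum
        B[:, t] = spec.M0.T @ Gcum.T @ spec.F[t]

    # state prior covariances P_t (left factor of cov(Θ_t) given Σ)
    Pcov = [spec.C0]
    for t in range(T):
        Pcov.append(spec.G[t] @ Pcov[-1] @ spec.G[t].T + spec.W[t])

    A = np.zeros((T, T))
    for s in range(1, T + 1):
        M = Pcov[s]
        A[s - 1, s - 1] = spec.gamma[s - 1] + spec.F[s - 1] @ M @ spec.F[s - 1]
        for t in range(s + 1, T + 1):
            M = spec.G[t - 1] @ M
            A[t - 1, s - 1] = spec.F[t - 1] @ M @ spec.F[s - 1]
            A[s - 1, t - 1] = A[t - 1, s - 1]
    A = 0.5 * (A + A.T)
    return MatrixTParams(v=spec.v, B=B, K=spec.Xi, A=A)


def collapse_gmgp(locations: Sequence, spec: GMGPSpec) -> MatrixTParams:
    """Collapsed matrix-t for the GP family: B = Θ(x), K = Ξ, A = I + Γ."""
    locations = list(locations)
    if len(locations) < 1:
        raise ValueError("at least one location is required")
    B = np.atleast_2d(np.asarray(spec.mean_fn(locations), dtype=float))
    if B.shape != (spec.P, len(locations)):
        raise ValueError(
            f"mean_fn must return a {spec.P}x{len(locations)} matrix, "
            f"got {B.shape}"
        )
    # each observed sample carries its own independent noise, so the
    # identity term is diagonal even at duplicated locations
    A = np.eye(len(locations)) + gram_matrix(spec.kernel_fn, locations)
    if not np.all(np.isfinite(A)):
        raise ValueError("kernel produced non-finite Gram entries")
    A = 0.5 * (A + A.T)
    return MatrixTParams(v=spec.v, B=B, K=spec.Xi, A=A)


# ---------------------------------------------------------------------------
# kernel library
# ---------------------------------------------------------------------------

def kernel_se(x, xp, lengthscale: float = 1.0, scale: float = 1.0) -> float:
    """Squared-exponential kernel scale·exp(-(x-x')²/(2·lengthscale²)).

    ``x`` may be a scalar coordinate or a vector; the squared Euclidean
    distance is used.
    """
    if lengthscale <= 0 or scale <= 0:
        raise ValueError("lengthscale and scale must be positive")
    d2 = float(np.sum((np.asarray(x, dtype=float) - np.asarray(xp, dtype=float)) ** 2))
    return scale * float(np.exp(-d2 / (2.0 * lengthscale**2)))


def kernel_block(group: Callable[[object], object] = lambda x: x):
    """Block-identity kernel: 1 when two locations share a group, else 0.

    ``group`` extracts the (exactly compared, hashable) group key from a
    location; e.g. ``lambda loc: loc[0]`` for (vessel, time) pairs.
    """

    def k(x, xp) -> float:
        return 1.0 if group(x) == group(xp) else 0.0

    return k


def kernel_product(k1, k2):
    """Element-wise (Hadamard) product of two kernels."""

    def k(x, xp) -> float:
        return k1(x, xp) * k2(x, xp)

    return k


def gram_matrix(kernel_fn, locs, locs2=None) -> np.ndarray:
    """Dense Gram matrix of ``kernel_fn`` over locations."""
    locs = list(locs)
    locs2 = locs if locs2 is None else list(locs2)
    out = np.empty((len(locs), len(locs2)))
    for i, x in enumerate(locs):
        for j, xp in enumerate(locs2):
            out[i, j] = kernel_fn(x, xp)
    return out


def identity_gram(locs) -> np.ndarray:
    """Gram of the identity kernel: 1 exactly when locations compare equal.

    Equality is exact (on user-supplied hashable keys / coordinates), not a
    floating-point tolerance.
    """
    locs = list(locs)
    n = len(locs)
    out = np.zeros((n, n))
    for i, x in enumerate(locs):
        for j in range(i, n):
            if _loc_equal(x, locs[j]):
                out[i, j] = out[j, i] = 1.0
    return out


def _loc_equal(a, b) -> bool:
    ar, br = np.asarray(a), np.asarray(b)
    if ar.shape != br.shape:
        return a == b
    return bool(np.all(ar == br))
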