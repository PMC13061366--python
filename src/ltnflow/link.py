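"""Log-ratio transforms and the logit-parameterized multinomial likelihood.

Counts are held categories-by-samples (D×N).  The additive log-ratio (ALR)
transform uses the LAST category as the reference, mapping the interior of
the D-simplex to R^{D-1}; its inverse is a softmax with the reference
coordinate pinned at 0.  All log-likelihoods omit the multinomial
coefficient, which is constant in eta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "CountMatrix",
    "Composition",
    "alr",
    "alr_inverse",
    "alr_to_clr",
    "multinomial_loglik",
    "multinomial_grad",
    "multinomial_hess",
]


@dataclass(frozen=True)
class CountMatrix:
    """D×N matrix of nonnegative integer counts; column j totals n[j].

    ``row_labels``/``col_labels`` are optional category and sample names
    carried along by the file readers.
    """

    Y: np.ndarray
    row_labels: tuple | None = None
    col_labels: tuple | None = None
    n: np.ndarray = field(init=False)

    def __post_init__(self):
        Y = np.asarray(self.Y)
        if Y.ndim != 2:
            raise ValueError(f"counts must be 2-D, got ndim={Y.ndim}")
        if not np.issubdtype(Y.dtype, np.integer):
            Yf = np.asarray(Y, dtype=float)
            if not np.all(np.isfinite(Yf)) or np.any(Yf != np.round(Yf)):
                raise ValueError("counts must be integers")
            Y = Yf.astype(np.int64)
        if np.any(Y < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "Y", Y.astype(np.int64))
        object.__setattr__(self, "n", Y.sum(axis=0))
        for attr, size in (("row_labels", Y.shape[0]), ("col_labels", Y.shape[1])):
            lab = getattr(self, attr)
            if lab is not None:
                lab = tuple(str(x) for x in lab)
                if len(lab) != size:
                    raise ValueError(f"{attr} must have length {size}")
                if len(set(lab)) != len(lab):
                    raise ValueError(f"{attr} contains duplicates")
                object.__setattr__(self, attr, lab)

    @property
    def D(self) -> int:
        return self.Y.shape[0]

    @property
    def N(self) -> int:
        return self.Y.shape[1]

    @property
    def sparsity(self) -> float:
        """Fraction of zero entries."""
        return float(np.mean(self.Y == 0))

    def require_positive_totals(self):
        empty = np.flatnonzero(self.n == 0)
        if empty.size:
            raise ValueError(
                f"columns {empty.tolist()} have zero total counts; they carry "
                "no likelihood information and are rejected at fit time"
            )


@dataclass(frozen=True)
class Composition:
    """D×N matrix with strictly positive columns on the simplex."""

    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 2:
            raise ValueError("composition must be 2-D")
        if np.any(pi <= 0):
            raise ValueError("composition entries must be strictly positive")
        colsums = pi.sum(axis=0)
        if np.max(np.abs(colsums - 1.0)) > 1e-12:
            raise ValueError("composition columns must sum to 1 within 1e-12")
        object.__setattr__(self, "pi", pi)


def _log_pi_from_eta(eta: np.ndarray) -> np.ndarray:
    """log of the inverse-ALR composition, D×N, via a log-sum-exp guard."""
    eta = np.asarray(eta, dtype=float)
    if eta.ndim != 2:
        raise ValueError("eta must be 2-D")
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta contains non-finite entries")
    full = np.vstack([eta, np.zeros((1, eta.shape[1]))])
    return full - logsumexp(full, axis=0, keepdims=True)


def alr_inverse(eta: np.ndarray) -> Composition:
    """Inverse additive log-ratio: column j maps to
    (e^{η_1j}, ..., e^{η_{D-1,j}}, 1) / (1 + Σ_i e^{η_ij})."""
    pi = np.exp(_log_pi_from_eta(eta))
    # guard against underflow to exact zero at extreme eta; the floor is
    # far below any count-data resolution
    pi = np.clip(pi, np.finfo(float).tiny, None)
    pi /= pi.sum(axis=0, keepdims=True)  # renormalize away rounding
    return Composition(pi=pi)


def alr(pi: Composition | np.ndarray) -> np.ndarray:
    """ALR transform with the last row as reference: log(π_i/π_D)."""
    arr = pi.pi if isinstance(pi, Composition) else np.asarray(pi, dtype=float)
    if np.any(arr <= 0):
        raise ValueError(
            "composition has zero entries; the ALR transform requires "
            "strictly positive proportions (a pseudo-count is appropriate "
            "only for the pseudo-count baseline model)"
        )
    return np.log(arr[:-1, :]) - np.log(arr[-1:, :])


def alr_to_clr(coords: np.ndarray) -> np.ndarray:
    """Map (D-1)×M ALR coordinates to D×M CLR coordinates.

    Appends a zero reference row then centers each column.  Being linear,
    this applies identically to eta columns and to rows of regression
    coefficients expressed per covariate.
    """
    coords = np.asarray(coords, dtype=float)
    full = np.vstack([coords, np.zeros((1, coords.shape[1]))])
    return full - full.mean(axis=0, keepdims=True)


def _check_shapes(Y: CountMatrix, eta: np.ndarray) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (Y.D - 1, Y.N):
        raise ValueError(
            f"eta must be {(Y.D - 1, Y.N)} for a {Y.D}x{Y.N} count matrix, "
            f"got {eta.shape}"
        )
    return eta


def multinomial_loglik(Y: CountMatrix, eta: np.ndarray) -> float:
    """Σ_j Σ_i Y_ij log π_ij with π = alr_inverse(eta); no multinomial
    coefficient (constant in eta)."""
    eta = _check_shapes(Y, eta)
    return float(np.sum(Y.Y * _log_pi_from_eta(eta)))


def multinomial_grad(Y: CountMatrix, eta: np.ndarray) -> np.ndarray:
    """Gradient of the log-likelihood w.r.t. eta: Y_{1:D-1} - n_j π̃_j."""
    eta = _check_shapes(Y, eta)
    pi = np.exp(_log_pi_from_eta(eta))[:-1, :]
    return Y.Y[:-1, :].astype(float) - Y.n[None, :] * pi


def multinomial_hess(Y: CountMatrix, eta: np.ndarray) -> np.ndarray:
    """Hessian of the NEGATIVE log-likelihood w.r.t. vec(eta), PN×PN.

    Block-diagonal (column-major vec): block j is
    n_j (diag(π̃_j) - π̃_j π̃_j^T) with π̃ the first D-1 proportions.
    """
    eta = _check_shapes(Y, eta)
    P, N = eta.shape
    pi = np.exp(_log_pi_from_eta(eta))[:-1, :]
    H = np.zeros((P * N, P * N))
    for j in range(N):
        pj = pi[:, j]
        block = Y.n[j] * (np.diag(pj) - np.outer(pj, pj))
        H[j * P : (j + 1) * P, j * P : (j + 1) * P] = block
    return H
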