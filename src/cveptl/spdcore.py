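"""Symmetric positive-definite (SPD) matrix algebra.

Covariance matrices of EEG trials live on the SPD manifold; classifying them
there requires a Riemannian metric, a mean, and a well-conditioned covariance
estimator.  This module provides:

* the sample covariance matrix (SCM) of a trial,
* shrinkage estimation ``P_sh = λΓ + (1−λ)P`` with the scaled-identity
  targets (two conventions for the scale v) and the Schäfer–Strimmer
  diagonal target with its analytic shrinkage intensity,
* the affine-invariant and log-Euclidean distances,
* the log-Euclidean mean (closed form) and the affine-invariant
  (Karcher) mean via fixed-point iteration,
* the inverse matrix square root used to build alignment references.

All matrix functions go through the symmetric eigendecomposition; inputs
whose smallest eigenvalue falls below ``EIGEN_FLOOR_REL`` times the largest
are floored there before a log or inverse square root, and every flooring
event is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "ShrinkageConfig",
    "scm",
    "shrink",
    "dist_ai",
    "dist_le",
    "mean_le",
    "mean_ai",
    "invsqrt",
    "logm_spd",
    "expm_sym",
    "is_spd",
]

logger = logging.getLogger(__name__)

#: Relative eigenvalue floor applied before matrix logs / inverse roots.
EIGEN_FLOOR_REL = 1e-12

_SYM_TOL = 1e-10


def _check_symmetric(P: np.ndarray, name: str = "matrix") -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"{name} must be square, got shape {P.shape}")
    scale = max(np.abs(P).max(), 1.0)
    if np.abs(P - P.T).max() > _SYM_TOL * scale:
        raise ValueError(f"{name} is not symmetric to tolerance {_SYM_TOL}")
    return 0.5 * (P + P.T)


def is_spd(P: np.ndarray, tol: float = 0.0) -> bool:
    """True when ``P`` is symmetric with all eigenvalues > ``tol``."""
    try:
        P = _check_symmetric(P)
    except ValueError:
        return False
    return bool(scipy.linalg.eigvalsh(P).min() > tol)


def _eigh_floored(P: np.ndarray, name: str = "matrix") -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with the relative eigenvalue floor applied."""
    w, V = scipy.linalg.eigh(P)
    floor = EIGEN_FLOOR_REL * max(w[-1], 0.0)
    if w[0] <= floor:
        if floor <= 0.0:
            raise ValueError(f"{name} has no positive eigenvalues (max {w[-1]:.3e})")
        logger.warning(
            "%s regularized: smallest eigenvalue %.3e floored to %.3e",
            name,
            w[0],
            floor,
        )
        w = np.maximum(w, floor)
    return w, V


def logm_spd(P: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (symmetric result)."""
    P = _check_symmetric(P)
    w, V = _eigh_floored(P, "logm input")
    return (V * np.log(w)) @ V.T


def expm_sym(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (SPD result)."""
    S = _check_symmetric(S)
    w, V = scipy.linalg.eigh(S)
    return (V * np.exp(w)) @ V.T


def invsqrt(P: np.ndarray) -> np.ndarray:
    """Inverse symmetric square root: returns M with ``M P M = I``."""
    P = _check_symmetric(P)
    w, V = _eigh_floored(P, "invsqrt input")
    return (V * (1.0 / np.sqrt(w))) @ V.T


def sqrtm_spd(P: np.ndarray) -> np.ndarray:
    """Symmetric square root of an SPD matrix."""
    P = _check_symmetric(P)
    w, V = _eigh_floored(P, "sqrtm input")
    return (V * np.sqrt(w)) @ V.T


def scm(trial: np.ndarray) -> np.ndarray:
    """Sample covariance matrix of a single trial.

    ``trial`` is channels × samples.  Rows are mean-centered (band-passed
    EEG is near zero-mean already; centering makes the estimator exact) and
    the unbiased normalization ``1/(Nt − 1)`` is used:

        P = X X^T / (Nt − 1).

    The result is symmetric PSD; it is rank-deficient whenever the number of
    rows exceeds ``Nt − 1``.
    """
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"trial must be 2-D (channels x samples), got {X.shape}")
    n, nt = X.shape
    if nt < 2:
        raise ValueError(f"need at least 2 samples, got {nt}")
    Xc = X - X.mean(axis=1, keepdims=True)
    P = (Xc @ Xc.T) / (nt - 1)
    return 0.5 * (P + P.T)


@dataclass(frozen=True)
class ShrinkageConfig:
    """How to regularize a sample covariance matrix.

    method
        ``none``            — return the SCM unchanged.
        ``ledoit_wolf``     — Γ = v·I with v = tr(P)  (sum of variances).
        ``blankertz``       — Γ = v·I with v = tr(P)/n (average variance).
        ``schafer_strimmer``— Γ = diag(P): off-diagonals shrink toward zero,
                              variances are kept.  The study default.
    lam
        Fixed shrinkage weight in [0, 1].  When ``None`` the analytic
        optimal intensity is estimated from the data (which must then be
        supplied to :func:`shrink`).
    """

    method: str = "schafer_strimmer"
    lam: float | None = None

    _METHODS = ("none", "ledoit_wolf", "blankertz", "schafer_strimmer")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(f"unknown shrinkage method {self.method!r}")
        if self.lam is not None and not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")


def _shrinkage_target(P: np.ndarray, method: str) -> np.ndarray:
    n = P.shape[0]
    if method == "ledoit_wolf":
        return np.trace(P) * np.eye(n)
    if method == "blankertz":
        return (np.trace(P) / n) * np.eye(n)
    if method == "schafer_strimmer":
        return np.diag(np.diag(P))
    raise ValueError(method)


def _analytic_lambda(P: np.ndarray, target: np.ndarray, data: np.ndarray) -> float:
    """Plug-in optimal shrinkage intensity (Schäfer–Strimmer style).

    λ* = Σ_ij Var(s_ij) / Σ_ij (s_ij − t_ij)², estimated from the centered
    samples and clipped to [0, 1].  Entries where the target equals the SCM
    (the diagonal, for the diagonal target) contribute nothing to the
    denominator, recovering the canonical correlation-shrinkage formula.
    """
    X = np.asarray(data, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    nt = Xc.shape[1]
    if nt < 3:
        return 0.0
    W_bar = (Xc @ Xc.T) / nt  # mean of w_k = x_k x_k^T over samples
    sq = Xc**2
    sum_w2 = sq @ sq.T  # Σ_k w_k ∘ w_k
    var_s = nt / (nt - 1) ** 3 * (sum_w2 - nt * W_bar**2)
    diff = P - target
    denom = float((diff**2).sum())
    # Var estimates only matter where the target disagrees with the SCM.
    mask = np.abs(diff) > 0
    num = float(var_s[mask].sum())
    if denom <= 0.0:
        return 0.0
    return float(np.clip(num / denom, 0.0, 1.0))


def shrink(
    P: np.ndarray,
    config: ShrinkageConfig = ShrinkageConfig(),
    data: np.ndarray | None = None,
) -> np.ndarray:
    """Shrinkage covariance estimate ``λΓ + (1−λ)P``.

    Parameters
    ----------
    P
        Symmetric PSD sample covariance matrix.
    config
        Target and (optionally fixed) intensity; see :class:`ShrinkageConfig`.
    data
        Centered-or-raw channels × samples matrix that produced ``P``;
        required when ``config.lam`` is None (the analytic intensity is a
        functional of the samples, not of ``P`` alone).
    """
    P = _check_symmetric(P, "shrink input")
    if config.method == "none":
        return P
    target = _shrinkage_target(P, config.method)
    if config.lam is not None:
        lam = config.lam
    else:
        if data is None:
            raise ValueError(
                "analytic shrinkage intensity requires the data matrix; "
                "pass data= or set a fixed lambda"
            )
        lam = _analytic_lambda(P, target, data)
    out = lam * target + (1.0 - lam) * P
    return 0.5 * (out + out.T)


def _check_spd_pair(P1: np.ndarray, P2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P1 = _check_symmetric(P1, "P1")
    P2 = _check_symmetric(P2, "P2")
    if P1.shape != P2.shape:
        raise ValueError(f"dimension mismatch: {P1.shape} vs {P2.shape}")
    for name, P in (("P1", P1), ("P2", P2)):
        if scipy.linalg.eigvalsh(P).min() <= 0:
            raise ValueError(f"{name} is not positive definite")
    return P1, P2


def dist_ai(P1: np.ndarray, P2: np.ndarray) -> float:
    """Affine-invariant Riemannian distance.

    ``d(P1, P2) = ||log(P1^{-1} P2)||_F = sqrt(Σ_e log² λ_e)`` over the
    generalized eigenvalues λ_e of the pencil (P2, P1).  Invariant under any
    joint congruence ``P ↦ U P U^T`` with invertible U.
    """
    P1, P2 = _check_spd_pair(P1, P2)
    w = scipy.linalg.eigvalsh(P2, P1)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def dist_le(P1: np.ndarray, P2: np.ndarray) -> float:
    """Log-Euclidean distance ``||log(P1) − log(P2)||_F``.

    Invariant under joint orthogonal congruence; for commuting pairs it
    coincides with the affine-invariant distance.
    """
    P1, P2 = _check_spd_pair(P1, P2)
    return float(np.linalg.norm(logm_spd(P1) - logm_spd(P2), "fro"))


def mean_le(matrices: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Log-Euclidean mean ``exp((1/N) Σ log P_i)``.

    This is the unique minimizer of ``Σ_i d_LE²(P_i, M)``: the arithmetic
    mean in the log domain, mapped back with the matrix exponential.  For a
    commuting (e.g. diagonal) family it reduces to the elementwise geometric
    mean of the eigenvalues.
    """
    mats = list(matrices)
    if len(mats) == 0:
        raise ValueError("mean of an empty set of matrices")
    logs = [logm_spd(P) for P in mats]
    return expm_sym(np.mean(logs, axis=0))


def mean_ai(
    matrices: list[np.ndarray] | np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> np.ndarray:
    """Affine-invariant (Karcher/Fréchet) mean.

    For two matrices the closed-form geodesic midpoint
    ``P1^{1/2} (P1^{-1/2} P2 P1^{-1/2})^{1/2} P1^{1/2}`` is returned.  For
    more, the standard fixed-point iteration

        M ← M^{1/2} exp( mean_i log(M^{-1/2} P_i M^{-1/2}) ) M^{1/2}

    runs until the Frobenius norm of the tangent-space gradient (the inner
    mean of logs) falls below ``tol``.
    """
    mats = [_check_symmetric(P) for P in matrices]
    if len(mats) == 0:
        raise ValueError("mean of an empty set of matrices")
    if len(mats) == 1:
        return mats[0].copy()
    if len(mats) == 2:
        P1, P2 = mats
        P1_half = sqrtm_spd(P1)
        P1_ihalf = invsqrt(P1)
        inner = sqrtm_spd(P1_ihalf @ P2 @ P1_ihalf)
        M = P1_half @ inner @ P1_half
        return 0.5 * (M + M.T)

    M = mean_le(mats)  # warm start near the solution
    for it in range(max_iter):
        M_half = sqrtm_spd(M)
        M_ihalf = invsqrt(M)
        tangent = np.mean(
            [logm_spd(M_ihalf @ P @ M_ihalf.T) for P in mats], axis=0
        )
        grad_norm = float(np.linalg.norm(tangent, "fro"))
        if grad_norm < tol:
            return 0.5 * (M + M.T)
        M = M_half @ expm_sym(tangent) @ M_half
        M = 0.5 * (M + M.T)
    raise RuntimeError(
        f"affine-invariant mean did not converge in {max_iter} iterations "
        f"(last gradient norm {grad_norm:.3e}, N={len(mats)})"
    )
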