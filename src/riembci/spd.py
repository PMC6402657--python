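"""Geometry of symmetric positive-definite (SPD) matrices.

Spatial covariance matrices of band-passed EEG are SPD and are treated as
points on the Riemannian manifold of SPD matrices equipped with the
affine-invariant metric.  This module provides the covariance descriptor,
matrix log/exp, the affine-invariant (geodesic) distance, the tangent-space
(log-map) linearization with its isometric vectorization, and the iterative
Karcher (Frechet) mean.

All operations accept plain ``numpy`` arrays for SPD matrices; tangent
vectors are represented by the small :class:`TangentVector` container that
remembers the reference point of the log map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

__all__ = [
    "DegenerateSegmentError",
    "KarcherConvergenceError",
    "TangentVector",
    "check_spd",
    "covariance_descriptor",
    "exp_map",
    "karcher_mean",
    "log_map",
    "riemannian_distance",
    "tangent_distance",
    "tangent_vectorize",
    "sym_powm",
]

#: eigenvalues below this are clipped (with a warning) before taking logs
EIG_FLOOR = 1e-12


class DegenerateSegmentError(ValueError):
    """A data segment produced a covariance that is not positive definite."""


class KarcherConvergenceError(RuntimeError):
    """Karcher mean iteration failed to converge; carries the last residual."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"Karcher mean did not converge in {max_iter} iterations "
            f"(last tangent-mean residual {residual:.3e})"
        )


def _symmetrize(A: np.ndarray) -> np.ndarray:
    return 0.5 * (A + A.T)


def check_spd(A: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Validate that ``A`` is SPD; returns the symmetrized matrix.

    Symmetry is required to within ``tol`` (relative to the largest entry)
    and all eigenvalues must be strictly positive.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix has non-finite entries")
    scale = max(np.abs(A).max(), 1.0)
    if np.abs(A - A.T).max() > tol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    S = _symmetrize(A)
    w = np.linalg.eigvalsh(S)
    if w.min() <= 0:
        raise ValueError(f"matrix is not positive definite (min eig {w.min():.3e})")
    return S


def _eigh_clipped(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the symmetrized matrix with floored eigenvalues."""
    w, U = np.linalg.eigh(_symmetrize(A))
    if w.min() < EIG_FLOOR:
        warnings.warn(
            f"eigenvalue {w.min():.3e} below floor {EIG_FLOOR:.0e}; clipping",
            RuntimeWarning,
            stacklevel=3,
        )
        w = np.maximum(w, EIG_FLOOR)
    return w, U


def sym_powm(A: np.ndarray, p: float) -> np.ndarray:
    """Matrix power A^p of an SPD matrix through its eigendecomposition."""
    w, U = _eigh_clipped(A)
    return (U * w**p) @ U.T


def sym_logm(A: np.ndarray) -> np.ndarray:
    w, U = _eigh_clipped(A)
    return (U * np.log(w)) @ U.T


def sym_expm(A: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(_symmetrize(A))
    return (U * np.exp(w)) @ U.T


@dataclass(frozen=True)
class TangentVector:
    """Tangent vector at a reference SPD point.

    ``sym`` is the symmetric matrix log(C^{-1/2} S C^{-1/2}) living in the
    tangent space at ``reference``; its isometric (half-)vectorization is
    available through :func:`tangent_vectorize`.
    """

    sym: np.ndarray
    reference: np.ndarray

    @property
    def dim(self) -> int:
        return self.sym.shape[0]

    def vector(self, off_diag_scale: float = np.sqrt(2.0)) -> np.ndarray:
        return tangent_vectorize(self, off_diag_scale=off_diag_scale)


def covariance_descriptor(X: np.ndarray, shrinkage: float = 0.0) -> np.ndarray:
    """Spatial covariance descriptor C = X X^T / (T - 1) of a segment.

    Parameters
    ----------
    X : (n_channels, T) array
        A band-passed, zero-mean EEG segment.
    shrinkage : float in [0, 1)
        Optional convex shrinkage toward the scaled identity
        (trace(C)/n) I, guaranteeing strict positive definiteness for
        rank-deficient segments.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("segment must be a 2-D (channels x samples) array")
    n, T = X.shape
    if T < 2:
        raise ValueError("segment needs at least 2 time samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("segment has non-finite samples")
    if not 0.0 <= shrinkage < 1.0:
        raise ValueError("shrinkage must be in [0, 1)")
    C = X @ X.T / (T - 1)
    C = _symmetrize(C)
    if shrinkage > 0.0:
        mu = np.trace(C) / n
        C = (1.0 - shrinkage) * C + shrinkage * mu * np.eye(n)
    w = np.linalg.eigvalsh(C)
    if w.min() <= EIG_FLOOR * max(w.max(), 1.0):
        raise DegenerateSegmentError(
            f"segment covariance is rank deficient (min eig {w.min():.3e}); "
            "pass shrinkage > 0 for rank-deficient segments"
        )
    return C


def riemannian_distance(S1: np.ndarray, S2: np.ndarray) -> float:
    """Affine-invariant geodesic distance sqrt(sum_i log^2 lambda_i).

    lambda_i are the generalized eigenvalues of the pencil (S2, S1); the
    distance is invariant to congruence by any invertible matrix and to
    joint inversion of both arguments.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    if S1.shape != S2.shape:
        raise ValueError(f"dimension mismatch: {S1.shape} vs {S2.shape}")
    w = eigh(_symmetrize(S2), _symmetrize(S1), eigvals_only=True)
    if w.min() <= 0:
        raise ValueError("inputs are not both positive definite")
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def log_map(S: np.ndarray, C: np.ndarray) -> TangentVector:
    """Log map of S at reference C: log(C^{-1/2} S C^{-1/2})."""
    S = np.asarray(S, dtype=float)
    C = np.asarray(C, dtype=float)
    if S.shape != C.shape:
        raise ValueError(f"dimension mismatch: {S.shape} vs {C.shape}")
    Cmh = sym_powm(C, -0.5)
    return TangentVector(sym=sym_logm(Cmh @ S @ Cmh), reference=C.copy())


def exp_map(T: TangentVector | np.ndarray, C: np.ndarray) -> np.ndarray:
    """Exp map at C: C^{1/2} exp(T_sym) C^{1/2}; inverse of :func:`log_map`."""
    C = np.asarray(C, dtype=float)
    if isinstance(T, TangentVector):
        if T.reference.shape != C.shape or not np.allclose(T.reference, C):
            raise ValueError("tangent vector reference does not match C")
        Tsym = T.sym
    else:
        Tsym = _symmetrize(np.asarray(T, dtype=float))
    if Tsym.shape != C.shape:
        raise ValueError(f"dimension mismatch: {Tsym.shape} vs {C.shape}")
    Ch = sym_powm(C, 0.5)
    return _symmetrize(Ch @ sym_expm(Tsym) @ Ch)


def tangent_vectorize(
    T: TangentVector | np.ndarray, off_diag_scale: float = np.sqrt(2.0)
) -> np.ndarray:
    """Half-vectorization of a symmetric matrix, off-diagonals scaled.

    With the default sqrt(2) scaling the Euclidean norm of the vector equals
    the Frobenius norm of the matrix, so Euclidean distances between feature
    vectors equal Frobenius distances between tangent matrices.
    """
    M = T.sym if isinstance(T, TangentVector) else np.asarray(T, dtype=float)
    n = M.shape[0]
    iu = np.triu_indices(n)
    scale = np.where(iu[0] == iu[1], 1.0, off_diag_scale)
    return M[iu] * scale


def tangent_distance(S1: np.ndarray, S2: np.ndarray, C: np.ndarray) -> float:
    """Euclidean distance between the tangent vectors of S1, S2 at C.

    Equals the geodesic distance exactly when S1, S2 and C commute, and
    approximates it for points close to C (this is the working metric for
    the RVM kernel once features are normalized at the dataset mean).
    """
    v1 = log_map(S1, C).vector()
    v2 = log_map(S2, C).vector()
    return float(np.linalg.norm(v1 - v2))


def karcher_mean(
    mats: list[np.ndarray] | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> np.ndarray:
    """Karcher (geometric/Frechet) mean of a set of SPD matrices.

    Fixed-point iteration: starting from the arithmetic mean, repeatedly
    average the tangent vectors of all points at the current estimate and
    exp-map the average back, until the mean tangent vector stops moving
    (norm change below ``tol``).  At the fixed point the mean tangent
    vector is zero, which characterizes the Frechet mean.
    """
    mats = [np.asarray(M, dtype=float) for M in mats]
    if len(mats) == 0:
        raise ValueError("empty set has no mean")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    shape = mats[0].shape
    if any(M.shape != shape for M in mats):
        raise ValueError("all matrices must share a common dimension")
    if len(mats) == 1:
        return mats[0].copy()

    Sbar = _symmetrize(np.mean(mats, axis=0))
    prev_norm = None
    residual = np.inf
    for _ in range(max_iter):
        half = sym_powm(Sbar, 0.5)
        mhalf = sym_powm(Sbar, -0.5)
        Tbar = np.zeros(shape)
        for M in mats:
            Tbar += sym_logm(mhalf @ M @ mhalf)
        Tbar /= len(mats)
        Sbar = _symmetrize(half @ sym_expm(Tbar) @ half)
        norm = float(np.linalg.norm(Tbar))
        residual = norm
        if norm < tol or (prev_norm is not None and abs(norm - prev_norm) < tol):
            return Sbar
        prev_norm = norm
    raise KarcherConvergenceError(residual, max_iter)
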