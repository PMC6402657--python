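"""Multi-class Relevance Vector Machine (mRVM) on tangent-space features.

A sparse Bayesian kernel classifier: every training sample contributes an
RBF basis function, a zero-mean Gaussian prior with per-weight precision
(ARD) is placed on the basis weights, and class membership follows a
multinomial probit link.  Expectation-maximization alternates posterior
expectations of the truncated latent class scores with weight/precision
updates; basis functions whose precisions diverge are pruned, leaving a
small set of relevance vectors.  Prediction returns a proper probability
vector over the classes.

The latent probit integrals are evaluated by fixed-node Gauss-Hermite
quadrature, so training and prediction are deterministic given the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.stats import norm

__all__ = ["RVMModel", "kernel", "median_bandwidth", "train", "predict_proba"]

_QUAD_NODES = 48
_PRUNE_THRESHOLD = 1e6
_ALPHA_CAP = 1e12
_JITTER = 1e-8


def _quadrature() -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E_{u~N(0,1)}[f(u)] (probabilists' Gauss-Hermite)."""
    x, w = np.polynomial.hermite_e.hermegauss(_QUAD_NODES)
    return x, w / np.sqrt(2.0 * np.pi)


def kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian RBF kernel exp(-||x - y||^2 / (2 sigma^2)) in (0, 1]."""
    if sigma <= 0:
        raise ValueError("kernel bandwidth must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("feature vectors must have equal length")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def median_bandwidth(features: np.ndarray) -> float:
    """Median pairwise distance of the training set (the median heuristic)."""
    d = pdist(np.asarray(features, dtype=float))
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    return float(np.median(d))


@dataclass
class RVMModel:
    """Trained sparse multinomial-probit kernel classifier."""

    relevance_vectors: np.ndarray  # (M, n_features)
    weights: np.ndarray  # (M, n_classes)
    sigma: float
    classes: np.ndarray
    rv_indices: np.ndarray  # indices into the training set
    n_train: int
    converged: bool
    alpha: np.ndarray | None = None  # per-relevance-vector precisions

    @property
    def n_relevance(self) -> int:
        return self.relevance_vectors.shape[0]


def _latent_expectations(M_scores: np.ndarray, y_idx: np.ndarray) -> np.ndarray:
    """Posterior means of the truncated latent scores, per sample.

    For sample n of true class i the latents satisfy y_i > y_j for all j;
    the conditional expectations follow the closed forms of the multinomial
    probit, computed by quadrature over the shared standard-normal variable.
    """
    n, C = M_scores.shape
    u, qw = _quadrature()
    mi = M_scores[np.arange(n), y_idx][:, None]  # (n, 1)
    # phi_q[n, q, j] = Phi(u_q + m_i - m_j), j != i handled via mask
    diff = mi[:, :, None] - M_scores[:, None, :]  # (n, 1, C)
    z = u[None, :, None] + diff  # (n, Q, C)
    Phi = norm.cdf(z)
    pdf = norm.pdf(z)
    mask = np.ones((n, 1, C), dtype=bool)
    mask[np.arange(n), 0, y_idx] = False
    Phi_masked = np.where(mask, Phi, 1.0)
    full_prod = np.prod(Phi_masked, axis=2)  # (n, Q)
    Z = np.maximum(full_prod @ qw, 1e-300)  # (n,)

    # leave-one-out products: divide the full product by the k-th factor
    ratio = full_prod[:, :, None] / np.maximum(Phi, 1e-300)
    corr = np.einsum("nqk,q->nk", ratio * pdf, qw) / Z[:, None]  # (n, C)
    corr[np.arange(n), y_idx] = 0.0
    Y = M_scores - corr
    # the true-class latent absorbs the mass removed from the others
    Y[np.arange(n), y_idx] = M_scores[np.arange(n), y_idx] + corr.sum(axis=1)
    return Y


def train(
    features: np.ndarray,
    labels: np.ndarray,
    sigma: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
    inner_iter: int = 5,
) -> RVMModel:
    """Fit the mRVM by EM with ARD pruning (prune-from-full variant).

    Each training sample carries one precision shared across the class
    weights it feeds, so samples are retained or pruned jointly for all
    classes.  Every EM step computes the latent probit expectations once,
    then applies up to ``inner_iter`` weight/precision updates (the
    precision fixed point converges much faster than the latents change).
    Samples whose precision diverges past 1e6 are pruned.

    Parameters
    ----------
    features : (n, p) array of tangent-space feature vectors.
    labels : class labels (any hashable values; >= 2 samples per class).
    sigma : RBF bandwidth; defaults to the median pairwise distance.
    max_iter : outer EM iteration cap.
    tol : convergence tolerance on the log precisions.
    inner_iter : precision/weight updates per latent refresh.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    labels = np.asarray(labels)
    classes, y_idx = np.unique(labels, return_inverse=True)
    C = classes.size
    if C < 2:
        raise ValueError("training data must contain at least 2 classes")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 training samples")
    n = X.shape[0]
    if sigma is None:
        sigma = median_bandwidth(X)

    K = _kernel_matrix(X, X, sigma)  # (n data, n basis)
    active = np.arange(n)
    Phi = K.copy()
    alpha = np.ones(n)
    targets = np.where(y_idx[:, None] == np.arange(C)[None, :], 1.0, -1.0)

    # ridge warm start for the weights
    G = Phi.T @ Phi + np.eye(n) * (1.0 + _JITTER)
    try:
        W = np.linalg.solve(G, Phi.T @ targets)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"kernel matrix numerically singular: {e}")

    converged = False
    delta = np.inf
    for _ in range(max_iter):
        Y = _latent_expectations(Phi @ W, y_idx)
        PtP = Phi.T @ Phi
        PtY = Phi.T @ Y
        for _ in range(inner_iter):
            m = Phi.shape[1]
            if m == 0:
                break
            Gm = PtP + np.diag(alpha) + np.eye(m) * _JITTER
            try:
                L = np.linalg.cholesky(Gm)
            except np.linalg.LinAlgError as e:
                raise np.linalg.LinAlgError(
                    f"kernel matrix numerically singular after jitter: {e}"
                )
            W_new = np.linalg.solve(Gm, PtY)
            Linv = np.linalg.inv(L)
            diag_Sigma = np.sum(Linv**2, axis=0)
            # MacKay-style update with the per-sample (class-shared) precision
            gamma = np.clip(C * (1.0 - alpha * diag_Sigma), 1e-12, None)
            alpha_new = np.minimum(
                gamma / np.maximum((W_new**2).sum(axis=1), 1e-300), _ALPHA_CAP
            )
            keep = alpha_new < _PRUNE_THRESHOLD
            delta = (
                np.abs(np.log(alpha_new[keep]) - np.log(alpha[keep])).max()
                if np.any(keep)
                else 0.0
            )
            active = active[keep]
            Phi = Phi[:, keep]
            PtP = PtP[np.ix_(keep, keep)]
            PtY = PtY[keep]
            alpha = alpha_new[keep]
            W = W_new[keep]
            if delta < tol:
                break
        if delta < tol or Phi.shape[1] == 0:
            converged = delta < tol
            break

    return RVMModel(
        relevance_vectors=X[active].copy(),
        weights=W.copy(),
        sigma=float(sigma),
        classes=classes,
        rv_indices=active.copy(),
        n_train=n,
        converged=converged,
        alpha=alpha.copy(),
    )


def _probit_probabilities(M_scores: np.ndarray) -> np.ndarray:
    """P(c) = E_u[prod_{j != c} Phi(u + m_c - m_j)] for each sample."""
    n, C = M_scores.shape
    u, qw = _quadrature()
    out = np.empty((n, C))
    for c in range(C):
        diff = M_scores[:, c][:, None, None] - M_scores[:, None, :]  # (n,1,C)
        z = u[None, :, None] + diff
        Phi = norm.cdf(z)
        Phi[:, :, c] = 1.0
        out[:, c] = np.prod(Phi, axis=2) @ qw
    out = np.clip(out, 0.0, None)
    s = out.sum(axis=1, keepdims=True)
    return np.where(s > 0, out / s, 1.0 / C)


def predict_proba(model: RVMModel, features: np.ndarray) -> np.ndarray:
    """Class-membership probabilities; rows are non-negative and sum to 1."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.relevance_vectors.shape[1]:
        raise ValueError(
            f"feature length {X.shape[1]} does not match model "
            f"({model.relevance_vectors.shape[1]})"
        )
    C = model.classes.size
    if model.n_relevance == 0:
        return np.full((X.shape[0], C), 1.0 / C)
    Kt = _kernel_matrix(X, model.relevance_vectors, model.sigma)
    return _probit_probabilities(Kt @ model.weights)


def predict(model: RVMModel, features: np.ndarray) -> np.ndarray:
    """Predicted class labels; probability ties break to the lowest class."""
    P = predict_proba(model, features)
    return model.classes[np.argmax(P, axis=1)]
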