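"""Evaluation metrics for co-adaptive BCI sessions.

Beyond raw segment accuracy, performance of the classifier and of the user
are assessed separately:

* **QCM** — quality of the confusion matrix, min(q)/mean(q) over class-wise
  recalls q.  It is 1 when all classes are recognized equally well and 0 when
  at least one class is never recognized, so a degenerate always-same-class
  predictor scores 25% accuracy but 0 QCM.
* **Separability** — geodesic distance between two classes' Karcher means
  divided by the product of the within-class distance spreads; a
  classifier-independent measure of how discriminable the user's covariance
  patterns are.
* **Instability** — number of principal components of a class's
  tangent-space scatter needed to reach 95% explained variance; a proxy for
  the user's exploration (high) versus exploitation (low).

Run-to-run improvement is tested with an exact left-tail Wilcoxon
signed-rank test (small paired samples), and per-subject trends are
summarized by ordinary least-squares regression of QCM over runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .spd import karcher_mean, log_map, riemannian_distance

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "qcm",
    "separability",
    "instability",
    "wilcoxon_left",
    "linreg_runs",
    "kappa_to_accuracy",
    "chance_level",
    "round_pvalue",
    "round_score",
]


def chance_level(n_classes: int = 4) -> float:
    """Accuracy of always guessing one class, as a fraction."""
    return 1.0 / n_classes


def kappa_to_accuracy(kappa: float, n_classes: int = 4) -> float:
    """Accuracy equivalent to a Cohen's kappa at uniform chance.

    kappa = (acc - p0) / (1 - p0) with p0 = 1/n_classes, so a kappa of 0.4
    corresponds to 70% accuracy for 2 classes but only 55% for 4.
    """
    p0 = chance_level(n_classes)
    return kappa * (1.0 - p0) + p0


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-normalized confusion matrix plus the raw counts.

    Rows are true classes; entry (i, j) is the fraction of class-i segments
    predicted as class j.  The diagonal ``q`` holds per-class recalls.
    """

    Q: np.ndarray
    counts: np.ndarray

    @property
    def q(self) -> np.ndarray:
        return np.diag(self.Q)

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else 0.0


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 4
) -> ConfusionMatrix:
    """Confusion matrix over labels 1..n_classes, row-normalized by class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true - 1, y_pred - 1):
        counts[t, p] += 1
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Q = np.where(row > 0, counts / np.maximum(row, 1), 0.0)
    return ConfusionMatrix(Q=Q, counts=counts)


def qcm(Q: ConfusionMatrix | np.ndarray) -> float:
    """Quality of the confusion matrix: min(q) / mean(q).

    ``Q`` may be a :class:`ConfusionMatrix`, a full row-normalized matrix,
    or the diagonal vector of class recalls directly.
    """
    if isinstance(Q, ConfusionMatrix):
        q = Q.q
    else:
        Q = np.asarray(Q, dtype=float)
        q = np.diag(Q) if Q.ndim == 2 else Q
    m = q.mean()
    if m == 0.0:
        return 0.0
    return float(q.min() / m)


def separability(
    class_a_covs: list[np.ndarray], class_b_covs: list[np.ndarray]
) -> float:
    """Between-class geodesic distance over the product of within-class spreads.

    s(A, B) = d(mu_A, mu_B) / (sigma_A * sigma_B), with mu the Karcher mean
    of each class and sigma the standard deviation of each member's geodesic
    distance to its own class mean.
    """
    if len(class_a_covs) < 2 or len(class_b_covs) < 2:
        raise ValueError("each class needs at least 2 samples")
    mu_a = karcher_mean(class_a_covs)
    mu_b = karcher_mean(class_b_covs)
    d_ab = riemannian_distance(mu_a, mu_b)
    sig_a = np.std([riemannian_distance(C, mu_a) for C in class_a_covs], ddof=1)
    sig_b = np.std([riemannian_distance(C, mu_b) for C in class_b_covs], ddof=1)
    if sig_a == 0.0 or sig_b == 0.0:
        raise ValueError("degenerate class: zero within-class spread")
    return float(d_ab / (sig_a * sig_b))


def instability(class_covs: list[np.ndarray], threshold: float = 0.95) -> int:
    """Principal components needed for ``threshold`` of tangent-space variance.

    All covariances are log-mapped at the class Karcher mean; PCA runs on the
    isometrically vectorized tangent vectors.  A class of identical
    covariances has zero variance and instability 0 by convention.
    """
    if len(class_covs) < 2:
        raise ValueError("need at least 2 samples")
    mu = karcher_mean(class_covs)
    V = np.array([log_map(C, mu).vector() for C in class_covs])
    V = V - V.mean(axis=0)
    s = np.linalg.svd(V, compute_uv=False)
    var = s**2
    total = var.sum()
    if total <= 0.0:
        return 0
    frac = np.cumsum(var) / total
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of mid-ranks of positive differences) and the mid-ranks."""
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    return w_pos, ranks


def wilcoxon_left(before: np.ndarray, after: np.ndarray) -> float:
    """Exact left-tail Wilcoxon signed-rank p-value for H1: before < after.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  The p-value is the exact probability, over all 2^n equally
    likely sign assignments of the observed absolute differences, that the
    positive-rank sum of before - after is <= the observed one.  Small-n
    regime (n <= 25 after dropping zeros).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if not (np.all(np.isfinite(before)) and np.all(np.isfinite(after))):
        raise ValueError("non-finite values in pairs")
    d = before - after
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n > 25:
        raise ValueError("exact enumeration supported only for n <= 25")
    w_obs, ranks = _signed_rank_stat(d)
    # doubled mid-ranks are integers -> exact subset-sum distribution by DP
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0**n
    w2 = int(np.rint(2.0 * w_obs))
    return float(dist[: w2 + 1].sum())


def linreg_runs(y: np.ndarray, runs: np.ndarray | None = None) -> tuple[float, float]:
    """OLS slope and intercept of scores over run index (default 1..len(y))."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 points")
    if runs is None:
        runs = np.arange(1, y.size + 1, dtype=float)
    res = stats.linregress(runs, y)
    return float(res.slope), float(res.intercept)


def round_pvalue(p: float) -> float:
    """Round a p-value the way the result tables print it.

    Three decimals when below 0.01, two otherwise; half-up rounding.
    """
    p = float(p)
    places = "0.001" if p < 0.01 else "0.01"
    return float(Decimal(repr(p)).quantize(Decimal(places), rounding=ROUND_HALF_UP))


def round_score(x: float) -> float:
    """One-decimal half-up rounding used for accuracy/QCM percentages."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )
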