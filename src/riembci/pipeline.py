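"""Adaptive mixture-of-RVM pipeline: sample selection, sub-model training,
online weighting, and the run/trial feedback protocol driver.

One *sub-model* is trained per run: a spatial filter W, the Karcher mean mu
of its training covariances (the tangent-space reference point), and an RVM
on the tangent features.  Training data are *representative segments*: per
trial, the k nearest neighbours (geodesic distance) of the trial's Karcher
mean — each trial is expected to repeat one central pattern, so segments far
from the trial mean are distraction.  k is cross-validated on the next
run's data by confusion-matrix quality (QCM).

Online, the active sub-models form an adaptively weighted mixture.  Each
sub-model i scores an incoming segment with prior a_i (its QCM-quality on
the latest run, suppressed to 0 below a threshold) divided by the running
mean distance of the current trial's covariances to mu_i — a sub-model
whose reference region the user has drifted away from loses weight within
a couple of segments.  Weights are normalized over active sub-models and
reset at each trial onset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import rvm as _rvm
from .csp import SpatialFilter, apply_filter, fit_covariances
from .metrics import ConfusionMatrix, confusion_matrix, qcm
from .signal_io import Segment, Session, segment_session
from .spd import (
    covariance_descriptor,
    karcher_mean,
    log_map,
    riemannian_distance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SubModel",
    "MixtureModel",
    "MixturePredictor",
    "prefilter",
    "select_representatives",
    "fit_filter_and_select",
    "train_submodel",
    "train_candidates",
    "cross_validate_k",
    "update_mixture",
    "mixture_predict",
    "predict_segments",
    "run_protocol",
    "adapt_session",
    "SessionResult",
]

_DIV_GUARD = 1e-6


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters (defaults follow the study protocol)."""

    d: int = 12  # CSP components kept
    k_min: int = 8  # representative segments per trial, lower bound
    k_max: int = 12  # upper bound (inclusive)
    k_init: int = 9  # k of the single model used during run 1
    epsilon: float = 0.25  # prior-suppression threshold on p(Q)
    epsilon_f: float = 0.1  # pre-filter threshold on true-class probability
    shrinkage: float = 0.0  # covariance shrinkage for rank-deficient segments
    off_diag_scale: float = float(np.sqrt(2.0))
    karcher_tol: float = 1e-6
    karcher_max_iter: int = 50
    rvm_max_iter: int = 500
    rvm_sigma: float | None = None  # None -> median heuristic
    dbar_mode: str = "trial"  # 'trial' | 'exponential' | 'run'
    dbar_decay: float = 0.9  # only for dbar_mode='exponential'
    selection_iterations: int = 1
    max_models: int | None = None  # optional cap, oldest evicted first

    @property
    def k_values(self) -> range:
        return range(self.k_min, self.k_max + 1)


@dataclass
class SubModel:
    """One run's trained classifier with its feature geometry attached."""

    rvm: _rvm.RVMModel
    W: SpatialFilter
    mu: np.ndarray  # reference Karcher mean of the training covariances
    k: int
    run: int
    a: float = 0.0  # prior weight; 0 = suppressed
    qcm: float = float("nan")  # quality on the most recent evaluation data

    def features(self, segments: list[Segment], config: PipelineConfig) -> np.ndarray:
        covs = _filtered_covariances(segments, self.W, config.shrinkage)
        return np.array(
            [log_map(C, self.mu).vector(config.off_diag_scale) for C in covs]
        )

    def predict_proba(
        self, segments: list[Segment], config: PipelineConfig
    ) -> np.ndarray:
        return _rvm.predict_proba(self.rvm, self.features(segments, config))


@dataclass
class MixtureModel:
    """Ordered set of sub-models with suppression threshold epsilon."""

    submodels: list[SubModel] = field(default_factory=list)
    epsilon: float = 0.25

    @property
    def m(self) -> int:
        return len(self.submodels)

    @property
    def active(self) -> list[SubModel]:
        return [s for s in self.submodels if s.a > 0]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _filtered_covariances(
    segments: list[Segment], W: SpatialFilter | None, shrinkage: float
) -> list[np.ndarray]:
    out = []
    for s in segments:
        X = s.samples if W is None else apply_filter(W, s.samples)
        out.append(covariance_descriptor(X, shrinkage))
    return out


def _group_by_trial(segments: list[Segment]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(segments):
        groups.setdefault(s.trial_index, []).append(i)
    return groups


# ---------------------------------------------------------------------------
# spatial-filter fitting and representative-sample selection
# ---------------------------------------------------------------------------


def prefilter(
    segments: list[Segment],
    previous_mixture: MixtureModel | None,
    epsilon_f: float = 0.1,
    config: PipelineConfig | None = None,
) -> list[Segment]:
    """Drop segments the previous model found certainly noisy.

    Keeps segments whose true-class probability under the previous mixture
    exceeds ``epsilon_f`` (chosen below chance, 0.1 < 0.25, so the selection
    stays nearly independent of the old models and can follow the user's
    exploration).  Without a previous mixture all segments are kept.  A
    trial that would lose every segment falls back to keeping its single
    highest-probability segment.
    """
    if not 0 <= epsilon_f < 1:
        raise ValueError("epsilon_f must be in [0, 1)")
    if previous_mixture is None or not previous_mixture.active or epsilon_f == 0:
        return list(segments)
    config = config or PipelineConfig()
    probs, _ = predict_segments(previous_mixture, segments, config)
    p_true = probs[np.arange(len(segments)), [s.label - 1 for s in segments]]
    kept: list[Segment] = []
    for trial, idx in _group_by_trial(segments).items():
        good = [i for i in idx if p_true[i] > epsilon_f]
        if not good:
            best = idx[int(np.argmax(p_true[idx]))]
            warnings.warn(
                f"trial {trial}: all segments below the pre-filter threshold; "
                "keeping its single most probable segment",
                RuntimeWarning,
            )
            good = [best]
        kept.extend(segments[i] for i in good)
    return kept


def select_representatives(
    covs: list[np.ndarray],
    k: int,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> list[int]:
    """Indices (0-based, ascending) of the k covariances nearest their
    Karcher mean; distance ties break to the lower index."""
    n = len(covs)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    mu = karcher_mean(covs, tol=tol, max_iter=max_iter)
    dists = np.array([riemannian_distance(C, mu) for C in covs])
    order = np.lexsort((np.arange(n), dists))[:k]
    return sorted(int(i) for i in order)


def _trial_rankings(
    segments: list[Segment], W: SpatialFilter, config: PipelineConfig
) -> dict[int, list[int]]:
    """Per trial, segment positions ordered by distance to the trial mean."""
    covs = _filtered_covariances(segments, W, config.shrinkage)
    rankings: dict[int, list[int]] = {}
    for trial, idx in _group_by_trial(segments).items():
        tc = [covs[i] for i in idx]
        mu = karcher_mean(tc, tol=config.karcher_tol, max_iter=config.karcher_max_iter)
        dists = np.array([riemannian_distance(C, mu) for C in tc])
        order = np.lexsort((np.arange(len(idx)), dists))
        rankings[trial] = [idx[i] for i in order]
    return rankings


def fit_filter_and_select(
    run_segments: list[Segment],
    d: int = 12,
    k: int = 9,
    W_init: SpatialFilter | None = None,
    previous_mixture: MixtureModel | None = None,
    config: PipelineConfig | None = None,
    source_run: int = -1,
) -> tuple[SpatialFilter, dict[int, list[int]]]:
    """One pass of spatial-filter fitting and representative-sample selection.

    Pre-filter -> apply W -> per-trial covariances -> keep each trial's k
    nearest neighbours of its Karcher mean -> refit the multi-class CSP on
    the selected segments only.  For the first run W is initialized from all
    segments; later runs pass the previous run's filter.
    """
    config = config or PipelineConfig()
    segs = prefilter(run_segments, previous_mixture, config.epsilon_f, config)
    W = W_init
    if W is None:
        covs = _filtered_covariances(segs, None, config.shrinkage)
        labels = np.array([s.label for s in segs])
        W = fit_covariances(np.stack(covs), labels, d, source_run=source_run)

    selections: dict[int, list[int]] = {}
    for _ in range(max(config.selection_iterations, 1)):
        rankings = _trial_rankings(segs, W, config)
        selected: list[Segment] = []
        selections = {}
        for trial, order in rankings.items():
            chosen = sorted(order[: min(k, len(order))])
            selections[trial] = [segs[i].segment_index for i in chosen]
            selected.extend(segs[i] for i in chosen)
        covs = _filtered_covariances(selected, None, config.shrinkage)
        labels = np.array([s.label for s in selected])
        W = fit_covariances(np.stack(covs), labels, d, source_run=source_run)
    return W, selections


# ---------------------------------------------------------------------------
# sub-model training and cross-validation
# ---------------------------------------------------------------------------


def _fit_submodel_from_selection(
    segs: list[Segment],
    W: SpatialFilter,
    selections: dict[int, list[int]],
    k: int,
    run: int,
    config: PipelineConfig,
) -> SubModel:
    by_trial = _group_by_trial(segs)
    selected = [
        segs[i]
        for trial, idx in by_trial.items()
        for i in idx
        if segs[i].segment_index in selections.get(trial, [])
    ]
    covs = _filtered_covariances(selected, W, config.shrinkage)
    mu = karcher_mean(covs, tol=config.karcher_tol, max_iter=config.karcher_max_iter)
    feats = np.array([log_map(C, mu).vector(config.off_diag_scale) for C in covs])
    labels = np.array([s.label for s in selected])
    model = _rvm.train(
        feats, labels, sigma=config.rvm_sigma, max_iter=config.rvm_max_iter
    )
    logger.info(
        "trained sub-model run=%d k=%d: %d relevance vectors / %d samples",
        run, k, model.n_relevance, model.n_train,
    )
    return SubModel(rvm=model, W=W, mu=mu, k=k, run=run)


def train_submodel(
    run_segments: list[Segment],
    k: int = 9,
    d: int = 12,
    W_init: SpatialFilter | None = None,
    previous_mixture: MixtureModel | None = None,
    config: PipelineConfig | None = None,
    run: int = 0,
) -> SubModel:
    """Full sub-model training: representative selection, tangent features at
    the selection's Karcher mean, then the sparse RVM."""
    config = config or PipelineConfig()
    segs = prefilter(run_segments, previous_mixture, config.epsilon_f, config)
    W, selections = fit_filter_and_select(
        segs, d=d, k=k, W_init=W_init, previous_mixture=None,
        config=replace(config, epsilon_f=0.0), source_run=run,
    )
    return _fit_submodel_from_selection(segs, W, selections, k, run, config)


def train_candidates(
    run_segments: list[Segment],
    d: int = 12,
    W_init: SpatialFilter | None = None,
    previous_mixture: MixtureModel | None = None,
    config: PipelineConfig | None = None,
    run: int = 0,
) -> dict[int, SubModel]:
    """Train the sub-model family {k_min..k_max} on one run's data.

    The pre-filter and the per-trial distance rankings are shared across k
    (only the k-NN cut and the CSP refit differ), which keeps the per-run
    adaptation cheap.
    """
    config = config or PipelineConfig()
    segs = prefilter(run_segments, previous_mixture, config.epsilon_f, config)
    W0 = W_init
    if W0 is None:
        covs = _filtered_covariances(segs, None, config.shrinkage)
        labels = np.array([s.label for s in segs])
        W0 = fit_covariances(np.stack(covs), labels, d, source_run=run)
    rankings = _trial_rankings(segs, W0, config)
    full_covs = _filtered_covariances(segs, None, config.shrinkage)
    all_labels = np.array([s.label for s in segs])

    out: dict[int, SubModel] = {}
    for k in config.k_values:
        sel_pos = [
            i for order in rankings.values() for i in sorted(order[:k])
        ]
        W_k = fit_covariances(
            np.stack([full_covs[i] for i in sel_pos]),
            all_labels[sel_pos],
            d,
            source_run=run,
        )
        selections = {
            trial: sorted(segs[i].segment_index for i in order[:k])
            for trial, order in rankings.items()
        }
        out[k] = _fit_submodel_from_selection(segs, W_k, selections, k, run, config)
    return out


def evaluate_submodel(
    sub: SubModel, segments: list[Segment], config: PipelineConfig | None = None
) -> ConfusionMatrix:
    """Confusion matrix of a single sub-model on labeled segments."""
    config = config or PipelineConfig()
    probs = sub.predict_proba(segments, config)
    preds = np.argmax(probs, axis=1) + 1
    return confusion_matrix([s.label for s in segments], preds)


def cross_validate_k(
    candidates: dict[int, SubModel] | list[SubModel],
    new_run_data: list[Segment],
    config: PipelineConfig | None = None,
) -> SubModel:
    """Pick the candidate with the best QCM on the new run; ties -> smaller k."""
    config = config or PipelineConfig()
    subs = list(candidates.values()) if isinstance(candidates, dict) else list(candidates)
    if not subs:
        raise ValueError("empty candidate set")
    best = None
    for sub in sorted(subs, key=lambda s: s.k):
        score = qcm(evaluate_submodel(sub, new_run_data, config))
        sub.qcm = score
        if best is None or score > best.qcm:
            best = sub
    logger.info("cross-validated k*=%d (qcm=%.3f)", best.k, best.qcm)
    return best


# ---------------------------------------------------------------------------
# mixture maintenance and online prediction
# ---------------------------------------------------------------------------


def update_mixture(
    mixture: MixtureModel,
    run_r_data: list[Segment],
    candidates_prev: dict[int, SubModel],
    candidates_r: dict[int, SubModel],
    config: PipelineConfig | None = None,
) -> MixtureModel:
    """Post-run mixture update.

    (1) the run-(r-1) sub-model is replaced by the candidate that
    cross-validates best on the just-completed run's data D_r; (2) the run-r
    sub-model is appended with that same k* (D_{r+1} does not exist yet, so
    k* is inferred); (3) every sub-model's prior a_i is set to its
    confusion-matrix quality p(Q_i) on D_r, the newest receiving the maximum
    of the others; (4) historical priors below epsilon are suppressed to 0.
    """
    config = config or PipelineConfig()
    best_prev = cross_validate_k(candidates_prev, run_r_data, config)
    submodels = [s for s in mixture.submodels if s.run != best_prev.run]
    submodels.append(best_prev)
    submodels.sort(key=lambda s: s.run)

    for sub in submodels:
        if np.isnan(sub.qcm) or sub is not best_prev:
            sub.qcm = qcm(evaluate_submodel(sub, run_r_data, config))
        sub.a = sub.qcm if sub.qcm >= mixture.epsilon else 0.0
        if sub.a == 0.0:
            logger.info("suppressed sub-model run=%d (qcm=%.3f < %.2f)",
                        sub.run, sub.qcm, mixture.epsilon)

    new_sub = candidates_r[best_prev.k]
    new_sub.a = max((s.qcm for s in submodels), default=0.0)
    if new_sub.a <= 0.0:
        new_sub.a = 1.0  # degenerate history: fall back to the newest alone
    submodels.append(new_sub)
    if config.max_models is not None and len(submodels) > config.max_models:
        submodels = submodels[-config.max_models :]
    return MixtureModel(submodels=submodels, epsilon=mixture.epsilon)


class MixturePredictor:
    """Stateful online predictor implementing the adaptive weights.

    For sub-model i the unnormalized weight is b_i = a_i / max(dbar_i, eps)
    where dbar_i is the running mean of the geodesic distances between the
    current trial's filtered covariances and the sub-model's reference mean
    mu_i; weights are normalized over active sub-models.  The running means
    reset at each trial onset (first segment's distance initializes them),
    keeping the weights responsive yet stable within a trial.
    """

    def __init__(self, mixture: MixtureModel, config: PipelineConfig | None = None):
        self.mixture = mixture
        self.config = config or PipelineConfig()
        self.active = mixture.active
        if not self.active:
            raise ValueError("mixture has no active sub-model (all priors zero)")
        self._dbar = np.zeros(len(self.active))
        self._count = 0

    def start_trial(self) -> None:
        if self.config.dbar_mode != "run":
            self._dbar = np.zeros(len(self.active))
            self._count = 0

    def predict(self, seg: Segment) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        probs = np.zeros((len(self.active), 4))
        dists = np.zeros(len(self.active))
        for i, sub in enumerate(self.active):
            C = covariance_descriptor(
                apply_filter(sub.W, seg.samples), cfg.shrinkage
            )
            dists[i] = riemannian_distance(C, sub.mu)
            probs[i] = sub.predict_proba([seg], cfg)[0]
        if cfg.dbar_mode == "exponential" and self._count > 0:
            self._dbar = cfg.dbar_decay * self._dbar + (1 - cfg.dbar_decay) * dists
        else:
            self._dbar = (self._dbar * self._count + dists) / (self._count + 1)
        self._count += 1
        a = np.array([s.a for s in self.active])
        b = a / np.maximum(self._dbar, _DIV_GUARD)
        w = b / b.sum()
        return w @ probs, w


def mixture_predict(
    mixture: MixtureModel,
    seg: Segment,
    predictor: MixturePredictor | None = None,
    config: PipelineConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and sub-model weights for one segment.

    Stateless convenience wrapper; pass a :class:`MixturePredictor` to carry
    the running distance means across the segments of a trial.
    """
    if predictor is None:
        predictor = MixturePredictor(mixture, config)
    return predictor.predict(seg)


def predict_segments(
    mixture: MixtureModel,
    segments: list[Segment],
    config: PipelineConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replay prediction over segments with trial-boundary weight resets.

    Returns (probabilities (n, 4), predicted labels (n,)).
    """
    predictor = MixturePredictor(mixture, config)
    probs = np.zeros((len(segments), 4))
    current = None
    for i, seg in enumerate(segments):
        key = (seg.run_index, seg.trial_index)
        if key != current:
            predictor.start_trial()
            current = key
        probs[i], _ = predictor.predict(seg)
    return probs, np.argmax(probs, axis=1) + 1


def run_protocol(
    mixture: MixtureModel | None,
    run_segments: list[Segment],
    mode: str = "constrained",
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> list[dict]:
    """Replay one run segment-by-segment, logging prediction and feedback.

    Modes: ``sham`` (no classifier required; the displayed motion is correct
    with probability 0.8 and random otherwise — the calibration run),
    ``constrained`` (the swarm advances only on correct predictions) and
    ``full`` (the raw prediction drives the feedback).
    """
    if mode not in ("sham", "constrained", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    predictor = None
    if mode != "sham":
        if mixture is None:
            raise ValueError(f"{mode} mode requires a mixture")
        predictor = MixturePredictor(mixture, config)
    log: list[dict] = []
    current = None
    for seg in run_segments:
        key = (seg.run_index, seg.trial_index)
        if key != current:
            if predictor is not None:
                predictor.start_trial()
            current = key
        rec = {
            "run": seg.run_index,
            "trial": seg.trial_index,
            "segment": seg.segment_index,
            "label": seg.label,
        }
        if mode == "sham":
            correct = bool(rng.random() < 0.8)
            shown = seg.label if correct else int(rng.integers(1, 5))
            rec.update(
                prediction=shown, probability=None,
                feedback="advance" if correct else "random",
                feedback_correct=correct, weights=(),
            )
        else:
            probs, w = predictor.predict(seg)
            pred = int(np.argmax(probs) + 1)
            correct = pred == seg.label
            if mode == "constrained":
                feedback = "advance" if correct else "still"
            else:
                feedback = f"motion-{pred}"
            rec.update(
                prediction=pred, probability=float(probs[seg.label - 1]),
                feedback=feedback, feedback_correct=bool(correct),
                weights=tuple(float(x) for x in w),
            )
        log.append(rec)
    return log


# ---------------------------------------------------------------------------
# session driver
# ---------------------------------------------------------------------------


@dataclass
class SessionResult:
    """Per-run artifacts of an adaptive replay of a whole session."""

    mixtures: list[MixtureModel]  # mixture *after* adapting on run r
    candidates: list[dict[int, SubModel]]
    online_logs: list[list[dict]]  # feedback log of each replayed run
    online_qcm: list[float]  # QCM of the online predictions, runs 1..
    online_accuracy: list[float]


def _run_mode(run_index: int, n_constrained: int = 4) -> str:
    if run_index == 0:
        return "sham"
    return "constrained" if run_index <= n_constrained else "full"


def adapt_session(
    session: Session,
    config: PipelineConfig | None = None,
    seed: int = 0,
    n_runs: int | None = None,
) -> SessionResult:
    """Replay a recorded/synthetic session through the co-adaptive protocol.

    Run 0 (sham feedback) trains the initial candidate family; during run r
    the mixture frozen after run r-1 predicts online; after run r the
    mixture is updated (cross-validated replacement + inferred new model).
    """
    config = config or PipelineConfig()
    total = n_runs if n_runs is not None else session.n_runs
    result = SessionResult([], [], [], [], [])

    run0 = segment_session(session, 0)
    cands0 = train_candidates(run0, d=config.d, config=config, run=0)
    result.candidates.append(cands0)
    result.online_logs.append(
        run_protocol(None, run0, "sham", seed=seed, config=config)
    )
    first = cands0[config.k_init]
    first.a = 1.0
    mixture = MixtureModel(submodels=[first], epsilon=config.epsilon)
    result.mixtures.append(mixture)

    for r in range(1, total):
        segs = segment_session(session, r)
        log = run_protocol(
            mixture, segs, _run_mode(r), seed=seed + r, config=config
        )
        result.online_logs.append(log)
        preds = [rec["prediction"] for rec in log]
        cm = confusion_matrix([s.label for s in segs], preds)
        result.online_qcm.append(qcm(cm))
        result.online_accuracy.append(cm.accuracy)

        prev_W = mixture.submodels[-1].W
        cands_r = train_candidates(
            segs, d=config.d, W_init=prev_W,
            previous_mixture=mixture, config=config, run=r,
        )
        result.candidates.append(cands_r)
        mixture = update_mixture(
            mixture, segs, result.candidates[r - 1], cands_r, config
        )
        result.mixtures.append(mixture)
    return result
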