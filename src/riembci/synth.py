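"""Seeded generator of 4-class EEG sessions with covariance-borne structure.

The generator emulates the recording protocol the pipeline targets
(60 channels at 256 Hz; 7 runs of 40 ten-second trials, 10 per class) with
all class-discriminative structure placed in the spatial covariance — which
is exactly what the covariance descriptor can see, making it the right
testing surface for the pipeline.  The hierarchy is:

* a base AR(1)-structured covariance C0 (channel correlation decaying with
  channel index distance), giving CSP realistic structure to exploit;
* class prototypes M_c = Exp_{C0}(delta U_c) along fixed orthonormal
  tangent directions U_c — ``delta`` (the separation) is the geodesic
  magnitude of the class effect;
* per-trial means Exp_{M_c}(tau V) with random unit tangent V — ``tau``
  (the dispersion) models the user's trial-to-trial exploration;
* run-to-run drift Exp(rho G_c) of the prototypes along fixed directions,
  and exploitation under feedback: the dispersion shrinks geometrically
  (tau_{r+1} = gamma tau_r) while the trial means concentrate onto a
  per-class preferred tangent axis, so exploration loses both magnitude
  and dimensionality across runs;
* optional outlier spans: 2 s stretches of a trial resampled from a far-off
  covariance (distraction), implanted in the time series so overlapping
  segmentation smears them realistically.

Trials are zero-mean Gaussian time series with the trial covariance; there
is no evoked temporal structure, no 1/f spectrum and no biophysical head
model, so passing tests demonstrate correct recovery of covariance
structure, not performance on physiological EEG.  Everything is bit-exactly
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import RawTrial, Session, SessionConfig
from .spd import exp_map, sym_powm

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "UserState",
    "make_base_covariance",
    "make_prototypes",
    "generate_trial",
    "generate_session",
    "user_model_step",
]

N_CLASSES = 4


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-session parameters; the defaults emulate the study protocol.

    ``separation`` and ``dispersion`` are geodesic magnitudes (affine-
    invariant metric, dimensionless); ``drift`` is the per-run prototype
    step; ``exploitation`` is the per-run dispersion shrink factor gamma in
    (0, 1]; ``concentration`` sets how fast exploitation aligns trial means
    with the class's preferred axis (alignment 1 - gamma^(concentration*r));
    ``outlier_prob`` is the probability that any 2 s span of a trial is
    replaced by distraction noise.
    """

    n_channels: int = 60
    rate: float = 256.0
    n_runs: int = 7
    trials_per_class: int = 10
    trial_seconds: float = 10.0
    separation: float = 0.5
    dispersion: float = 0.3
    drift: float = 0.1
    exploitation: float = 0.9
    concentration: float = 8.0
    outlier_prob: float = 0.0
    outlier_magnitude: float = 3.0
    ar_coeff: float = 0.5
    seed: int = 0

    def session_config(self) -> SessionConfig:
        return SessionConfig(
            n_channels=self.n_channels,
            n_eog=0,
            rate=self.rate,
            n_runs=self.n_runs,
            trials_per_class=self.trials_per_class,
            trial_seconds=self.trial_seconds,
        )

    def validate(self) -> None:
        for name in ("separation", "dispersion", "drift", "outlier_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.exploitation <= 1:
            raise ValueError("exploitation factor must be in (0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually drew, for recovery checks."""

    prototypes: list[np.ndarray]  # [run][class] SPD, indexed prototypes[r][c-1]
    trial_means: dict[tuple[int, int], np.ndarray]  # (run, trial) -> SPD
    outlier_spans: dict[tuple[int, int], list[tuple[int, int]]]  # sample ranges
    dispersions: list[float]  # tau per run

    def outlier_segments(
        self, run: int, trial: int, window: float = 2.0, step: float = 0.25,
        rate: float = 256.0, duration: float = 10.0,
    ) -> list[int]:
        """1-based indices of segments overlapping an implanted outlier span."""
        spans = self.outlier_spans.get((run, trial), [])
        wlen = int(round(window * rate))
        slen = int(round(step * rate))
        n_seg = (int(round(duration * rate)) - wlen) // slen + 1
        out = []
        for i in range(n_seg):
            a, b = i * slen, i * slen + wlen
            if any(a < hi and lo < b for lo, hi in spans):
                out.append(i + 1)
        return out


def make_base_covariance(n_channels: int, ar_coeff: float = 0.5) -> np.ndarray:
    """AR(1) base covariance: corr(i, j) = ar_coeff^|i-j|."""
    idx = np.arange(n_channels)
    return ar_coeff ** np.abs(idx[:, None] - idx[None, :])


def _class_directions(n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed orthonormal tangent directions, one per class.

    The directions are diagonal in the whitened frame of the base
    covariance, with orthonormal diagonal vectors; within this commuting
    family the manifold is flat, so pairwise prototype distances are exactly
    separation * sqrt(2).
    """
    G = rng.standard_normal((n_channels, N_CLASSES))
    Q, _ = np.linalg.qr(G)
    return Q[:, :N_CLASSES].T  # (4, n_channels) orthonormal rows


def make_prototypes(config: GeneratorConfig) -> tuple[list[np.ndarray], np.ndarray]:
    """Class prototypes for run 0 plus the diagonal direction vectors."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    C0 = make_base_covariance(config.n_channels, config.ar_coeff)
    dirs = _class_directions(config.n_channels, rng)
    C0h = sym_powm(C0, 0.5)
    protos = [
        C0h @ np.diag(np.exp(config.separation * u)) @ C0h for u in dirs
    ]
    return protos, dirs


def _random_unit_tangent(n: int, rng: np.random.Generator) -> np.ndarray:
    V = rng.standard_normal((n, n))
    V = 0.5 * (V + V.T)
    return V / np.linalg.norm(V)


def generate_trial(
    prototype: np.ndarray,
    tau: float,
    p_out: float,
    rng: np.random.Generator,
    rate: float = 256.0,
    duration: float = 10.0,
    label: int = 1,
    trial_index: int = 0,
    run_index: int = 0,
    outlier_magnitude: float = 3.0,
    direction: np.ndarray | None = None,
) -> tuple[RawTrial, np.ndarray, list[tuple[int, int]]]:
    """One trial: Gaussian series around a dispersed trial mean.

    The trial mean sits at geodesic distance ``tau`` from the prototype
    along ``direction`` (a random unit tangent when not given).  Returns the
    trial, the trial-mean covariance actually used, and the sample spans
    (if any) replaced by outlier noise.
    """
    n = prototype.shape[0]
    if tau > 0:
        V = direction if direction is not None else _random_unit_tangent(n, rng)
        M_trial = exp_map(tau * V, prototype)
    else:
        M_trial = prototype.copy()
    T = int(round(duration * rate))
    L = np.linalg.cholesky(M_trial)
    X = L @ rng.standard_normal((n, T))

    spans: list[tuple[int, int]] = []
    if p_out > 0:
        span_len = int(round(2.0 * rate))
        M_out = exp_map(
            outlier_magnitude * _random_unit_tangent(n, rng), M_trial
        )
        L_out = np.linalg.cholesky(M_out)
        n_spans = (T - span_len) // span_len + 1
        chosen = [i for i in range(n_spans) if rng.random() < p_out]
        # distraction hits isolated moments: outlier spans stay a strict
        # minority so the trial's central pattern remains dominant
        cap = max((n_spans - 1) // 2, 1)
        if len(chosen) > cap:
            chosen = sorted(rng.choice(chosen, size=cap, replace=False))
        for i in chosen:
            start = i * span_len
            X[:, start : start + span_len] = L_out @ rng.standard_normal(
                (n, span_len)
            )
            spans.append((start, start + span_len))

    trial = RawTrial(
        samples=X, rate=rate, label=label, trial_index=trial_index,
        run_index=run_index,
    )
    return trial, M_trial, spans


def generate_session(config: GeneratorConfig) -> tuple[Session, GroundTruth]:
    """A full multi-run session with drifting prototypes and shrinking tau."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    C0 = make_base_covariance(config.n_channels, config.ar_coeff)
    dirs = _class_directions(config.n_channels, rng)
    C0h = sym_powm(C0, 0.5)

    # fixed drift directions per class (also diagonal in the whitened frame,
    # drawn orthogonal to the class directions to keep separation stable)
    G = rng.standard_normal((config.n_channels, N_CLASSES))
    G -= dirs.T @ (dirs @ G)
    G /= np.linalg.norm(G, axis=0, keepdims=True)
    drift_dirs = G.T

    # exploitation concentrates exploration onto a preferred tangent axis;
    # the axis is shared by all classes (concentration reflects a settling
    # mental strategy, not class content) so a zero-separation session stays
    # uninformative about the labels
    preferred = _random_unit_tangent(config.n_channels, rng)

    truth = GroundTruth(
        prototypes=[], trial_means={}, outlier_spans={}, dispersions=[]
    )
    trials: list[RawTrial] = []
    tau = config.dispersion
    for r in range(config.n_runs):
        protos = [
            C0h
            @ np.diag(
                np.exp(config.separation * dirs[c] + r * config.drift * drift_dirs[c])
            )
            @ C0h
            for c in range(N_CLASSES)
        ]
        truth.prototypes.append(protos)
        truth.dispersions.append(tau)
        labels = np.repeat(np.arange(1, N_CLASSES + 1), config.trials_per_class)
        rng.shuffle(labels)
        # exploitation concentrates the trial means onto the class's
        # preferred axis (amplitude still varies, so between-trial variance
        # survives while its rank collapses)
        conc = 1.0 - config.exploitation ** (config.concentration * r)
        for j, label in enumerate(labels):
            R = _random_unit_tangent(config.n_channels, rng)
            a = rng.standard_normal()
            V = (1.0 - conc) * R + conc * a * preferred
            trial, M_trial, spans = generate_trial(
                protos[label - 1],
                tau,
                config.outlier_prob,
                rng,
                rate=config.rate,
                duration=config.trial_seconds,
                label=int(label),
                trial_index=j,
                run_index=r,
                outlier_magnitude=config.outlier_magnitude,
                direction=V,
            )
            trials.append(trial)
            truth.trial_means[(r, j)] = M_trial
            if spans:
                truth.outlier_spans[(r, j)] = spans
        tau *= config.exploitation

    session = Session(
        trials=trials,
        config=config.session_config(),
        seed=config.seed,
        preprocessing=["synthetic"],
    )
    return session, truth


# ---------------------------------------------------------------------------
# feedback-responsive user model
# ---------------------------------------------------------------------------


@dataclass
class UserState:
    """Exploration state of the simulated user.

    ``drift_directions`` holds one unit-Frobenius symmetric tangent matrix
    per class; a regime-change drift step of size s moves each prototype by
    exactly geodesic distance s along its direction.
    """

    dispersion: float
    prototypes: list[np.ndarray]
    drift_directions: list[np.ndarray]
    exploitation: float = 0.9
    regime: str = "constrained"
    drift_step: float = 0.1


def user_model_step(state: UserState, feedback_event: dict) -> UserState:
    """Advance the user model after one trial's feedback.

    Majority-correct feedback in a trial shrinks the dispersion by the
    exploitation factor gamma (the user repeats what worked); majority-
    incorrect feedback inflates it by 1/gamma (renewed exploration).  A
    feedback-regime change (constrained -> full) makes the prototypes take
    one drift step along their fixed directions (the user adjusts strategy).
    """
    new = replace(state, prototypes=[P.copy() for P in state.prototypes])
    regime = feedback_event.get("regime", state.regime)
    if regime != state.regime:
        new.prototypes = [
            exp_map(state.drift_step * V, P)
            for P, V in zip(new.prototypes, state.drift_directions)
        ]
        new.regime = regime
    if "majority_correct" in feedback_event:
        if feedback_event["majority_correct"]:
            new.dispersion = state.dispersion * state.exploitation
        else:
            new.dispersion = state.dispersion / state.exploitation
    return new
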