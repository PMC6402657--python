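"""EEG ingestion, preprocessing, segmentation and the internal session format.

The experimental protocol this package targets records 64-channel EEG
(60 analysis channels plus 4 EOG channels) at 1000 Hz, downsampled to
256 Hz, band-passed 8-70 Hz with a 5th-order Butterworth filter and notched
at 60 Hz.  A session holds 7 runs of 40 ten-second trials (10 per class,
4 classes); the online classifier predicts every 0.25 s on sliding 2 s
windows, so a 10 s trial yields 33 overlapping segments.

Readers for EDF and BrainVision recordings are thin wrappers over ``mne``
(optional dependency); sessions round-trip bit-exactly through an HDF5
container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "RawTrial",
    "Segment",
    "Session",
    "SessionConfig",
    "bandpass",
    "notch",
    "resample",
    "segment",
    "segment_session",
    "remove_eog_artifacts",
    "read_edf",
    "read_brainvision",
    "save_session",
    "load_session",
    "export_predictions_csv",
]

CLASS_LABELS = (1, 2, 3, 4)


@dataclass(frozen=True)
class SessionConfig:
    """Protocol constants of one recording session."""

    n_channels: int = 60
    n_eog: int = 4
    rate: float = 256.0
    n_runs: int = 7
    trials_per_class: int = 10
    n_classes: int = 4
    trial_seconds: float = 10.0
    window_seconds: float = 2.0
    step_seconds: float = 0.25

    @property
    def trials_per_run(self) -> int:
        return self.trials_per_class * self.n_classes

    @property
    def segments_per_trial(self) -> int:
        return (
            int(
                np.floor(
                    (self.trial_seconds - self.window_seconds) / self.step_seconds
                )
            )
            + 1
        )


@dataclass(frozen=True)
class RawTrial:
    """One labeled trial: (n_channels, n_samples) in microvolts."""

    samples: np.ndarray
    rate: float
    label: int
    trial_index: int
    run_index: int

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {self.label}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be (channels, time)")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.rate


@dataclass(frozen=True)
class Segment:
    """A 2 s analysis window; the atomic classified unit."""

    samples: np.ndarray
    rate: float
    label: int
    trial_index: int
    segment_index: int
    run_index: int


@dataclass
class Session:
    """All trials of a session, ordered run-by-run, plus provenance."""

    trials: list[RawTrial]
    config: SessionConfig = field(default_factory=SessionConfig)
    seed: int | None = None
    channel_names: list[str] | None = None
    preprocessing: list[str] = field(default_factory=list)

    def run(self, run_index: int) -> list[RawTrial]:
        return [t for t in self.trials if t.run_index == run_index]

    @property
    def n_runs(self) -> int:
        return max(t.run_index for t in self.trials) + 1


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _apply(trial: RawTrial, sos: np.ndarray, zero_phase: bool, tag: str) -> RawTrial:
    fn = sps.sosfiltfilt if zero_phase else sps.sosfilt
    out = fn(sos, trial.samples, axis=1)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"{tag} produced non-finite output (unstable design)")
    return replace(trial, samples=np.ascontiguousarray(out))


def bandpass(
    trial: RawTrial,
    low: float = 8.0,
    high: float = 70.0,
    order: int = 5,
    zero_phase: bool = True,
) -> RawTrial:
    """Butterworth band-pass; zero-phase for offline analysis, causal for replay."""
    if trial.rate <= 2 * high:
        raise ValueError(
            f"sampling rate {trial.rate} Hz too low for a {high} Hz band edge"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=trial.rate, output="sos")
    return _apply(trial, sos, zero_phase, "bandpass")


def notch(
    trial: RawTrial, freq: float = 60.0, q: float = 30.0, zero_phase: bool = True
) -> RawTrial:
    """IIR notch removing line noise at ``freq`` Hz."""
    if trial.rate <= 2 * freq:
        raise ValueError(f"sampling rate {trial.rate} Hz too low to notch {freq} Hz")
    b, a = sps.iirnotch(freq, q, fs=trial.rate)
    sos = sps.tf2sos(b, a)
    return _apply(trial, sos, zero_phase, "notch")


def resample(trial: RawTrial, target: float = 256.0, max_denominator: int = 1000) -> RawTrial:
    """Polyphase rational resampling (1000 -> 256 Hz is exactly 32/125)."""
    from fractions import Fraction

    if target >= trial.rate:
        raise ValueError("target rate must be below the current rate")
    frac = Fraction(target / trial.rate).limit_denominator(max_denominator)
    if abs(float(frac) - target / trial.rate) > 1e-9:
        raise ValueError(
            f"ratio {target}/{trial.rate} is not rational within the configured precision"
        )
    out = sps.resample_poly(
        trial.samples, frac.numerator, frac.denominator, axis=1, padtype="line"
    )
    return replace(trial, samples=np.ascontiguousarray(out), rate=float(target))


def remove_eog_artifacts(trial: RawTrial, method=None) -> RawTrial:
    """Hook for ocular-artifact removal.

    The pipeline is agnostic to the specific regression/subtraction scheme;
    pass a callable ``method(samples, rate) -> samples`` to plug one in.
    The default is an identity pass-through.
    """
    if method is None:
        return trial
    return replace(trial, samples=np.asarray(method(trial.samples, trial.rate)))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment(
    trial: RawTrial, window: float = 2.0, step: float = 0.25
) -> list[Segment]:
    """Sliding-window segmentation; every segment inherits the trial label.

    Windows advance by ``step`` seconds; a 10 s trial with the default
    2 s / 0.25 s settings yields 33 segments with 1.75 s overlap.
    """
    n = trial.samples.shape[1]
    wlen = int(round(window * trial.rate))
    slen = int(round(step * trial.rate))
    if wlen > n:
        raise ValueError("window longer than trial")
    n_seg = (n - wlen) // slen + 1
    return [
        Segment(
            samples=trial.samples[:, i * slen : i * slen + wlen],
            rate=trial.rate,
            label=trial.label,
            trial_index=trial.trial_index,
            segment_index=i + 1,
            run_index=trial.run_index,
        )
        for i in range(n_seg)
    ]


def segment_session(
    session: Session, run_index: int | None = None
) -> list[Segment]:
    cfg = session.config
    trials = session.trials if run_index is None else session.run(run_index)
    out: list[Segment] = []
    for t in trials:
        out.extend(segment(t, cfg.window_seconds, cfg.step_seconds))
    return out


# ---------------------------------------------------------------------------
# external readers (mne-backed)
# ---------------------------------------------------------------------------


def _epoch_raw(raw, event_id_map, trial_seconds, run_index, eog_prefix):
    import mne

    picks = [
        name for name in raw.ch_names if not name.upper().startswith(eog_prefix)
    ]
    events, ann_map = mne.events_from_annotations(raw, verbose="error")
    trials = []
    idx = 0
    rate = float(raw.info["sfreq"])
    n_keep = int(round(trial_seconds * rate))
    data = raw.get_data(picks=picks)
    for onset_sample, _, code in events:
        label = None
        for name, lab in event_id_map.items():
            if ann_map.get(name) == code:
                label = lab
        if label is None:
            continue
        chunk = data[:, onset_sample : onset_sample + n_keep]
        if chunk.shape[1] < n_keep:
            continue
        trials.append(
            RawTrial(
                samples=chunk * 1e6,  # mne uses volts
                rate=rate,
                label=label,
                trial_index=idx,
                run_index=run_index,
            )
        )
        idx += 1
    return trials


def read_edf(
    path,
    event_id_map: dict[str, int],
    trial_seconds: float = 10.0,
    run_index: int = 0,
    eog_prefix: str = "EOG",
) -> list[RawTrial]:
    """Read an EDF recording and cut labeled trials at its annotations.

    ``event_id_map`` maps annotation descriptions to class labels 1-4.
    Channels whose name starts with ``eog_prefix`` are excluded from the
    analysis montage.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return _epoch_raw(raw, event_id_map, trial_seconds, run_index, eog_prefix)


def read_brainvision(
    vhdr_path,
    event_id_map: dict[str, int],
    trial_seconds: float = 10.0,
    run_index: int = 0,
    eog_prefix: str = "EOG",
) -> list[RawTrial]:
    """Read a BrainVision (.vhdr/.eeg/.vmrk) recording into labeled trials."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    return _epoch_raw(raw, event_id_map, trial_seconds, run_index, eog_prefix)


# ---------------------------------------------------------------------------
# internal session format (HDF5)
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = (
    "n_channels",
    "n_eog",
    "rate",
    "n_runs",
    "trials_per_class",
    "n_classes",
    "trial_seconds",
    "window_seconds",
    "step_seconds",
)


def save_session(session: Session, path) -> None:
    """Write a session to HDF5; numeric payloads round-trip bit-exactly."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("config")
        for name in _CONFIG_FIELDS:
            g.attrs[name] = getattr(session.config, name)
        f.attrs["seed"] = -1 if session.seed is None else int(session.seed)
        f.attrs["preprocessing"] = "\n".join(session.preprocessing)
        if session.channel_names:
            f.attrs["channel_names"] = "\n".join(session.channel_names)
        trials = f.create_group("trials")
        for i, t in enumerate(session.trials):
            d = trials.create_dataset(f"{i:04d}", data=t.samples)
            d.attrs["rate"] = t.rate
            d.attrs["label"] = t.label
            d.attrs["trial_index"] = t.trial_index
            d.attrs["run_index"] = t.run_index


def load_session(path) -> Session:
    import h5py

    with h5py.File(path, "r") as f:
        cfg = SessionConfig(
            **{
                name: type(getattr(SessionConfig, name))(f["config"].attrs[name])
                for name in _CONFIG_FIELDS
            }
        )
        seed = int(f.attrs["seed"])
        trials = []
        for key in sorted(f["trials"].keys()):
            d = f["trials"][key]
            trials.append(
                RawTrial(
                    samples=d[()],
                    rate=float(d.attrs["rate"]),
                    label=int(d.attrs["label"]),
                    trial_index=int(d.attrs["trial_index"]),
                    run_index=int(d.attrs["run_index"]),
                )
            )
        names = f.attrs.get("channel_names")
        prep = f.attrs.get("preprocessing", "")
        return Session(
            trials=trials,
            config=cfg,
            seed=None if seed < 0 else seed,
            channel_names=names.split("\n") if names else None,
            preprocessing=prep.split("\n") if prep else [],
        )


def export_predictions_csv(records: list[dict], path) -> None:
    """Write per-segment prediction records (one dict per segment) as CSV."""
    import pandas as pd

    pd.DataFrame.from_records(records).to_csv(path, index=False)
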