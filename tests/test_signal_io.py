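"""Preprocessing filters, segmentation, readers and the session format."""

import struct

import numpy as np
import pytest

from riembci.signal_io import (
    RawTrial,
    Session,
    SessionConfig,
    bandpass,
    load_session,
    notch,
    read_brainvision,
    read_edf,
    remove_eog_artifacts,
    resample,
    save_session,
    segment,
    segment_session,
)


def sinusoid_trial(freq, rate=256.0, seconds=10.0, channels=2, label=1):
    t = np.arange(int(seconds * rate)) / rate
    x = np.sin(2 * np.pi * freq * t)
    return RawTrial(
        samples=np.tile(x, (channels, 1)), rate=rate, label=label,
        trial_index=0, run_index=0,
    )


def _steady_amplitude(trial):
    # ignore filter edge transients
    n = trial.samples.shape[1]
    return np.abs(trial.samples[0, n // 4 : 3 * n // 4]).max()


class TestBandpass:
    def test_midband_passes(self):
        out = bandpass(sinusoid_trial(20.0))
        assert _steady_amplitude(out) == pytest.approx(1.0, rel=0.05)

    def test_low_frequency_attenuated(self):
        out = bandpass(sinusoid_trial(4.0))
        assert _steady_amplitude(out) < 10 ** (-20 / 20)

    def test_dc_removed(self):
        trial = sinusoid_trial(20.0)
        dc = RawTrial(np.ones_like(trial.samples), trial.rate, 1, 0, 0)
        out = bandpass(dc)
        assert np.abs(out.samples).max() < 1e-3

    def test_rate_too_low(self):
        with pytest.raises(ValueError):
            bandpass(sinusoid_trial(10.0, rate=100.0))

    def test_causal_mode_stays_finite(self):
        out = bandpass(sinusoid_trial(20.0), zero_phase=False)
        assert np.all(np.isfinite(out.samples))


class TestNotch:
    def test_line_frequency_attenuated(self):
        out = notch(sinusoid_trial(60.0))
        assert _steady_amplitude(out) < 10 ** (-20 / 20)

    def test_neighbour_band_passes(self):
        out = notch(sinusoid_trial(30.0))
        assert _steady_amplitude(out) == pytest.approx(1.0, rel=0.05)

    def test_zero_in_zero_out(self):
        z = RawTrial(np.zeros((3, 2560)), 256.0, 2, 0, 0)
        assert np.all(notch(z).samples == 0)


class TestResample:
    def test_length_arithmetic_1000_to_256(self):
        trial = sinusoid_trial(10.0, rate=1000.0)
        out = resample(trial, 256.0)
        assert out.samples.shape[1] == 2560
        assert out.rate == 256.0

    def test_sinusoid_preserved(self):
        out = resample(sinusoid_trial(10.0, rate=1000.0), 256.0)
        t = np.arange(out.samples.shape[1]) / out.rate
        ref = np.sin(2 * np.pi * 10.0 * t)
        r = np.corrcoef(out.samples[0], ref)[0, 1]
        assert r > 0.999

    def test_constant_preserved(self):
        trial = RawTrial(np.full((2, 10000), 3.5), 1000.0, 1, 0, 0)
        out = resample(trial, 256.0)
        # anti-alias FIR leaves sub-0.1% passband ripple
        assert np.allclose(out.samples, 3.5, atol=1e-3)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample(sinusoid_trial(10.0, rate=256.0), 512.0)


class TestSegmentation:
    def test_ten_second_trial_yields_33_segments(self):
        segs = segment(sinusoid_trial(20.0))
        assert len(segs) == 33
        assert all(s.samples.shape[1] == 512 for s in segs)

    def test_two_second_trial_yields_one(self):
        segs = segment(sinusoid_trial(20.0, seconds=2.0))
        assert len(segs) == 1

    def test_windows_tile_the_trial_exactly(self):
        segs = segment(sinusoid_trial(20.0))
        step = int(0.25 * 256)
        starts = [(s.segment_index - 1) * step for s in segs]
        assert starts[0] == 0
        assert starts[-1] + 512 == 2560

    def test_labels_inherited(self):
        segs = segment(sinusoid_trial(20.0, label=3))
        assert {s.label for s in segs} == {3}

    def test_full_run_segment_counts(self, rng):
        # 40 trials (10 per class) -> 1320 segments, 330 per class
        trials = [
            RawTrial(rng.standard_normal((2, 2560)), 256.0, c, i, 0)
            for i, c in enumerate(np.repeat([1, 2, 3, 4], 10))
        ]
        session = Session(trials=trials, config=SessionConfig(n_channels=2))
        segs = segment_session(session, 0)
        assert len(segs) == 1320
        labels = np.array([s.label for s in segs])
        assert all((labels == c).sum() == 330 for c in (1, 2, 3, 4))

    def test_window_longer_than_trial(self):
        with pytest.raises(ValueError):
            segment(sinusoid_trial(20.0, seconds=1.0))


def test_eog_hook_default_is_identity(rng):
    trial = RawTrial(rng.standard_normal((4, 512)), 256.0, 1, 0, 0)
    out = remove_eog_artifacts(trial)
    np.testing.assert_array_equal(out.samples, trial.samples)
    halved = remove_eog_artifacts(trial, method=lambda x, rate: x / 2)
    np.testing.assert_allclose(halved.samples, trial.samples / 2)


def test_session_round_trip_bit_exact(rng, tmp_path):
    trials = [
        RawTrial(rng.standard_normal((3, 512)), 256.0, c, i, i // 4)
        for i, c in enumerate([1, 2, 3, 4, 1, 2, 3, 4])
    ]
    session = Session(
        trials=trials,
        config=SessionConfig(n_channels=3),
        seed=42,
        channel_names=["C3", "C4", "CZ"],
        preprocessing=["bandpass 8-70", "notch 60"],
    )
    path = tmp_path / "session.h5"
    save_session(session, path)
    back = load_session(path)
    assert back.seed == 42
    assert back.channel_names == ["C3", "C4", "CZ"]
    assert back.preprocessing == ["bandpass 8-70", "notch 60"]
    assert back.config == session.config
    assert len(back.trials) == len(trials)
    for a, b in zip(back.trials, trials):
        np.testing.assert_array_equal(a.samples, b.samples)
        assert (a.label, a.trial_index, a.run_index) == (
            b.label, b.trial_index, b.run_index,
        )


# ---------------------------------------------------------------------------
# external readers on synthetic files written at test time
# ---------------------------------------------------------------------------


def _write_edf(path, data, rate, annotations):
    """Minimal EDF+ writer (int16, one data record per second) for testing."""
    n_ch, n_samp = data.shape
    n_records = n_samp // int(rate)
    chans = [f"CH{i}" for i in range(n_ch)] + ["EDF Annotations"]
    phys_min, phys_max = -3000, 3000
    dig_min, dig_max = -32768, 32767
    ann_per_record = 60  # 2-byte samples reserved for the annotation channel

    header = bytearray()
    header += b"0".ljust(8)
    header += b"X".ljust(80)  # patient
    header += b"X".ljust(80)  # recording
    header += b"01.01.20".ljust(8) + b"00.00.00".ljust(8)
    n_total = len(chans)
    header += str(256 * (1 + n_total)).encode().ljust(8)
    header += b"EDF+C".ljust(44)
    header += str(n_records).encode().ljust(8)
    header += b"1".ljust(8)  # record duration (s)
    header += str(n_total).encode().ljust(4)
    for name in chans:
        header += name.encode().ljust(16)
    for _ in chans:
        header += b"".ljust(80)  # transducer
    for name in chans:
        header += (b"uV" if name != "EDF Annotations" else b"").ljust(8)
    for name in chans:
        header += str(phys_min).encode().ljust(8)
    for name in chans:
        header += str(phys_max).encode().ljust(8)
    for name in chans:
        header += str(dig_min).encode().ljust(8)
    for name in chans:
        header += str(dig_max).encode().ljust(8)
    for _ in chans:
        header += b"".ljust(80)  # prefiltering
    for name in chans:
        ns = int(rate) if name != "EDF Annotations" else ann_per_record
        header += str(ns).encode().ljust(8)
    for _ in chans:
        header += b"".ljust(32)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    body = bytearray()
    ann_iter = iter(annotations)
    pending = sorted(annotations, key=lambda a: a[0])
    for rec in range(n_records):
        sl = slice(rec * int(rate), (rec + 1) * int(rate))
        for ch in range(n_ch):
            dig = np.clip(
                np.round((data[ch, sl] - phys_min) * scale) + dig_min,
                dig_min, dig_max,
            ).astype("<i2")
            body += dig.tobytes()
        ann = f"+{rec}\x14\x14\x00".encode()
        for onset, text in pending:
            if rec <= onset < rec + 1:
                ann += f"+{onset}\x14{text}\x14\x00".encode()
        ann = ann.ljust(2 * ann_per_record, b"\x00")[: 2 * ann_per_record]
        body += ann
    path.write_bytes(bytes(header) + bytes(body))


def test_edf_reader_round_trip(rng, tmp_path):
    mne = pytest.importorskip("mne")
    rate = 128.0
    data = rng.standard_normal((3, int(rate) * 12)) * 40
    path = tmp_path / "rec.edf"
    _write_edf(path, data, rate, annotations=[(0, "left"), (6, "word")])
    trials = read_edf(
        path, {"left": 1, "word": 2}, trial_seconds=5.0, run_index=2
    )
    assert [t.label for t in trials] == [1, 2]
    assert all(t.samples.shape == (3, int(5 * rate)) for t in trials)
    assert trials[0].run_index == 2
    # EDF is 16-bit quantized: agreement to the quantization step
    np.testing.assert_allclose(
        trials[0].samples, data[:, : int(5 * rate)], atol=0.2
    )


def _write_brainvision(base, data, rate, markers):
    n_ch = data.shape[0]
    (base.with_suffix(".vhdr")).write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={base.name}.eeg\nMarkerFile={base.name}.vmrk\n"
        "DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={n_ch}\n"
        f"SamplingInterval={1e6 / rate:.0f}\n"
        "[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n"
        "[Channel Infos]\n"
        + "".join(
            f"Ch{i + 1}=CH{i},,1,µV\n" for i in range(n_ch)
        )
    )
    lines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        f"DataFile={base.name}.eeg",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for i, (sample, desc) in enumerate(markers, start=2):
        lines.append(f"Mk{i}=Stimulus,{desc},{sample + 1},1,0")
    (base.with_suffix(".vmrk")).write_text("\n".join(lines) + "\n")
    (base.parent / (base.name + ".eeg")).write_bytes(
        data.T.astype("<f4").tobytes()
    )


def test_brainvision_reader_round_trip(rng, tmp_path):
    mne = pytest.importorskip("mne")
    rate = 250.0
    data = rng.standard_normal((4, int(rate) * 10)) * 25
    base = tmp_path / "rec"
    _write_brainvision(
        base, data, rate, markers=[(0, "S  1"), (int(rate) * 4, "S  3")]
    )
    trials = read_brainvision(
        base.with_suffix(".vhdr"),
        {"Stimulus/S  1": 1, "Stimulus/S  3": 3},
        trial_seconds=3.0,
    )
    assert [t.label for t in trials] == [1, 3]
    np.testing.assert_allclose(
        trials[1].samples,
        data[:, int(rate) * 4 : int(rate) * 7],
        rtol=1e-5, atol=1e-4,
    )
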