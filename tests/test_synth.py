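"""Synthetic session generator: geometry, determinism, ground truth."""

import numpy as np
import pytest

from riembci.metrics import instability
from riembci.signal_io import segment, segment_session
from riembci.spd import (
    covariance_descriptor,
    karcher_mean,
    riemannian_distance,
)
from riembci.synth import (
    GeneratorConfig,
    UserState,
    generate_session,
    generate_trial,
    make_base_covariance,
    make_prototypes,
    user_model_step,
)

SMALL = dict(n_channels=8, trials_per_class=3, seed=5)


class TestPrototypes:
    def test_zero_separation_collapses_to_base(self):
        cfg = GeneratorConfig(separation=0.0, **SMALL)
        protos, _ = make_prototypes(cfg)
        C0 = make_base_covariance(cfg.n_channels, cfg.ar_coeff)
        for P in protos:
            np.testing.assert_allclose(P, C0, atol=1e-10)

    def test_pairwise_distances_are_separation_times_sqrt2(self):
        cfg = GeneratorConfig(separation=0.8, **SMALL)
        protos, _ = make_prototypes(cfg)
        for i in range(4):
            for j in range(i + 1, 4):
                d = riemannian_distance(protos[i], protos[j])
                assert d == pytest.approx(0.8 * np.sqrt(2), rel=1e-8)

    def test_seed_determinism(self):
        cfg = GeneratorConfig(separation=0.5, **SMALL)
        p1, _ = make_prototypes(cfg)
        p2, _ = make_prototypes(cfg)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a, b)

    def test_negative_separation_rejected(self):
        with pytest.raises(ValueError):
            make_prototypes(GeneratorConfig(separation=-1.0, **SMALL))


class TestGenerateTrial:
    def test_long_trial_covariance_converges_to_prototype(self):
        rng = np.random.default_rng(0)
        cfg = GeneratorConfig(**SMALL)
        protos, _ = make_prototypes(GeneratorConfig(separation=0.6, **SMALL))
        trial, M, spans = generate_trial(
            protos[0], tau=0.0, p_out=0.0, rng=rng, rate=256.0,
            duration=400.0,  # ~1e5 samples
        )
        C = covariance_descriptor(trial.samples)
        assert riemannian_distance(C, protos[0]) < 0.1
        assert spans == []
        np.testing.assert_array_equal(M, protos[0])

    def test_outlier_segments_are_farthest_from_trial_mean(self):
        # in >= 90% of trials with implanted outliers, the segment farthest
        # from the trial Karcher mean overlaps an outlier span
        protos, _ = make_prototypes(GeneratorConfig(separation=0.5, **SMALL))
        rng = np.random.default_rng(3)
        hits = trials = 0
        while trials < 15:
            trial, M, spans = generate_trial(
                protos[0], tau=0.1, p_out=0.3, rng=rng
            )
            if not spans:
                continue
            trials += 1
            segs = segment(trial)
            covs = [covariance_descriptor(s.samples) for s in segs]
            mu = karcher_mean(covs, max_iter=100)
            d = np.array([riemannian_distance(C, mu) for C in covs])
            flagged = [
                i
                for i, s in enumerate(segs)
                if any(
                    lo < (s.segment_index - 1) * 64 + 512
                    and (s.segment_index - 1) * 64 < hi
                    for lo, hi in spans
                )
            ]
            if int(np.argmax(d)) in flagged:
                hits += 1
        assert hits / trials >= 0.9

    def test_fixed_rng_reproduces_bits(self):
        protos, _ = make_prototypes(GeneratorConfig(separation=0.5, **SMALL))
        t1, _, _ = generate_trial(protos[1], 0.2, 0.0, np.random.default_rng(9))
        t2, _, _ = generate_trial(protos[1], 0.2, 0.0, np.random.default_rng(9))
        np.testing.assert_array_equal(t1.samples, t2.samples)


class TestGenerateSession:
    def test_bitwise_determinism(self):
        cfg = GeneratorConfig(n_runs=2, separation=0.5, **SMALL)
        s1, g1 = generate_session(cfg)
        s2, g2 = generate_session(cfg)
        for a, b in zip(s1.trials, s2.trials):
            np.testing.assert_array_equal(a.samples, b.samples)
            assert a.label == b.label

    def test_balanced_segment_counts_per_class(self):
        cfg = GeneratorConfig(
            n_channels=4, n_runs=1, trials_per_class=10, separation=0.5, seed=2
        )
        session, _ = generate_session(cfg)
        segs = segment_session(session, 0)
        assert len(segs) == 1320
        labels = np.array([s.label for s in segs])
        for c in (1, 2, 3, 4):
            assert (labels == c).sum() == 330

    def test_dispersion_shrinks_geometrically(self):
        cfg = GeneratorConfig(
            n_runs=4, dispersion=0.4, exploitation=0.8, separation=0.5, **SMALL
        )
        _, truth = generate_session(cfg)
        np.testing.assert_allclose(
            truth.dispersions, 0.4 * 0.8 ** np.arange(4)
        )

    def test_no_drift_keeps_prototypes_fixed(self):
        cfg = GeneratorConfig(
            n_runs=3, drift=0.0, exploitation=1.0, separation=0.5, **SMALL
        )
        _, truth = generate_session(cfg)
        for c in range(4):
            for r in (1, 2):
                assert riemannian_distance(
                    truth.prototypes[0][c], truth.prototypes[r][c]
                ) < 1e-10

    def test_drift_moves_prototypes_by_configured_step(self):
        cfg = GeneratorConfig(
            n_runs=3, drift=0.15, exploitation=1.0, separation=0.5, **SMALL
        )
        _, truth = generate_session(cfg)
        for c in range(4):
            d = riemannian_distance(
                truth.prototypes[0][c], truth.prototypes[1][c]
            )
            assert d == pytest.approx(0.15, rel=1e-8)

    def test_class_mean_recovery_from_generated_run(self):
        # Karcher means of per-class segment covariances recover the true
        # prototypes within geodesic distance 0.2 (averaged over seeds)
        dists = []
        for seed in range(3):
            cfg = GeneratorConfig(
                n_channels=8, trials_per_class=5, n_runs=1,
                separation=0.8, dispersion=0.15, seed=seed,
            )
            session, truth = generate_session(cfg)
            segs = segment_session(session, 0)
            for c in (1, 2, 3, 4):
                covs = [
                    covariance_descriptor(s.samples)
                    for s in segs
                    if s.label == c
                ]
                mu = karcher_mean(covs, max_iter=100)
                dists.append(
                    riemannian_distance(mu, truth.prototypes[0][c - 1])
                )
        assert np.mean(dists) < 0.2

    def test_exploitation_reduces_instability_across_runs(self):
        # gamma < 1 concentrates exploration: class instability is
        # non-increasing from the first to the last run on average over seeds
        deltas = []
        for seed in range(3):
            cfg = GeneratorConfig(
                n_channels=8, trials_per_class=10, n_runs=4, separation=0.6,
                dispersion=2.5, exploitation=0.85, drift=0.0, seed=seed,
            )
            session, _ = generate_session(cfg)
            for c in (1, 2, 3, 4):
                ks = []
                for r in (0, 3):
                    covs = [
                        covariance_descriptor(s.samples)
                        for s in segment_session(session, r)
                        if s.label == c
                    ]
                    ks.append(instability(covs))
                deltas.append(ks[1] - ks[0])
        assert np.mean(deltas) <= 0


class TestUserModel:
    def _state(self):
        protos, _ = make_prototypes(GeneratorConfig(separation=0.5, **SMALL))
        rng = np.random.default_rng(1)
        dirs = []
        for _ in range(4):
            V = rng.standard_normal((8, 8))
            V = 0.5 * (V + V.T)
            dirs.append(V / np.linalg.norm(V))
        return UserState(
            dispersion=0.4, prototypes=protos, drift_directions=dirs,
            exploitation=0.8, drift_step=0.12,
        )

    def test_three_correct_trials_shrink_tau_cubed(self):
        state = self._state()
        for _ in range(3):
            state = user_model_step(state, {"majority_correct": True})
        assert state.dispersion == pytest.approx(0.4 * 0.8**3)

    def test_alternating_feedback_cancels(self):
        state = self._state()
        for flag in (True, False, True, False):
            state = user_model_step(state, {"majority_correct": flag})
        assert state.dispersion == pytest.approx(0.4)

    def test_regime_change_moves_prototypes_by_drift_step(self):
        state = self._state()
        before = [P.copy() for P in state.prototypes]
        state = user_model_step(state, {"regime": "full"})
        for P0, P1 in zip(before, state.prototypes):
            assert riemannian_distance(P0, P1) == pytest.approx(0.12, rel=1e-6)
        # a second event in the same regime does not move them again
        state2 = user_model_step(state, {"regime": "full"})
        for P1, P2 in zip(state.prototypes, state2.prototypes):
            np.testing.assert_allclose(P1, P2)
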