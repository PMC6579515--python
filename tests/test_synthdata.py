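"""Ground-truth properties of the synthetic-session generator."""

import numpy as np
import pytest
from scipy.special import i0, i1

from thetalink.core import ParameterError
from thetalink.spectral import pooled_coherence
from thetalink.synthdata import (
    SessionSpec,
    generate_behavior,
    generate_coherent_pair,
    generate_phase_locked_spikes,
    generate_session,
)

FS = 1000.0


class TestCoherentPair:
    def test_target_one_is_scaled_copy(self):
        x, y = generate_coherent_pair(int(60 * FS), FS, 1.0, seed=0)
        f, c, _ = pooled_coherence(x, y)
        assert np.nanmin(c[(f > 1) & (f < 400)]) > 0.999

    def test_target_zero_sits_at_bias_floor(self):
        from thetalink.spectral import coherence_bias_floor

        x, y = generate_coherent_pair(int(300 * FS), FS, 0.0, seed=1)
        f, c, dof = pooled_coherence(x, y)
        sel = (f > 1) & (f < 400)
        assert abs(c[sel].mean() - coherence_bias_floor(dof)) < 0.02

    def test_half_target_in_theta_band(self):
        x, y = generate_coherent_pair(600000, FS, 0.5, seed=1)
        f, c, _ = pooled_coherence(x, y)
        sel = (f >= 6) & (f <= 12)
        assert abs(c[sel].mean() - 0.5) < 0.03

    def test_unit_variance_channels(self):
        x, y = generate_coherent_pair(int(120 * FS), FS, 0.5, seed=2)
        assert abs(x.values.var() - 1.0) < 0.01
        assert abs(y.values.var() - 1.0) < 0.01

    def test_invalid_target_rejected(self):
        with pytest.raises(ParameterError):
            generate_coherent_pair(10000, FS, 1.2, seed=0)


class TestBehaviorGeneration:
    def test_homecage_has_no_rewards_and_straddles_threshold(self):
        spec = SessionSpec(duration=300.0, behavior_mode="homecage", seed=3)
        tracking, rewards = generate_behavior(spec)
        assert len(rewards) == 0
        from thetalink.behavior import compute_speed

        sp = compute_speed(tracking)
        frac_fast = np.nanmean(sp.values > 3.0)
        assert 0.2 < frac_fast < 0.8

    def test_rewards_only_in_goal_zones(self):
        spec = SessionSpec(duration=300.0, behavior_mode="linear_track", seed=4)
        tracking, rewards = generate_behavior(spec)
        assert len(rewards) >= 2
        x_at = np.interp(rewards.times, tracking.times, tracking.x)
        in_lo = (x_at >= 10.0) & (x_at <= 15.0 + 1.0)
        in_hi = (x_at >= 85.0 - 1.0) & (x_at <= 90.0)
        assert np.all(in_lo | in_hi)

    def test_positions_stay_on_track(self):
        spec = SessionSpec(duration=300.0, behavior_mode="linear_track", seed=5)
        tracking, _ = generate_behavior(spec)
        assert tracking.x.min() >= 0.0 and tracking.x.max() <= 100.0

    def test_goal_directed_collects_more_rewards_than_exploratory(self):
        wins = 0
        for seed in range(50):
            goal = SessionSpec(duration=120.0, behavior_mode="linear_track",
                               speed_profile="goal_directed", seed=seed)
            expl = SessionSpec(duration=120.0, behavior_mode="linear_track",
                               speed_profile="exploratory", seed=seed)
            n_goal = len(generate_behavior(goal)[1])
            n_expl = len(generate_behavior(expl)[1])
            wins += n_goal > n_expl
        assert wins >= 40  # clear majority ordering


class TestPhaseLockedSpikes:
    def _phase_series(self, n, seed=0):
        # uniformly advancing 8 Hz phase
        return (2 * np.pi * 8.0 * np.arange(n) / FS) % (2 * np.pi) - np.pi

    def test_kappa_zero_is_homogeneous(self):
        phase = self._phase_series(int(300 * FS))
        train = generate_phase_locked_spikes(phase, FS, 20.0, 0.0, 0.0, seed=6)
        phases = phase[np.round(train.times * FS).astype(int).clip(0, phase.size - 1)]
        R = np.abs(np.mean(np.exp(1j * phases)))
        assert R < 0.05
        assert abs(len(train) / 300.0 - 20.0) < 1.5

    def test_resultant_matches_von_mises_closed_form(self):
        phase = self._phase_series(int(600 * FS))
        kappa = 5.0
        train = generate_phase_locked_spikes(phase, FS, 10.0, kappa, 1.0, seed=7)
        phases = phase[np.round(train.times * FS).astype(int).clip(0, phase.size - 1)]
        R = np.abs(np.mean(np.exp(1j * phases)))
        assert abs(R - i1(kappa) / i0(kappa)) < 0.05

    def test_mean_angle_recovery(self):
        phase = self._phase_series(int(600 * FS))
        mu = np.deg2rad(231.0)
        train = generate_phase_locked_spikes(phase, FS, 10.0, 2.0, mu, seed=8)
        phases = phase[np.round(train.times * FS).astype(int).clip(0, phase.size - 1)]
        ang = np.angle(np.mean(np.exp(1j * phases)))
        delta = np.rad2deg(np.angle(np.exp(1j * (ang - mu))))
        assert abs(delta) < 10.0

    def test_rate_scales_linearly(self):
        phase = self._phase_series(int(600 * FS))
        n1 = len(generate_phase_locked_spikes(phase, FS, 5.0, 1.0, 0.0, seed=9))
        n2 = len(generate_phase_locked_spikes(phase, FS, 10.0, 1.0, 0.0, seed=10))
        assert abs(n2 / n1 - 2.0) < 0.1

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            generate_phase_locked_spikes(np.zeros(100), FS, -1.0, 0.0, 0.0, seed=0)


class TestGenerateSession:
    def test_unit_variance_before_line_and_artifacts(self):
        spec = SessionSpec(duration=120.0, seed=12, line_noise_amplitude=0.0,
                           artifact_rate=0.0)
        bundle, _ = generate_session(spec)
        for tr in bundle.signals.values():
            assert abs(tr.values.var() - 1.0) < 0.01

    def test_coherence_target_ordering_across_seeds(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = SessionSpec(
                duration=120.0,
                seed=100 + seed,
                coherence_targets={("hpc_l", "crus1"): 0.5, ("hpc_l", "lob23"): 0.46},
                channels=[("hpc_l", "hippocampus_left"), ("crus1", "crusI"),
                          ("lob23", "lobII_III")],
            )
            bundle, _ = generate_session(spec)
            f, c1, _ = pooled_coherence(bundle.signals["hpc_l"], bundle.signals["crus1"])
            _, c2, _ = pooled_coherence(bundle.signals["hpc_l"], bundle.signals["lob23"])
            sel = (f >= 6) & (f <= 12)
            hits += c1[sel].mean() > c2[sel].mean()
        assert hits >= 19  # >= 95% of seeds

    def test_zero_targets_at_bias_floor(self):
        from thetalink.spectral import coherence_bias_floor

        spec = SessionSpec(duration=240.0, seed=14, line_noise_amplitude=0.0)
        bundle, _ = generate_session(spec)
        f, c, dof = pooled_coherence(bundle.signals["hpc_l"], bundle.signals["crus1"])
        sel = (f > 1) & (f < 45)
        assert abs(c[sel].mean() - coherence_bias_floor(dof)) < 0.05

    def test_line_noise_present_at_50hz(self):
        from thetalink.core import SignalTrace
        from thetalink.spectral import multitaper_spectrogram

        spec = SessionSpec(duration=60.0, seed=15, line_noise_amplitude=0.5)
        bundle, _ = generate_session(spec)
        sp = multitaper_spectrogram(bundle.signals["hpc_l"], step=1.0)
        mean = sp.values.mean(axis=0)
        at50 = mean[np.argmin(np.abs(sp.freqs - 50.0))]
        at40 = mean[np.argmin(np.abs(sp.freqs - 40.0))]
        assert at50 > 10 * at40

    def test_infeasible_cereb_cereb_target_rejected(self):
        spec = SessionSpec(
            duration=10.0,
            seed=16,
            coherence_targets={
                ("hpc_l", "crus1"): 0.5,
                ("hpc_l", "lob6"): 0.5,
                ("crus1", "lob6"): 0.9,  # star topology implies 0.25
            },
        )
        with pytest.raises(ParameterError):
            generate_session(spec)

    def test_determinism_per_seed(self):
        spec_a = SessionSpec(duration=30.0, seed=17, artifact_rate=1.0)
        spec_b = SessionSpec(duration=30.0, seed=17, artifact_rate=1.0)
        ba, _ = generate_session(spec_a)
        bb, _ = generate_session(spec_b)
        for lab in ba.signals:
            np.testing.assert_array_equal(ba.signals[lab].values, bb.signals[lab].values)
        np.testing.assert_array_equal(ba.tracking.x, bb.tracking.x)
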