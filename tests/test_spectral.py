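"""Multitaper estimators: oracles, limits, bias structure, summaries."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from thetalink.core import (
    BandDefinition,
    DistanceProfile,
    IntervalSet,
    ParameterError,
    SignalTrace,
)
from thetalink.spectral import (
    average_hemispheres,
    band_series,
    coherence_bias_floor,
    mask_line_band,
    multitaper_coherogram,
    multitaper_spectrogram,
    pool_profile,
    pooled_coherence,
    zscore_power_spectrum,
)
from thetalink.synthdata import generate_coherent_pair

FS = 1000.0
THETA = BandDefinition("theta", 6.0, 12.0)


class TestSpectrogram:
    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(0)
        tr = SignalTrace(rng.normal(size=int(600 * FS)), FS)
        spec = multitaper_spectrogram(tr, step=1.0)
        mean = spec.values.mean(axis=0)
        sel = (spec.freqs >= 1) & (spec.freqs <= 300)
        ratio = mean[sel] / mean[sel].mean()
        assert np.all(np.abs(ratio - 1.0) < 0.10)

    def test_sinusoid_peak_location_and_leakage(self):
        t = np.arange(int(30 * FS)) / FS
        tr = SignalTrace(np.sin(2 * np.pi * 8.0 * t), FS)
        spec = multitaper_spectrogram(tr, step=1.0)
        mean = spec.values.mean(axis=0)
        peak_bin = int(np.argmax(mean))
        assert abs(spec.freqs[peak_bin] - 8.0) <= 1.0
        bin20 = int(np.argmin(np.abs(spec.freqs - 20.0)))
        assert 10 * np.log10(mean[peak_bin] / mean[bin20]) >= 20.0

    def test_parseval_total_power_matches_variance(self):
        rng = np.random.default_rng(1)
        tr = SignalTrace(rng.normal(size=int(60 * FS)), FS)
        spec = multitaper_spectrogram(tr, step=1.0)
        df = spec.freqs[1] - spec.freqs[0]
        total = spec.values.sum(axis=1).mean() * df
        assert abs(total - 1.0) < 0.10

    def test_excluded_windows_are_nan(self):
        rng = np.random.default_rng(2)
        tr = SignalTrace(rng.normal(size=int(20 * FS)), FS)
        excl = IntervalSet.from_pairs([(5.0, 7.0)])
        spec = multitaper_spectrogram(tr, exclude=excl)
        dropped = ~spec.valid_mask
        centers = spec.window_centers
        should_drop = (centers > 4.5) & (centers < 7.5)
        assert np.all(dropped[should_drop])
        assert not np.any(dropped[(centers < 4.0) | (centers > 8.0)])

    def test_exclusion_bookkeeping_exact(self):
        """Spectrogram of clean segments equals segment spectrograms."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=int(20 * FS))
        tr = SignalTrace(x, FS)
        excl = IntervalSet.from_pairs([(8.0, 12.0)])
        spec = multitaper_spectrogram(tr, exclude=excl, step=1.0)
        first = SignalTrace(x[: int(8 * FS)], FS)
        spec_first = multitaper_spectrogram(first, step=1.0)
        keep = spec.window_centers < 7.6
        np.testing.assert_allclose(
            spec.values[keep], spec_first.values[: keep.sum()], rtol=1e-10
        )

    def test_window_longer_than_trace_rejected(self):
        from thetalink.core import DegenerateInputError

        with pytest.raises(DegenerateInputError):
            multitaper_spectrogram(SignalTrace(np.zeros(100), FS))


class TestCoherence:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(4)
        tr = SignalTrace(rng.normal(size=int(30 * FS)), FS)
        cohg = multitaper_coherogram(tr, tr)
        assert np.nanmax(np.abs(cohg.values - 1.0)) < 1e-8

    @pytest.mark.parametrize("target", [0.2, 0.5, 0.8])
    def test_pooled_estimate_matches_mixing_oracle(self, target):
        x, y = generate_coherent_pair(int(600 * FS), FS, target, seed=int(target * 10))
        f, c, dof = pooled_coherence(x, y)
        sel = (f >= 6) & (f <= 12)
        assert abs(c[sel].mean() - target) < 0.03

    def test_independent_pair_sits_at_analytic_floor(self):
        x, _ = generate_coherent_pair(int(600 * FS), FS, 0.0, seed=21)
        _, y = generate_coherent_pair(int(600 * FS), FS, 0.0, seed=22)
        f, c, dof = pooled_coherence(x, y)
        sel = (f >= 2) & (f <= 100)
        assert abs(c[sel].mean() - coherence_bias_floor(dof)) < 0.05

    def test_bias_decreases_with_degrees_of_freedom(self):
        """Independent signals: longer pooling window -> lower mean estimate."""
        x, _ = generate_coherent_pair(int(240 * FS), FS, 0.0, seed=31)
        _, y = generate_coherent_pair(int(240 * FS), FS, 0.0, seed=32)
        means = {}
        for win in (1.0, 2.0):
            f, c, _ = pooled_coherence(x, y, window=win, step=4.0)
            means[win] = c[(f >= 2) & (f <= 100)].mean()
        assert means[2.0] < means[1.0]

    def test_per_window_floor_matches_four_taper_bias(self):
        """Mean of the per-window coherogram for independent inputs sits at
        the K=4 magnitude bias floor (~0.457) - the scale of the study's
        baseline coherence values."""
        x, _ = generate_coherent_pair(int(120 * FS), FS, 0.0, seed=41)
        _, y = generate_coherent_pair(int(120 * FS), FS, 0.0, seed=42)
        cohg = multitaper_coherogram(x, y, step=1.0)
        sel = (cohg.freqs >= 2) & (cohg.freqs <= 100)
        mean = np.nanmean(cohg.values[:, sel])
        assert abs(mean - coherence_bias_floor(4)) < 0.03

    def test_amplitude_scaling_invariance(self):
        x, y = generate_coherent_pair(int(60 * FS), FS, 0.5, seed=5)
        c1 = multitaper_coherogram(x, y).values
        c2 = multitaper_coherogram(x.with_values(3.5 * x.values), y).values
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_zero_lag_mixture_invisible_to_imaginary_coherency(self):
        rng = np.random.default_rng(6)
        n = int(300 * FS)
        t = np.arange(n) / FS
        shared = np.sin(2 * np.pi * 8.0 * t + rng.uniform(0, 2 * np.pi))
        a = SignalTrace(shared + rng.normal(scale=0.5, size=n), FS)
        b = SignalTrace(shared + rng.normal(scale=0.5, size=n), FS)
        f, mag, _ = pooled_coherence(a, b, mode="magnitude")
        _, imag, _ = pooled_coherence(a, b, mode="imaginary")
        at8 = np.argmin(np.abs(f - 8.0))
        assert mag[at8] > 0.7
        assert abs(imag[at8]) < 0.05

    def test_welch_cross_check(self):
        """Independent estimator (scipy Welch coherence) agrees on the
        frequency-flat mixing construction."""
        x, y = generate_coherent_pair(int(300 * FS), FS, 0.6, seed=7)
        f, cxy = sp_signal.coherence(x.values, y.values, fs=FS, nperseg=1024)
        sel = (f >= 4) & (f <= 40)
        assert abs(np.sqrt(cxy[sel]).mean() - 0.6) < 0.04
        fp, cp, _ = pooled_coherence(x, y)
        selp = (fp >= 4) & (fp <= 40)
        assert abs(cp[selp].mean() - np.sqrt(cxy[sel]).mean()) < 0.04

    def test_rate_mismatch_rejected(self):
        a = SignalTrace(np.zeros(2000), 1000.0)
        b = SignalTrace(np.zeros(2000), 500.0)
        with pytest.raises(ParameterError):
            multitaper_coherogram(a, b)


class TestSummaries:
    def test_band_series_tracks_am_envelope(self):
        t = np.arange(int(60 * FS)) / FS
        env = 1.0 + 0.8 * np.sin(2 * np.pi * 0.05 * t)
        tr = SignalTrace(env * np.sin(2 * np.pi * 8.0 * t), FS)
        spec = multitaper_spectrogram(tr)
        series = band_series(spec, THETA)
        env_at = np.interp(series.times, t, env) ** 2
        r = np.corrcoef(series.values, env_at)[0, 1]
        assert r >= 0.8
        assert series.sample_rate == pytest.approx(10.0)

    def test_band_series_constant_map(self):
        tf = multitaper_spectrogram(
            SignalTrace(np.random.default_rng(8).normal(size=int(5 * FS)), FS)
        )
        const = tf.copy_with(np.ones_like(tf.values))
        out = band_series(const, THETA)
        np.testing.assert_allclose(out.values, 1.0)

    def test_band_outside_axis_rejected(self):
        tf = multitaper_spectrogram(
            SignalTrace(np.random.default_rng(9).normal(size=int(5 * FS)), FS),
            max_freq=50.0,
        )
        with pytest.raises(ParameterError):
            band_series(tf, BandDefinition("high", 200.0, 300.0))

    def test_zscore_spectrum_scale_invariant_and_flat_zero(self):
        freqs = np.linspace(0.5, 400, 200)
        spec = 1.0 / freqs
        _, z1 = zscore_power_spectrum(freqs, spec)
        _, z2 = zscore_power_spectrum(freqs, 7.3 * spec)
        np.testing.assert_allclose(z1, z2, atol=1e-9)
        _, zf = zscore_power_spectrum(freqs, np.ones_like(freqs))
        np.testing.assert_allclose(zf, 0.0)

    def test_zscore_theta_peak_beats_gamma_for_hippocampal_shape(self):
        from thetalink.synthdata import lfp_spectral_shape

        freqs = np.linspace(0.5, 400, 800)
        power = lfp_spectral_shape(freqs) ** 2
        zf, z = zscore_power_spectrum(freqs, power)
        z_theta = z[np.argmin(np.abs(zf - 8.0))]
        z_30 = z[np.argmin(np.abs(zf - 30.0))]
        assert z_theta > z_30

    def test_mask_line_band_idempotent_and_local(self):
        tf = multitaper_spectrogram(
            SignalTrace(np.random.default_rng(10).normal(size=int(5 * FS)), FS)
        )
        once = mask_line_band(tf)
        twice = mask_line_band(once)
        sel = (tf.freqs >= 48) & (tf.freqs <= 52)
        assert np.all(np.isnan(once.values[:, sel]))
        np.testing.assert_array_equal(once.values[:, ~sel], tf.values[:, ~sel])
        np.testing.assert_array_equal(
            np.isnan(twice.values), np.isnan(once.values)
        )

    def test_pool_profile_identity_and_weighted_oracle(self):
        rng = np.random.default_rng(11)
        centers = np.arange(-99.5, 0.0, 1.0)
        occ = rng.uniform(0.0, 3.0, centers.size)
        const = DistanceProfile(centers, np.full(centers.size, 0.7), occ)
        assert pool_profile(const) == pytest.approx(0.7)
        vals = rng.normal(size=centers.size)
        prof = DistanceProfile(centers, vals, occ)
        sel = (centers >= -60) & (centers <= -20) & (occ > 0)
        expected = np.average(vals[sel], weights=occ[sel])
        assert pool_profile(prof) == pytest.approx(expected)

    def test_pool_profile_empty_window_is_nan(self):
        centers = np.arange(-10.5, 0.0, 1.0)
        prof = DistanceProfile(centers, np.ones(centers.size), np.ones(centers.size))
        assert np.isnan(pool_profile(prof, distance_window=(-90, -80)))

    def test_average_hemispheres_rules(self):
        assert average_hemispheres(0.4, 0.6) == pytest.approx(0.5)
        assert average_hemispheres(None, 0.6) == pytest.approx(0.6)
        assert average_hemispheres(0.4, None) == pytest.approx(0.4)
        assert average_hemispheres(None, None) is None
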