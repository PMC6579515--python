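"""Speed derivation, active-movement epochs, run segmentation, binning."""

import numpy as np
import pytest

from thetalink.behavior import (
    bin_by_distance,
    compute_speed,
    detect_active_epochs,
    distance_at_times,
    segment_runs,
)
from thetalink.core import (
    DegenerateInputError,
    EventSeries,
    IntervalSet,
    SignalTrace,
    TrackingTrace,
)

TRACK_RATE = 30.0


def _tracking(x, y=None, rate=TRACK_RATE):
    x = np.asarray(x, dtype=float)
    times = np.arange(x.size) / rate
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return TrackingTrace(times=times, x=x, y=y, source_rate=rate)


def brute_force_epochs(values, rate, threshold, min_duration, t0=0.0):
    """Per-sample scan oracle for sustained-speed epochs."""
    out = []
    start = None
    for i, v in enumerate(list(values) + [-np.inf]):
        if not np.isnan(v) and v > threshold:
            if start is None:
                start = i
        else:
            if start is not None:
                if (i - start) / rate >= min_duration:
                    out.append((t0 + start / rate, t0 + i / rate))
                start = None
    return IntervalSet.from_pairs(out)


class TestComputeSpeed:
    def test_stationary_is_zero(self):
        sp = compute_speed(_tracking(np.full(600, 12.0)))
        assert np.nanmax(sp.values) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_motion_recovered(self):
        x = 5.0 * np.arange(900) / TRACK_RATE
        sp = compute_speed(_tracking(x))
        mid = sp.values[5:-5]
        assert np.all(np.abs(mid - 5.0) < 0.1)

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(0)
        steps = rng.normal(0.0, 0.2, 3000)
        x = np.cumsum(steps)
        tr = _tracking(x)
        sp = compute_speed(tr, smooth_s=0.5)
        # oracle: same smoothing, central difference at tracking rate,
        # sampled on the 10 Hz grid
        k = int(round(0.5 * TRACK_RATE))
        kern = np.ones(k) / k
        pad = np.concatenate([np.full(k // 2, x[0]), x, np.full(k - 1 - k // 2, x[-1])])
        xs = np.convolve(pad, kern, mode="valid")
        vx = np.gradient(xs, tr.times)
        expected = np.interp(sp.times, tr.times, np.abs(vx))
        np.testing.assert_allclose(sp.values, expected, atol=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_speed(_tracking(np.array([1.0])))


class TestActiveEpochs:
    def test_constant_fast_speed_spans_trace(self):
        sp = SignalTrace(np.full(7200, 5.0), 10.0)
        epochs = detect_active_epochs(sp)
        assert list(epochs) == [(0.0, 720.0)]

    def test_just_below_min_duration_excluded(self):
        v = np.zeros(200)
        v[50:89] = 5.0  # 3.9 s at 10 Hz
        assert len(detect_active_epochs(SignalTrace(v, 10.0))) == 0
        v[50:90] = 5.0  # exactly 4.0 s
        assert len(detect_active_epochs(SignalTrace(v, 10.0))) == 1

    def test_matches_brute_force_scan_on_random_traces(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            v = rng.exponential(3.0, size=rng.integers(50, 400))
            sp = SignalTrace(v, 10.0)
            fast = detect_active_epochs(sp, threshold=3.0, min_duration=1.0)
            oracle = brute_force_epochs(v, 10.0, 3.0, 1.0)
            assert fast == oracle

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        v = rng.exponential(3.0, size=600)
        sp = SignalTrace(v, 10.0)
        low = detect_active_epochs(sp, threshold=2.0, min_duration=2.0)
        high = detect_active_epochs(sp, threshold=4.0, min_duration=2.0)
        # every interval found at the high threshold is covered at the low one
        assert high.intersect(low) == high


class TestSegmentRuns:
    def _back_and_forth(self, n_traversals=6, speed=20.0):
        rate = TRACK_RATE
        lo, hi = 12.5, 87.5
        xs, rewards = [], []
        pos, target, direction = lo, hi, 1
        t = 0.0
        while len(rewards) < n_traversals:
            xs.append(pos)
            pos += direction * speed / rate
            t += 1.0 / rate
            if (direction > 0 and pos >= target) or (direction < 0 and pos <= target):
                rewards.append(t)
                direction *= -1
                target = lo if target == hi else hi
        xs = np.asarray(xs)
        return _tracking(xs), EventSeries("reward", np.asarray(rewards))

    def test_run_count_is_rewards_minus_one(self):
        tracking, rewards = self._back_and_forth(6)
        runs = segment_runs(tracking, rewards)
        assert len(runs) == len(rewards) - 1

    def test_distance_is_negative_and_ends_near_zero(self):
        tracking, rewards = self._back_and_forth(5)
        runs = segment_runs(tracking, rewards)
        for run in runs:
            assert np.all(run.distance <= 0.0)
            assert -1.0 < run.distance[-1] <= 0.0
            assert np.all(run.distance >= -100.0)

    def test_turnaround_flagged_but_kept(self):
        rate = TRACK_RATE
        # out, halfway back, then on to the far goal
        seg1 = np.linspace(12.5, 60.0, 80)
        seg2 = np.linspace(60.0, 40.0, 40)
        seg3 = np.linspace(40.0, 87.5, 90)
        x = np.concatenate([[12.5], seg1, seg2, seg3])
        tracking = _tracking(x)
        t_end = (x.size - 1) / rate
        rewards = EventSeries("reward", np.array([0.0, t_end]))
        runs = segment_runs(tracking, rewards)
        assert len(runs) == 1
        assert not runs[0].monotonic

    def test_no_rewards_gives_no_runs(self):
        tracking, _ = self._back_and_forth(4)
        assert segment_runs(tracking, EventSeries("reward", np.empty(0))) == []


class TestBinByDistance:
    def _runs_and_series(self, seed=3):
        rng = np.random.default_rng(seed)
        tracking, rewards = TestSegmentRuns()._back_and_forth(8, speed=25.0)
        runs = segment_runs(tracking, rewards)
        t_end = tracking.times[-1]
        grid = np.arange(0.05, t_end, 0.1)
        series = SignalTrace(rng.normal(size=grid.size), 10.0, t0=float(grid[0]))
        return runs, series

    def test_constant_series_gives_constant_profile(self):
        runs, series = self._runs_and_series()
        const = series.with_values(np.ones(series.n))
        prof = bin_by_distance(const, runs)
        occupied = prof.occupancy > 0
        np.testing.assert_allclose(prof.values[occupied], 1.0)

    def test_occupancy_conserves_run_time(self):
        runs, series = self._runs_and_series()
        prof = bin_by_distance(series, runs)
        run_total = sum(r.times[-1] - r.times[0] for r in runs)
        assert abs(prof.occupancy.sum() - run_total) <= 2 * 0.1  # one grid sample per end

    def test_matches_groupby_oracle(self):
        runs, series = self._runs_and_series()
        prof = bin_by_distance(series, runs, bin_width=1.0)
        dist = distance_at_times(runs, series.times)
        ok = ~np.isnan(dist)
        for i, c in enumerate(prof.bin_centers):
            sel = ok & (dist >= c - 0.5) & (dist < c + 0.5)
            if sel.any():
                assert prof.values[i] == pytest.approx(series.values[sel].mean())
            else:
                assert np.isnan(prof.values[i]) or prof.occupancy[i] == 0

    def test_binning_independent_of_run_order(self):
        runs, series = self._runs_and_series()
        prof1 = bin_by_distance(series, runs)
        prof2 = bin_by_distance(series, list(reversed(runs)))
        np.testing.assert_allclose(prof1.values, prof2.values, equal_nan=True)
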