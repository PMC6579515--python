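"""Speed, active-movement epochs, linear-track runs and distance binning.

Active movement is a sustained speed above 3 cm/s for at least 4 s.  On the
linear track each traversal between consecutive rewards is a run; series on
the 10 Hz analysis grid are averaged by distance from the upcoming reward
in 1 cm bins, normalized by occupancy (time spent per bin), with the reward
at 0 cm and approach distances negative.
"""

from __future__ import annotations

import numpy as np

from .core import (
    DegenerateInputError,
    DistanceProfile,
    EventSeries,
    IntervalSet,
    RunSegment,
    SignalTrace,
    TrackingTrace,
)

__all__ = [
    "compute_speed",
    "detect_active_epochs",
    "segment_runs",
    "bin_by_distance",
    "distance_at_times",
]


def compute_speed(
    tracking: TrackingTrace,
    out_rate: float = 10.0,
    smooth_s: float = 0.5,
    t_grid: np.ndarray | None = None,
) -> SignalTrace:
    """Instantaneous speed (cm/s) resampled onto the 10 Hz analysis grid.

    Positions are smoothed with a 0.5 s moving average before central
    differencing (tracker jitter at 30 Hz otherwise inflates speed), then
    speed is linearly interpolated onto ``t_grid`` (or a uniform grid at
    ``out_rate`` spanning the tracking).
    """
    if tracking.times.size < 2:
        raise DegenerateInputError("need >= 2 tracking samples for speed")
    times = tracking.times
    dt = np.median(np.diff(times))
    k = max(1, int(round(smooth_s / dt)))
    kern = np.ones(k) / k

    def smooth(v):
        if k == 1:
            return v
        pad = np.concatenate([np.full(k // 2, v[0]), v, np.full(k - 1 - k // 2, v[-1])])
        return np.convolve(pad, kern, mode="valid")

    xs, ys = smooth(tracking.x), smooth(tracking.y)
    vx = np.gradient(xs, times)
    vy = np.gradient(ys, times)
    sp = np.hypot(vx, vy)
    if t_grid is None:
        t_grid = np.arange(times[0], times[-1], 1.0 / out_rate)
    out = np.interp(t_grid, times, sp, left=np.nan, right=np.nan)
    rate = out_rate if t_grid.size < 2 else 1.0 / float(np.median(np.diff(t_grid)))
    return SignalTrace(out, sample_rate=rate, t0=float(t_grid[0]), label="speed", units="cm/s")


def detect_active_epochs(
    speed: SignalTrace, threshold: float = 3.0, min_duration: float = 4.0
) -> IntervalSet:
    """Maximal intervals where speed exceeds threshold at every sample for
    at least ``min_duration`` (the sustained-movement inclusion rule).

    "Sustained" is read strictly: a single sub-threshold sample breaks an
    epoch (no dip tolerance by default).
    """
    above = speed.values > threshold
    above &= ~np.isnan(speed.values)
    runs = IntervalSet.from_boolean(above, speed.sample_rate, t0=speed.t0)
    keep = [(s, e) for s, e in runs if (e - s) >= min_duration]
    return IntervalSet.from_pairs(keep)


def _along_track(tracking: TrackingTrace) -> np.ndarray:
    # 1-D track: along-track coordinate is x
    return tracking.x


def segment_runs(
    tracking: TrackingTrace,
    rewards: EventSeries,
    track_length: float = 100.0,
    goal_offset: float = 10.0,
    goal_width: float = 5.0,
) -> list[RunSegment]:
    """Split a linear-track session into reward-to-reward runs.

    One RunSegment per inter-reward traversal; direction is the sign of the
    net displacement, and the distance series is the (negative) along-track
    distance remaining to the rewarded goal position.  Runs containing a
    mid-track turnaround are retained but flagged non-monotonic, matching
    the inclusion of exploratory early-training runs.
    """
    if len(rewards) < 2:
        return []
    pos = _along_track(tracking)
    t = tracking.times
    runs: list[RunSegment] = []
    for t_start, t_end in zip(rewards.times[:-1], rewards.times[1:]):
        sel = (t > t_start) & (t <= t_end)
        if sel.sum() < 2:
            continue
        seg_t, seg_x = t[sel], pos[sel]
        net = seg_x[-1] - seg_x[0]
        direction = 1 if net >= 0 else -1
        goal = float(seg_x[-1])  # position at reward delivery
        signed = -np.abs(goal - seg_x)
        # turnaround = cumulative retracement against the run direction
        # beyond tracker jitter (2 cm)
        progress = direction * seg_x
        drawdown = np.max(np.maximum.accumulate(progress) - progress)
        monotonic = bool(drawdown <= 2.0)
        runs.append(
            RunSegment(
                interval=(float(t_start), float(t_end)),
                direction=direction,
                reward_time=float(t_end),
                times=seg_t,
                distance=signed,
                monotonic=monotonic,
            )
        )
    return runs


def distance_at_times(runs: list[RunSegment], t_grid: np.ndarray) -> np.ndarray:
    """Signed distance-to-upcoming-reward at arbitrary grid times.

    Grid points outside every run are NaN.  Within a run the tracking-rate
    distance series is linearly interpolated.
    """
    out = np.full(np.asarray(t_grid, dtype=float).shape, np.nan)
    t_grid = np.asarray(t_grid, dtype=float)
    for run in runs:
        sel = (t_grid >= run.times[0]) & (t_grid <= run.times[-1])
        if sel.any():
            out[sel] = np.interp(t_grid[sel], run.times, run.distance)
    return out


def bin_by_distance(
    series: SignalTrace,
    runs: list[RunSegment],
    bin_width: float = 1.0,
    max_distance: float | None = None,
) -> DistanceProfile:
    """Occupancy-normalized distance profile of a 10 Hz series.

    Each grid sample inside a run contributes its value to the 1 cm bin
    containing its distance-to-reward, weighted by the grid dwell time;
    the profile value is the time-weighted mean, and ``occupancy`` is the
    summed dwell time per bin.  Zero-occupancy bins are NaN.
    """
    t_grid = series.times
    dist = distance_at_times(runs, t_grid)
    ok = ~np.isnan(dist) & ~np.isnan(series.values)
    dt = 1.0 / series.sample_rate
    if max_distance is None:
        max_distance = float(np.nanmin(dist)) if ok.any() else -bin_width
    edges = np.arange(np.floor(max_distance / bin_width) * bin_width, 0.0 + bin_width, bin_width)
    centers = edges[:-1] + bin_width / 2.0
    idx = np.digitize(dist[ok], edges) - 1
    valid = (idx >= 0) & (idx < centers.size)
    idx = idx[valid]
    vals = series.values[ok][valid]
    occ = np.bincount(idx, minlength=centers.size) * dt
    sums = np.bincount(idx, weights=vals, minlength=centers.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(occ > 0, sums * dt / np.where(occ > 0, occ, 1.0), np.nan)
    return DistanceProfile(
        bin_centers=centers, values=mean, occupancy=occ, freqs=None, label=series.label
    )
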