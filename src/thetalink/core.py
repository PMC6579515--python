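"""Shared in-memory containers for the analysis pipeline.

All times are seconds from the session origin; intervals are half-open
``[start, end)`` so that masks tile without double counting.  Signals are
uniformly sampled; behavioral streams carry explicit time stamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SignalTrace",
    "IntervalSet",
    "TrackingTrace",
    "EventSeries",
    "SpikeTrain",
    "TimeFrequencyMap",
    "BandDefinition",
    "DistanceProfile",
    "RunSegment",
    "SessionBundle",
    "ParameterError",
    "FormatError",
    "DegenerateInputError",
]


class ParameterError(ValueError):
    """A caller-supplied parameter is outside its valid domain."""


class FormatError(ValueError):
    """An on-disk stream violates the session layout contract."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but too short/constant for the operation."""


@dataclass
class SignalTrace:
    """One uniformly sampled continuous signal (LFP, EMG, or speed)."""

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("SignalTrace values must be 1-D")
        if not self.sample_rate > 0:
            raise ParameterError("sample_rate must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sample_rate

    def with_values(self, values: np.ndarray, units: str | None = None) -> "SignalTrace":
        return SignalTrace(
            values=np.asarray(values, dtype=float),
            sample_rate=self.sample_rate,
            t0=self.t0,
            label=self.label,
            units=self.units if units is None else units,
        )


def _merge_pairs(pairs: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/abutting half-open intervals."""
    if pairs.size == 0:
        return np.empty((0, 2), dtype=float)
    order = np.argsort(pairs[:, 0], kind="stable")
    pairs = pairs[order]
    merged = [list(pairs[0])]
    for start, end in pairs[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.asarray(merged, dtype=float)


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, disjoint, half-open time intervals used as inclusion/exclusion masks.

    Supports the boolean algebra needed for epoch bookkeeping: union,
    intersection, and complement within a span.  Construction always
    normalizes (sorts, drops empties, merges overlaps), so any two sets
    describing the same point set compare equal.
    """

    intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        arr = arr[arr[:, 1] > arr[:, 0]]
        object.__setattr__(self, "intervals", _merge_pairs(arr))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "IntervalSet":
        return cls(np.asarray(list(pairs), dtype=float).reshape(-1, 2))

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls()

    @classmethod
    def span(cls, start: float, end: float) -> "IntervalSet":
        return cls.from_pairs([(start, end)])

    @classmethod
    def from_boolean(cls, mask: np.ndarray, sample_rate: float, t0: float = 0.0) -> "IntervalSet":
        """Intervals covering the True runs of a per-sample boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size == 0 or not mask.any():
            return cls.empty()
        padded = np.concatenate(([False], mask, [False]))
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        pairs = np.stack([t0 + run_starts / sample_rate, t0 + run_ends / sample_rate], axis=1)
        return cls(pairs)

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals.shape == other.intervals.shape and np.allclose(
            self.intervals, other.intervals
        )

    @property
    def total_duration(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(np.vstack([self.intervals, other.intervals]))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        for a0, a1 in self.intervals:
            lo = np.searchsorted(other.intervals[:, 1], a0, side="right")
            for b0, b1 in other.intervals[lo:]:
                if b0 >= a1:
                    break
                s, e = max(a0, b0), min(a1, b1)
                if e > s:
                    out.append((s, e))
        return IntervalSet.from_pairs(out)

    def complement(self, start: float, end: float) -> "IntervalSet":
        """Complement of the set within ``[start, end)``."""
        out = []
        cursor = start
        for a0, a1 in self.intervals:
            if a1 <= start:
                continue
            if a0 >= end:
                break
            if a0 > cursor:
                out.append((cursor, min(a0, end)))
            cursor = max(cursor, a1)
        if cursor < end:
            out.append((cursor, end))
        return IntervalSet.from_pairs(out)

    def contains_times(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside the set (half-open)."""
        times = np.asarray(times, dtype=float)
        if len(self) == 0:
            return np.zeros(times.shape, dtype=bool)
        idx = np.searchsorted(self.intervals[:, 0], times, side="right") - 1
        inside = idx >= 0
        inside[inside] &= times[inside] < self.intervals[idx[inside], 1]
        return inside

    def overlaps_window(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean mask: which half-open windows [start, end) intersect the set."""
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        if len(self) == 0:
            return np.zeros(starts.shape, dtype=bool)
        # window overlaps some interval iff an interval starts before the window
        # ends and ends after the window starts
        i = np.searchsorted(self.intervals[:, 0], ends, side="left") - 1
        hit = i >= 0
        hit[hit] &= self.intervals[i[hit], 1] > starts[hit]
        return hit


@dataclass
class TrackingTrace:
    """Animal position samples (x, y in cm) at the tracker rate."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    source_rate: float = 30.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.times.size == self.x.size == self.y.size):
            raise ParameterError("tracking arrays must share length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise FormatError("tracking times must be strictly increasing")


@dataclass
class EventSeries:
    """Sorted point events (rewards, MFB stimulations, light onsets)."""

    name: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size >= 2 and np.any(np.diff(self.times) < 0):
            raise FormatError(f"event times for '{self.name}' must be sorted")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit (sorting is upstream of this pipeline)."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise FormatError(f"spike times for unit '{self.unit_id}' must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ParameterError(f"band '{self.name}': need 0 < f_lo < f_hi")


#: canonical band table: delta 2-4, theta 6-12, beta 13-29, low gamma 30-48 Hz
DEFAULT_BANDS = {
    "delta": BandDefinition("delta", 2.0, 4.0),
    "theta": BandDefinition("theta", 6.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 29.0),
    "low_gamma": BandDefinition("low_gamma", 30.0, 48.0),
}


@dataclass
class TimeFrequencyMap:
    """Window-center x frequency matrix of power or coherence.

    ``values`` is (n_windows, n_freqs); NaN marks windows dropped by
    exclusion masks.  ``kind`` tags the quantity: ``power``, ``coherence``,
    ``imaginary_coherency``.
    """

    window_centers: np.ndarray
    freqs: np.ndarray
    values: np.ndarray
    window_s: float
    step_s: float
    n_tapers: int
    kind: str = "power"

    def __post_init__(self) -> None:
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.window_centers.size, self.freqs.size):
            raise ParameterError("TimeFrequencyMap shape mismatch")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.all(np.isnan(self.values), axis=1)

    def copy_with(self, values: np.ndarray, kind: str | None = None) -> "TimeFrequencyMap":
        return TimeFrequencyMap(
            window_centers=self.window_centers.copy(),
            freqs=self.freqs.copy(),
            values=values,
            window_s=self.window_s,
            step_s=self.step_s,
            n_tapers=self.n_tapers,
            kind=self.kind if kind is None else kind,
        )


@dataclass
class DistanceProfile:
    """Per-(distance-bin, frequency) values with occupancy, reward at 0 cm.

    ``bin_centers`` are negative approaching the reward.  ``freqs`` is None
    for single-band profiles (``values`` is then 1-D).  Bins with zero
    occupancy hold NaN.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    occupancy: np.ndarray
    freqs: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != self.bin_centers.shape:
            raise ParameterError("occupancy must align with bin_centers")
        if np.any(self.occupancy < 0):
            raise ParameterError("occupancy must be nonnegative")


@dataclass
class RunSegment:
    """One reward-to-reward traversal of the linear track."""

    interval: tuple[float, float]
    direction: int  # +1 toward increasing x, -1 toward decreasing x
    reward_time: float
    times: np.ndarray  # tracking-rate times within the run
    distance: np.ndarray  # signed cm to the upcoming reward (<= 0)
    monotonic: bool = True  # False when the run contains a turnaround

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)


@dataclass
class SessionBundle:
    """Everything recorded in one session, on a common time origin."""

    signals: dict[str, SignalTrace] = field(default_factory=dict)
    tracking: TrackingTrace | None = None
    events: dict[str, EventSeries] = field(default_factory=dict)
    spikes: dict[str, SpikeTrain] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def channel_roles(self) -> dict[str, str]:
        return dict(self.metadata.get("channel_roles", {}))

    def channels_with_role(self, *roles: str) -> list[str]:
        wanted = set(roles)
        return [label for label, role in self.channel_roles.items() if role in wanted]
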