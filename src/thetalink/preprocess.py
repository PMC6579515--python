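"""LFP conditioning: standardize, 50 Hz notch, local-linear detrend, masks.

Order of application in the pipeline is standardize -> notch -> detrend,
then artifact detection on the conditioned trace.  Artifact removal and
peri-stimulation exclusion are expressed as :class:`IntervalSet` masks that
downstream spectral windows are checked against, so dropping masked data
never shifts the time base.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal

from .core import (
    DegenerateInputError,
    EventSeries,
    IntervalSet,
    ParameterError,
    SignalTrace,
)

__all__ = [
    "standardize",
    "notch_filter",
    "detrend_local_linear",
    "detect_artifact_intervals",
    "build_exclusion_mask",
    "preprocess_lfp",
]


def standardize(trace: SignalTrace) -> SignalTrace:
    """Z-score a trace over its full duration (mean 0, variance 1)."""
    if trace.n < 2:
        raise DegenerateInputError("need >= 2 samples to standardize")
    sd = trace.values.std()
    if sd == 0:
        raise DegenerateInputError(f"constant trace '{trace.label}' cannot be z-scored")
    return trace.with_values((trace.values - trace.values.mean()) / sd, units="z")


def notch_filter(trace: SignalTrace, center: float = 50.0, quality: float = 30.0) -> SignalTrace:
    """Zero-phase narrow band-stop at the electrical line frequency.

    An IIR notch applied forward-backward (filtfilt) so the phase response
    is identically zero; quality factor 30 keeps the -3 dB stop band under
    2 Hz wide, leaving theta (8 Hz) and 100 Hz gains within 1% of unity.
    """
    if center >= trace.sample_rate / 2:
        raise ParameterError("notch center must be below Nyquist")
    b, a = sp_signal.iirnotch(center, quality, fs=trace.sample_rate)
    return trace.with_values(sp_signal.filtfilt(b, a, trace.values))


def detrend_local_linear(trace: SignalTrace, window: float = 1.0, step: float = 0.5) -> SignalTrace:
    """Remove the slow DC component by moving-window linear regression.

    Within each 1 s window (advanced in 0.5 s steps) an ordinary least
    squares line is fitted and subtracted; residuals of overlapping windows
    are blended with a triangular cross-fade so the output is continuous.
    A globally linear input maps to ~0 everywhere.
    """
    fs = trace.sample_rate
    wlen = int(round(window * fs))
    stp = int(round(step * fs))
    n = trace.n
    if n < wlen:
        raise DegenerateInputError("trace shorter than one detrending window")
    x = trace.values
    t = np.arange(wlen, dtype=float)
    t_mean = t.mean()
    t_c = t - t_mean
    denom = np.sum(t_c**2)
    tri = np.bartlett(wlen + 2)[1:-1]  # strictly positive triangular weights

    starts = list(range(0, max(n - wlen, 0) + 1, stp))
    if starts[-1] != n - wlen:
        starts.append(n - wlen)  # cover the tail
    acc = np.zeros(n)
    wsum = np.zeros(n)
    for s in starts:
        seg = x[s : s + wlen]
        slope = np.dot(t_c, seg) / denom
        resid = seg - (seg.mean() + slope * t_c)
        acc[s : s + wlen] += resid * tri
        wsum[s : s + wlen] += tri
    return trace.with_values(acc / wsum)


def detect_artifact_intervals(
    trace: SignalTrace,
    band: tuple[float, float] = (0.5, 5.0),
    z_threshold: float = 4.0,
    window: float = 1.0,
    step: float = 0.1,
    n_tapers: int = 4,
) -> IntervalSet:
    """Flag windows with large low-frequency transients.

    The mean multitaper power in the 0.5-5 Hz band is computed per sliding
    window, z-scored across time, and windows above ``z_threshold`` are
    returned (full window extents, merged).  The z-scoring uses robust
    location/scale (median and 1.4826*MAD) so that the artifacts being
    hunted cannot inflate the scale and mask one another.  The default
    threshold of 4 is conservative: only large-amplitude events are removed.
    """
    from .spectral import multitaper_spectrogram  # local import avoids cycle

    spec = multitaper_spectrogram(
        trace, window=window, step=step, n_tapers=n_tapers, max_freq=band[1] + 5.0
    )
    sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    power = spec.values[:, sel].mean(axis=1)
    med = np.median(power)
    sd = 1.4826 * np.median(np.abs(power - med))
    if sd == 0:
        sd = power.std()
    if sd == 0:
        return IntervalSet.empty()
    z = (power - med) / sd
    hot = z > z_threshold
    if not hot.any():
        return IntervalSet.empty()
    half = window / 2.0
    pairs = [
        (c - half, c + half) for c, h in zip(spec.window_centers, hot) if h
    ]
    return IntervalSet.from_pairs(pairs)


def build_exclusion_mask(
    events: EventSeries, pad: float = 0.5, total: IntervalSet | None = None
) -> IntervalSet:
    """Peri-event exclusion: union of [t-pad, t+pad) per event.

    Used for the +/-0.5 s windows around MFB reward stimulations; the
    result is intersected with ``total`` (the session span) when given.
    """
    mask = IntervalSet.from_pairs([(t - pad, t + pad) for t in events.times])
    if total is not None:
        mask = mask.intersect(total)
    return mask


def preprocess_lfp(
    trace: SignalTrace,
    notch_center: float = 50.0,
    notch_q: float = 30.0,
    detrend_window: float = 1.0,
    detrend_step: float = 0.5,
) -> SignalTrace:
    """Standard conditioning chain: z-score, 50 Hz notch, local-linear detrend."""
    out = standardize(trace)
    out = notch_filter(out, center=notch_center, quality=notch_q)
    return detrend_local_linear(out, window=detrend_window, step=detrend_step)
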