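"""Bootstrap shuffle nulls for speed correlations and distribution shape.

The speed-correlation test follows the study's resampling scheme: the
observed statistic is the Spearman rank correlation between an
instantaneous band series (power or coherence) and instantaneous speed on
the shared 10 Hz grid; the null is built by recomputing the correlation
against 1000 random rearrangements of the speed values, and the confidence
limits are the 0.025/0.975 empirical quantiles of that null.

A full permutation treats samples as exchangeable; for autocorrelated
series this understates the null spread, so a block shuffle is offered as
an option (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .core import DegenerateInputError, IntervalSet, SignalTrace

__all__ = [
    "CorrelationBootstrapResult",
    "ShapeSummary",
    "speed_correlation_bootstrap",
    "distribution_shape",
]


@dataclass
class CorrelationBootstrapResult:
    rho_observed: float
    null_values: np.ndarray
    lower: float
    upper: float
    significant: bool
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower limit exceeds upper limit")


@dataclass
class ShapeSummary:
    skewness: float
    normality_p: float
    modality_note: str
    histogram: tuple[np.ndarray, np.ndarray]


def _rank(v: np.ndarray) -> np.ndarray:
    return sp_stats.rankdata(v, method="average")


def _pearson_of_ranks(ra: np.ndarray, rb: np.ndarray) -> float:
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))


def speed_correlation_bootstrap(
    series: SignalTrace,
    speed: SignalTrace,
    mask: IntervalSet | None = None,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    block_s: float | None = None,
    min_samples: int = 40,
) -> CorrelationBootstrapResult:
    """Spearman correlation with a shuffled-speed null.

    ``mask`` restricts the comparison to active-movement samples.  The null
    permutes the masked speed vector wholesale (``block_s`` switches to a
    circular block shuffle that preserves autocorrelation within blocks).
    Significance: the observed rho falls outside the [alpha/2, 1-alpha/2]
    null quantiles.
    """
    if series.values.size != speed.values.size:
        raise DegenerateInputError("series and speed must share the 10 Hz grid")
    keep = ~np.isnan(series.values) & ~np.isnan(speed.values)
    if mask is not None:
        keep &= mask.contains_times(series.times)
    a = series.values[keep]
    b = speed.values[keep]
    if a.size < min_samples:
        raise DegenerateInputError(f"only {a.size} retained samples (< {min_samples})")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant series or speed: correlation undefined")

    ra, rb = _rank(a), _rank(b)
    rho = _pearson_of_ranks(ra, rb)

    rng = np.random.default_rng(seed)
    n = rb.size
    ra_c = ra - ra.mean()
    ra_c /= np.sqrt(ra_c @ ra_c)
    null = np.empty(n_shuffles)
    # vectorized permutation null: rho* = <ra_c, perm(rb_c)>
    rb_c = rb - rb.mean()
    rb_c /= np.sqrt(rb_c @ rb_c)
    if block_s is None:
        for i in range(n_shuffles):
            null[i] = ra_c @ rb_c[rng.permutation(n)]
    else:
        blk = max(1, int(round(block_s * series.sample_rate)))
        n_blocks = int(np.ceil(n / blk))
        for i in range(n_shuffles):
            order = rng.permutation(n_blocks)
            shift = rng.integers(n)
            rolled = np.roll(rb_c, shift)
            pieces = [rolled[j * blk : (j + 1) * blk] for j in order]
            null[i] = ra_c @ np.concatenate(pieces)[:n]
    lower, upper = np.quantile(null, [alpha / 2.0, 1.0 - alpha / 2.0])
    return CorrelationBootstrapResult(
        rho_observed=rho,
        null_values=null,
        lower=float(lower),
        upper=float(upper),
        significant=bool(rho < lower or rho > upper),
        n_samples=int(n),
        seed=seed,
    )


def distribution_shape(values: np.ndarray, n_bins: int = 30) -> ShapeSummary:
    """Sample skewness (adjusted Fisher-Pearson), Shapiro-Wilk normality p,
    and a histogram summary for descriptive modality inspection."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 8:
        raise DegenerateInputError("need >= 8 values for a shape summary")
    skew = float(sp_stats.skew(v, bias=False))
    # Shapiro-Wilk p is unreliable above n~5000; subsample deterministically
    sub = v if v.size <= 5000 else v[:: max(1, v.size // 5000)][:5000]
    normality_p = float(sp_stats.shapiro(sub).pvalue)
    counts, edges = np.histogram(v, bins=n_bins)
    interior = counts[1:-1]
    n_modes = int(
        np.sum(
            (interior > np.maximum(counts[:-2], counts[2:]))
            & (interior > 0.1 * counts.max())
        )
    )
    note = "unimodal" if n_modes <= 1 else f"{n_modes} local modes"
    return ShapeSummary(skewness=skew, normality_p=normality_p, modality_note=note,
                        histogram=(counts, edges))
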