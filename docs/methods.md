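# Methods

This note documents the models, estimators and design choices behind the
package, what the synthetic-data generator does and does not emulate, and
the numerical conventions that affect results.

## Signal conditioning

LFP traces are processed in the order **z-score → 50 Hz notch →
local-linear detrend**.

* Standardization is over the whole trace (mean 0, variance 1); constant
  traces are a degenerate-input error.
* The notch is an IIR band-stop at 50 Hz with quality factor 30, applied
  forward–backward (zero phase). With these settings the attenuation at
  50 Hz exceeds 30 dB after the two passes while the gain at 8 Hz and
  100 Hz stays within 1% of unity. Because the notch leaves a spectral
  scar, the 48–52 Hz band is masked (NaN) in all coherence products before
  any band averaging; the low-gamma band deliberately ends at 48 Hz.
* Detrending fits an ordinary-least-squares line in a 1 s window advanced
  in 0.5 s steps and subtracts it; residuals of overlapping windows are
  blended with a triangular cross-fade, which makes the output continuous
  and reproduces the plain OLS residual exactly when the trace is a single
  window. A globally linear input maps to ~0.

**Artifact exclusion.** Large low-frequency transients are found by
z-scoring the mean multitaper power in the 0.5–5 Hz band across time
(1 s / 0.1 s / 4-taper spectrogram) and flagging windows above z = 4. The
z-scoring uses robust location and scale (median, 1.4826·MAD): with plain
mean/SD a handful of very large artifacts inflate the scale enough to mask
one another, which we verified directly on injected bursts. The threshold
default of 4 is deliberately conservative — only "large-amplitude" events
are removed — and is configurable. Reward (MFB) stimulation times are
excluded with a ±0.5 s pad. Exclusion is implemented as half-open interval
sets; any analysis window that overlaps an excluded interval is dropped
whole, never truncated, so removing masked windows cannot change the
values computed from the remaining ones (verified by a concatenation
test).

## Multitaper estimation

All spectral quantities use a 1 s sliding window in 0.1 s steps with
K = 4 DPSS tapers at time–bandwidth NW = 2.5, following the K = 2·NW − 1
convention of the standard electrophysiology toolboxes. Power is scaled as
a one-sided density so the frequency integral matches the windowed
variance (Parseval check in the tests).

Coherence is reported as the **magnitude** of coherency, not the squared
magnitude. The package exposes both behind a switch, but magnitude is the
default because the per-window magnitude floor for independent signals at
K = 4, E|Ĉ| = (√π/2)·Γ(K)/Γ(K+½) ≈ 0.457, matches the scale of baseline
session coherence values produced by this windowing convention; squared
coherence would put the floor at 1/K = 0.25.

Two coherence read-outs coexist deliberately:

* **Per-window coherogram** — 4 degrees of freedom per window; heavily
  positively biased for weak coupling; its band average on the 10 Hz
  window grid is the "instantaneous coherence" series, and its time mean
  is the session-scale coherence. These values must only be compared
  against each other (same bias), never read as absolute coupling.
* **Pooled coherence** — cross- and auto-spectra averaged over all
  retained (default non-overlapping) windows and tapers, then normalized.
  With N pooled estimates the independence floor decays as √(π/4N) and
  the estimator converges on the population coherence; this is the
  read-out the mixing oracle validates to ±0.03 at targets 0.2/0.5/0.8.

The imaginary part of coherency is computed with the same machinery. For
any zero-lag mixture it is ~0 in expectation, while magnitude coherence is
inflated by the shared source; the per-window |Im C| series has its own
noise floor (comparable to the magnitude floor), so only the pooled
imaginary coherency should be used as a quantitative volume-conduction
control.

Spectra averaged over windows are z-scored **across frequency bins** in
the 0.1–500 Hz range (not per-frequency across time). This removes global
scale differences between animals and regions; a strong theta oscillation
then appears as a z ≈ 4–6 peak over the 1/f background, which the
hippocampus-like synthetic spectrum reproduces.

## Behavior

Speed is derived from 30 Hz position tracking: positions are smoothed with
a 0.5 s moving average (tracker jitter otherwise inflates the
finite-difference speed), differentiated, and interpolated onto the 10 Hz
spectrogram window-center grid so that speed, band power and band
coherence share one time base. Active movement is speed > 3 cm/s sustained
for ≥ 4 s, with "sustained" read strictly — a single sub-threshold sample
breaks the epoch; a dip-tolerance parameter exists but defaults to 0.

On the linear track, a run is the interval between consecutive rewards.
Direction is the sign of net displacement; the distance series is the
negative along-track distance to the position where the next reward was
delivered (0 at the reward, negative on approach). Runs containing a
turnaround (cumulative retracement > 2 cm against the run direction) are
flagged but retained, since early-training exploratory runs are part of
the analysis. Distance binning is occupancy-normalized: each 10 Hz sample
inside a run contributes its dwell time (0.1 s) to its 1 cm bin, profile
values are time-weighted means, and occupancy totals are conserved (equal
to summed run time up to one grid sample per run boundary). Pooling over
the (−60, −20) cm approach window is occupancy-weighted.

The EMG-based epoching fallback (used in the original protocol for one
animal without tracking) is not implemented beyond a stub: the defining
thresholds are not specified anywhere we could adopt them from.

## Statistics

**Speed-correlation bootstrap.** Spearman's ρ between a 10 Hz series and
speed over the masked (active-movement) samples; the null is built by
fully permuting the masked speed vector and recomputing ρ 1000 times;
significance means ρ falls outside the empirical 0.025/0.975 null
quantiles. The permutation preserves the speed marginal exactly and the
test is exchangeable under the null, giving a measured type-I rate of
~0.05 for serially independent series. For strongly autocorrelated series
(which 1 s windows at 0.1 s steps produce) a full permutation understates
the null spread and the test becomes anticonservative; a circular block
shuffle (`block_s`) is provided for that regime, and the worked example's
"significant" speed correlations on smooth synthetic series should be read
with this caveat.

**Distribution shape.** Sample skewness (adjusted Fisher–Pearson),
Shapiro–Wilk normality p (computed on a deterministic subsample above
n = 5000, where the test statistic's p-value is otherwise unreliable), and
a histogram-based modality note (descriptive only; no dip test).

**Phase-locking.** Theta phase is the angle of the analytic signal of the
6–12 Hz band-passed LFP (3rd-order Butterworth, zero-phase). Convention:
phase 0 at the oscillation peak, ±180° at the trough. Spike phases are
nearest-sample lookups; units with fewer than 10 retained spikes return an
explicit insufficient-data result. The Rayleigh p uses the standard
finite-n series approximation, which we checked against a 2·10⁵-draw
Monte-Carlo null (agreement within 0.01 at n ≤ 12) and against an
independent circular-statistics implementation.

**Photo-identification.** Trial-averaged rate in 10 ms bins over a 1 s
baseline plus the 100 ms light window, z-scored by the baseline bins'
mean/SD. The default decision statistic is the *mean* z over the light
window against ±1.96 (a per-bin any-crossing option exists but is noisier).
For W = 10 light bins and B = 100 baseline bins the mean-z rule's nominal
false-classification level is 2·(1 − Φ(1.96/√(1/W + 1/B))) ≈ 3×10⁻⁹ —
effectively zero — and simulated homogeneous Poisson units reproduce this.
Simple and complex spikes are pooled.

## Synthetic sessions

The generator's purpose is statistical, not biophysical: every estimator
gets inputs whose population value is known in closed form.

* **Coherence by construction.** Channels are built as
  y = w·x̂ + √(1−w²)·n̂ with x̂ the unit-variance latent hippocampal
  reference and n̂ channel noise with the identical spectral envelope
  (1/√f background plus an 8 Hz theta bump), orthogonalized against the
  reference so unit variance holds to roundoff. Population coherence
  between a channel and the reference is exactly w at every frequency.
  Pairwise targets must involve a hippocampal channel (star topology);
  cerebellar–cerebellar coherence is implied as the product of weights,
  and contradictory explicit targets raise a non-realizable error. A
  time-varying weight implements the approach-zone coherence increment on
  the track.
* **Behavior.** Home cage: bout-structured 2-D walk in a 30 × 10 cm box
  (rest/locomotion states with ~6 s/~10 s dwell times) so that speeds
  straddle the 3 cm/s threshold and bouts can satisfy the 4 s rule. Track:
  back-and-forth runs on a 100 cm track with 5 cm goal zones 10 cm from
  each end; "goal-directed" runs accelerate to a ~22 cm/s plateau and
  decelerate into the zone, "exploratory" runs move slowly with random
  pauses and turnarounds. Rewards fire on goal-zone arrival.
* **Nuisances.** 50 Hz sinusoidal line noise at configurable amplitude;
  artifacts as Gaussian-windowed 0.5–5 Hz bursts at 10–20× the signal SD,
  Poisson-placed at the configured rate, with ground-truth intervals
  returned for round-trip tests.
* **Spikes.** Inhomogeneous point process with intensity
  base_rate·exp(κ·cos(φ−μ))/I₀(κ) evaluated on the reference's theta
  phase, thinned per sample; κ = 0 reduces to homogeneous Poisson, the
  resultant length matches I₁(κ)/I₀(κ), and spike counts scale linearly
  with base_rate.
* **Determinism.** All randomness derives from one session seed through
  named, CRC-keyed substreams, so identical specs produce byte-identical
  sessions.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real recordings: behavioral-state dependence of
theta (the synthetic hippocampal theta-power distribution is positively
skewed, where awake-behaving hippocampus shows a negatively skewed,
near-saturated distribution); non-stationary theta frequency; cross-
frequency coupling; realistic artifact waveforms; electrode drift; and any
anatomical or causal structure behind the imposed coherence values.

## Resolution limits and problem sizes

Coherence differences of a few hundredths are at the edge of what a single
session can resolve. With the per-window read-out, a 12-min session's
active windows give a paired-difference SD of roughly 0.01–0.03 between
two cerebellar sites, so an imposed 0.04 separation (0.50 vs 0.46) is
ordered correctly only ~70–90% of the time; the pooled read-out at
~200 active seconds does no better than SD ≈ 0.025. The package therefore
tests that contrast in the extended-recording regime (36-min home-cage
sessions, pooled summary), where it is reliably resolved, and reserves
single-session ordering claims for large imposed differences (the
0.46 → 0.65 approach-zone increment, resolved in 20/20 seeds). This
mirrors why long recordings are concatenated into 12-min blocks and
averaged, and why small between-site differences are group-level findings
rather than single-session ones.

Test and validation problem sizes were chosen as the smallest that leave
the Monte-Carlo error well inside each tolerance: 600 non-overlapping
windows for the ±0.03 coherence oracle; 1500 simulated sessions/units for
the 0.05 ± 0.02 type-I calibrations (binomial SD 0.006); 100 seeds for
detection/classification rates; 6-min track sessions for end-to-end
ordering.

## Known limitations

* The pipeline analyzes one session at a time; group-level inference
  (ANOVA/Friedman/Kruskal–Wallis families) is intentionally out of scope
  and should be applied to the per-session tables with standard tools.
* The full-permutation speed null is anticonservative for autocorrelated
  series (see above); block shuffling is available but block length is a
  user choice.
* Hemisphere averaging assumes the two hippocampal electrodes measure the
  same process; with one electrode absent the other passes through
  unchanged, which silently halves the averaging benefit.
* The phase convention (0 = peak) is internal; absolute preferred-phase
  values are only comparable between analyses using the same convention.
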