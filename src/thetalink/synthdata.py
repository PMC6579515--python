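"""Synthetic sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes —
multi-channel LFPs with a dominant hippocampal 6-12 Hz rhythm and
controllable pairwise theta coherence, 50 Hz line contamination, large
low-frequency artifacts, home-cage and linear-track behavior with rewards
at fixed goal zones, von-Mises phase-locked spike trains, and light-evoked
firing-rate changes.  It is not a biophysical model: its purpose is to give
every estimator in the pipeline an input whose population value is known in
closed form.

Coherence is imposed by equal-spectrum mixing: given a unit-variance
reference x and an independent noise n with the *same* power spectrum,
y = c*x + sqrt(1-c^2)*n has population magnitude coherence exactly c at
every frequency.  Sessions use a star topology around a latent hippocampal
reference, so any pairwise target involving a hippocampal channel is
realizable for c in [0,1].
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0

from .core import (
    EventSeries,
    IntervalSet,
    ParameterError,
    SessionBundle,
    SignalTrace,
    SpikeTrain,
    TrackingTrace,
)

__all__ = [
    "SessionSpec",
    "generate_coherent_pair",
    "generate_behavior",
    "generate_phase_locked_spikes",
    "generate_session",
    "lfp_spectral_shape",
]

HIPPOCAMPAL_ROLES = {"hippocampus_left", "hippocampus_right"}
CEREBELLAR_ROLES = {"crusI", "lobVI", "lobII_III"}


@dataclass
class SessionSpec:
    """Parameters of one synthetic session.

    Defaults reproduce the study's recording conditions: LFP at 1 kHz,
    tracking at 30 Hz, 12-minute sessions, a 100 cm track with 5 cm goal
    zones 10 cm from each end, and a hippocampal theta band of 6-12 Hz.
    """

    duration: float = 720.0
    sample_rate: float = 1000.0
    tracking_rate: float = 30.0
    channels: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("hpc_l", "hippocampus_left"),
            ("crus1", "crusI"),
            ("lob6", "lobVI"),
            ("lob23", "lobII_III"),
        ]
    )
    coherence_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    theta_band: tuple[float, float] = (6.0, 12.0)
    theta_freq: float = 8.0
    line_noise_amplitude: float = 0.2
    artifact_rate: float = 0.0  # events per minute
    behavior_mode: str = "homecage"  # or "linear_track"
    speed_profile: str = "goal_directed"  # or "exploratory" (linear track)
    track_length: float = 100.0
    goal_zone_width: float = 5.0
    goal_zone_offset: float = 10.0
    interhemispheric_coherence: float = 0.9
    coherence_boost: dict[str, tuple[float, tuple[float, float]]] = field(default_factory=dict)
    spike_units: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ParameterError("duration must be positive")
        for pair, c in self.coherence_targets.items():
            if not 0.0 <= c <= 1.0:
                raise ParameterError(f"coherence target {pair} = {c} outside [0, 1]")
        if self.behavior_mode not in ("homecage", "linear_track"):
            raise ParameterError(f"unknown behavior_mode '{self.behavior_mode}'")
        labels = [lab for lab, _ in self.channels]
        if len(labels) != len(set(labels)):
            raise ParameterError("channel labels must be unique")

    def subseed(self, stream: str) -> np.random.Generator:
        """Per-stream child generator derived from the single session seed."""
        tag = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence([self.seed, tag])
        return np.random.default_rng(ss)


def lfp_spectral_shape(freqs: np.ndarray, theta_freq: float = 8.0, theta_gain: float = 6.0):
    """Amplitude profile of the synthetic LFP: 1/f background plus a theta bump."""
    f = np.maximum(np.abs(freqs), 0.1)
    background = 1.0 / np.sqrt(f)
    bump = theta_gain * np.exp(-0.5 * ((np.abs(freqs) - theta_freq) / 1.0) ** 2)
    shape = background + bump
    shape[np.abs(freqs) < 0.1] = 0.0  # no DC
    return shape


def _shaped_noise(n: int, sample_rate: float, rng: np.random.Generator,
                  shape_kind: str = "lfp", theta_freq: float = 8.0) -> np.ndarray:
    """Unit-variance Gaussian noise with a deterministic amplitude spectrum.

    All realizations share the same spectral envelope, so mixing two of
    them yields exactly the closed-form coherence of the mixing weights.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    if shape_kind == "white":
        amp = np.ones_like(freqs)
        amp[0] = 0.0
    else:
        amp = lfp_spectral_shape(freqs, theta_freq=theta_freq)
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    z[0] = 0.0
    if n % 2 == 0:
        z[-1] = z[-1].real
    x = np.fft.irfft(amp * z, n=n)
    return x / x.std()


def _orthonormal_noise(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Remove the sample projection of n on x and renormalize.

    Population-independent realizations still have O(1/sqrt(N)) sample
    correlation, which would perturb the mixed channel's variance; exact
    orthogonalization makes the unit-variance invariant hold to roundoff
    while leaving the noise spectrum asymptotically unchanged.
    """
    n2 = n - (x @ n) / (x @ x) * x
    return n2 / n2.std()


def generate_coherent_pair(
    n_samples: int,
    sample_rate: float,
    target: float,
    seed: int,
    shape_kind: str = "lfp",
) -> tuple[SignalTrace, SignalTrace]:
    """Two signals with population magnitude coherence ``target`` at every
    frequency, via equal-spectrum mixing y = c*x + sqrt(1-c^2)*n."""
    if not 0.0 <= target <= 1.0:
        raise ParameterError(f"coherence target {target} outside [0, 1]")
    if n_samples < 4:
        raise ParameterError("n_samples too small")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1F]))
    x = _shaped_noise(n_samples, sample_rate, rng, shape_kind)
    n = _orthonormal_noise(x, _shaped_noise(n_samples, sample_rate, rng, shape_kind))
    y = target * x + np.sqrt(1.0 - target**2) * n
    return (
        SignalTrace(x, sample_rate, label="x"),
        SignalTrace(y, sample_rate, label="y"),
    )


# ---------------------------------------------------------------------------
# behavior


def _homecage_walk(spec: SessionSpec, rng: np.random.Generator) -> TrackingTrace:
    """Bout-structured 2-D walk in a 30 x 10 cm box.

    Movement alternates between rest (~0.5 cm/s jitter, mean dwell 6 s) and
    locomotion bouts (~7 cm/s, mean dwell 10 s) so the speed distribution
    straddles the 3 cm/s inclusion threshold and bouts can satisfy the
    4 s sustained-movement rule.
    """
    dt = 1.0 / spec.tracking_rate
    n = int(round(spec.duration * spec.tracking_rate))
    moving = rng.random() < 0.5
    p_start = dt / 6.0  # mean rest 6 s
    p_stop = dt / 10.0  # mean bout 10 s
    target = 0.5
    v = 0.5
    heading = rng.uniform(0, 2 * np.pi)
    x = np.empty(n)
    y = np.empty(n)
    px, py = 15.0, 5.0
    for i in range(n):
        if moving and rng.random() < p_stop:
            moving = False
        elif not moving and rng.random() < p_start:
            moving = True
            target = rng.uniform(5.0, 10.0)
        if not moving:
            target = 0.5
        v += (target - v) * dt / 0.5 + 0.8 * np.sqrt(dt) * rng.standard_normal()
        v = max(v, 0.0)
        heading += 1.5 * np.sqrt(dt) * rng.standard_normal()
        px += v * np.cos(heading) * dt
        py += v * np.sin(heading) * dt
        if not 0.0 <= px <= 30.0:
            px = float(np.clip(px, 0.0, 30.0))
            heading = np.pi - heading
        if not 0.0 <= py <= 10.0:
            py = float(np.clip(py, 0.0, 10.0))
            heading = -heading
        x[i], y[i] = px, py
    times = np.arange(n) * dt
    return TrackingTrace(times=times, x=x, y=y, source_rate=spec.tracking_rate)


def _goal_positions(spec: SessionSpec) -> tuple[float, float]:
    lo = spec.goal_zone_offset + spec.goal_zone_width / 2.0
    hi = spec.track_length - spec.goal_zone_offset - spec.goal_zone_width / 2.0
    return lo, hi


def _track_runs(spec: SessionSpec, rng: np.random.Generator):
    """Back-and-forth 1-D trajectory with rewards on goal-zone entry."""
    dt = 1.0 / spec.tracking_rate
    n = int(round(spec.duration * spec.tracking_rate))
    goal_lo, goal_hi = _goal_positions(spec)
    x = np.empty(n)
    times = np.arange(n) * dt
    rewards: list[float] = []
    pos = goal_lo
    target = goal_hi
    direction = 1
    goal_directed = spec.speed_profile == "goal_directed"
    v = 0.0
    dwell = 0
    for i in range(n):
        x[i] = pos
        if dwell > 0:
            dwell -= 1
            continue
        span = abs(target - pos)
        if goal_directed:
            # accelerate-plateau-decelerate: speed set by remaining distance
            v_plateau = rng.normal(22.0, 2.0)
            v = np.clip(min(span * 1.2 + 2.0, v_plateau), 2.0, 40.0)
            v *= 1.0 + 0.05 * rng.standard_normal()
        else:
            # exploratory: slow OU speed with occasional pauses/turnarounds
            v = max(0.0, v + (-0.4 * (v - 5.0)) * dt + 4.0 * np.sqrt(dt) * rng.standard_normal())
            if rng.random() < 0.002:  # turnaround
                direction, target = -direction, (goal_lo if target == goal_hi else goal_hi)
        pos = pos + direction * v * dt
        pos = float(np.clip(pos, 0.0, spec.track_length))
        arrived = (direction > 0 and pos >= target) or (direction < 0 and pos <= target)
        if arrived:
            rewards.append(times[i])
            dwell = int(round(rng.uniform(0.5, 1.5) / dt))  # consume reward
            direction = -direction
            target = goal_lo if target == goal_hi else goal_hi
            v = 0.0
    y = np.zeros(n)
    return (
        TrackingTrace(times=times, x=x, y=y, source_rate=spec.tracking_rate),
        EventSeries(name="reward", times=np.asarray(rewards)),
    )


def generate_behavior(spec: SessionSpec) -> tuple[TrackingTrace, EventSeries]:
    """Position tracking plus reward events for the configured behavior mode.

    Home-cage mode yields a 2-D random walk and no rewards; linear-track
    mode yields back-and-forth runs with a reward each time the animal
    reaches the opposite goal zone.
    """
    rng = spec.subseed("behavior")
    if spec.behavior_mode == "homecage":
        return _homecage_walk(spec, rng), EventSeries(name="reward", times=np.empty(0))
    return _track_runs(spec, rng)


# ---------------------------------------------------------------------------
# spikes


def generate_phase_locked_spikes(
    phase_series: np.ndarray,
    sample_rate: float,
    base_rate: float,
    kappa: float,
    mu: float,
    seed: int,
    unit_id: str = "unit",
    t0: float = 0.0,
) -> SpikeTrain:
    """Inhomogeneous point process with von-Mises phase preference.

    Intensity is base_rate * exp(kappa*cos(phase - mu)) / I0(kappa), so the
    time-averaged rate stays at ``base_rate`` (phase is ~uniform over time)
    and kappa = 0 reduces to a homogeneous Poisson process.
    """
    if base_rate <= 0:
        raise ParameterError("base_rate must be positive")
    if kappa < 0:
        raise ParameterError("kappa must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E]))
    phase = np.asarray(phase_series, dtype=float)
    lam = base_rate * np.exp(kappa * np.cos(phase - mu)) / i0(kappa)
    p = lam / sample_rate
    if np.nanmax(p) > 0.5:
        raise ParameterError("base_rate too high for per-sample thinning at this sample rate")
    p = np.nan_to_num(p)
    hits = rng.random(phase.size) < p
    times = t0 + np.flatnonzero(hits) / sample_rate
    # sub-sample jitter keeps times strictly increasing and off-grid
    times = times + rng.uniform(0, 0.9 / sample_rate, times.size)
    return SpikeTrain(unit_id=unit_id, times=np.sort(times))


# ---------------------------------------------------------------------------
# sessions


def _mixing_coefficients(spec: SessionSpec) -> dict[str, float]:
    """Per-channel mixing weight against the latent hippocampal reference.

    Hippocampal channels default to weight 1 (left) and the configured
    interhemispheric coherence (right).  A cerebellar channel's weight is
    its coherence target with any hippocampal channel.  Explicit
    cerebellar-cerebellar targets must equal the implied product c_i*c_j;
    otherwise the pairwise matrix is not realizable in a star topology.
    """
    roles = dict(spec.channels)
    weights: dict[str, float] = {}
    for label, role in spec.channels:
        if role == "hippocampus_left":
            weights[label] = 1.0
        elif role == "hippocampus_right":
            weights[label] = spec.interhemispheric_coherence
        else:
            weights[label] = 0.0
    deferred = []
    for (a, b), c in spec.coherence_targets.items():
        for lab in (a, b):
            if lab not in roles:
                raise ParameterError(f"coherence target references unknown channel '{lab}'")
        a_h = roles[a] in HIPPOCAMPAL_ROLES
        b_h = roles[b] in HIPPOCAMPAL_ROLES
        if a_h == b_h:
            deferred.append(((a, b), c))
            continue
        hpc, cereb = (a, b) if a_h else (b, a)
        w = c / weights[hpc] if weights[hpc] > 0 else c
        if not 0.0 <= w <= 1.0 + 1e-9:
            raise ParameterError(
                f"target {c} for {a}-{b} not realizable given hippocampal weight {weights[hpc]}"
            )
        weights[cereb] = min(w, 1.0)
    for (a, b), c in deferred:
        implied = weights[a] * weights[b]
        if abs(c - implied) > 0.05:
            raise ParameterError(
                f"pairwise target {a}-{b}={c} conflicts with star-implied value "
                f"{implied:.3f}; only targets involving a hippocampal channel are free"
            )
    return weights


def _boost_weight(
    spec: SessionSpec,
    label: str,
    base_w: float,
    t_lfp: np.ndarray,
    runs_distance: np.ndarray | None,
) -> np.ndarray:
    """Time-resolved mixing weight, optionally raised inside a distance window."""
    w = np.full(t_lfp.size, base_w)
    if label in spec.coherence_boost and runs_distance is not None:
        boosted, (d_lo, d_hi) = spec.coherence_boost[label]
        in_zone = (runs_distance >= d_lo) & (runs_distance <= d_hi)
        w[in_zone] = boosted
    return w


def generate_session(spec: SessionSpec) -> tuple[SessionBundle, dict]:
    """Full synthetic session plus its ground-truth record.

    LFP channels achieve the requested pairwise theta coherence through
    star mixing against a latent hippocampal reference; the 50 Hz sinusoid
    and 0.5-5 Hz artifact bursts are added after mixing.  The returned
    ground truth holds the mixing weights, artifact intervals and spike
    parameters so tests can close the loop.
    """
    weights = _mixing_coefficients(spec)
    n = int(round(spec.duration * spec.sample_rate))
    fs = spec.sample_rate
    t_lfp = np.arange(n) / fs

    tracking, rewards = generate_behavior(spec)
    runs_distance = None
    if spec.behavior_mode == "linear_track" and len(rewards) >= 2:
        from .behavior import distance_at_times, segment_runs

        runs = segment_runs(tracking, rewards, spec.track_length, spec.goal_zone_offset,
                            spec.goal_zone_width)
        runs_distance = distance_at_times(runs, t_lfp)

    rng_ref = spec.subseed("lfp_reference")
    reference = _shaped_noise(n, fs, rng_ref, "lfp", spec.theta_freq)

    signals: dict[str, SignalTrace] = {}
    artifact_truth: dict[str, list[tuple[float, float]]] = {}
    line_phase = spec.subseed("line").uniform(0, 2 * np.pi)
    for label, role in spec.channels:
        rng_ch = spec.subseed(f"chan:{label}")
        noise = _orthonormal_noise(reference, _shaped_noise(n, fs, rng_ch, "lfp", spec.theta_freq))
        w = _boost_weight(spec, label, weights[label], t_lfp, runs_distance)
        w = np.nan_to_num(w, nan=weights[label])
        vals = w * reference + np.sqrt(np.clip(1.0 - w**2, 0.0, 1.0)) * noise
        if spec.line_noise_amplitude > 0:
            vals = vals + spec.line_noise_amplitude * np.sin(2 * np.pi * 50.0 * t_lfp + line_phase)
        art_spans: list[tuple[float, float]] = []
        if spec.artifact_rate > 0:
            n_art = spec.subseed(f"art_n:{label}").poisson(spec.artifact_rate * spec.duration / 60.0)
            rng_a = spec.subseed(f"art:{label}")
            for _ in range(int(n_art)):
                center = rng_a.uniform(2.0, spec.duration - 2.0)
                f_art = rng_a.uniform(0.5, 5.0)
                amp = rng_a.uniform(10.0, 20.0)
                width = rng_a.uniform(0.3, 0.8)
                env = np.exp(-0.5 * ((t_lfp - center) / width) ** 2)
                vals = vals + amp * env * np.sin(2 * np.pi * f_art * (t_lfp - center))
                art_spans.append((center - 2 * width, center + 2 * width))
        artifact_truth[label] = art_spans
        signals[label] = SignalTrace(vals, fs, label=label, units="a.u.")

    # spikes phase-locked to the hippocampal theta component of the reference
    from scipy.signal import butter, filtfilt, hilbert

    b, a = butter(3, np.array(spec.theta_band) / (fs / 2), btype="band")
    theta_phase = np.angle(hilbert(filtfilt(b, a, reference)))
    spikes: dict[str, SpikeTrain] = {}
    spike_truth: dict[str, dict] = {}
    for i, params in enumerate(spec.spike_units):
        uid = params.get("unit_id", f"unit{i}")
        train = generate_phase_locked_spikes(
            theta_phase, fs, params.get("base_rate", 20.0), params.get("kappa", 0.0),
            params.get("mu", 0.0), seed=spec.seed + 1000 + i, unit_id=uid,
        )
        spikes[uid] = train
        spike_truth[uid] = dict(params)

    events = {"reward": rewards}
    bundle = SessionBundle(
        signals=signals,
        tracking=tracking,
        events=events,
        spikes=spikes,
        metadata={
            "channel_roles": dict(spec.channels),
            "sample_rate": fs,
            "duration": spec.duration,
            "seed": spec.seed,
            "behavior_mode": spec.behavior_mode,
            "track_length": spec.track_length,
            "goal_zone_offset": spec.goal_zone_offset,
            "goal_zone_width": spec.goal_zone_width,
        },
    )
    truth = {
        "mixing_weights": weights,
        "coherence_targets": dict(spec.coherence_targets),
        "artifact_intervals": {
            lab: IntervalSet.from_pairs(spans) for lab, spans in artifact_truth.items()
        },
        "spike_params": spike_truth,
        "theta_phase": theta_phase,
    }
    return bundle, truth
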