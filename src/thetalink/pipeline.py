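"""End-to-end orchestration of the two study-shaped analyses.

``run_homecage`` reproduces the home-cage workflow: preprocess LFP, keep
active-movement data (speed > 3 cm/s sustained >= 4 s), concatenate into
12-minute blocks, and report z-scored power spectra, cerebello-hippocampal
coherence (hemisphere-averaged, block-averaged), instantaneous theta
power/coherence distributions, and shuffled-speed correlation bootstraps.

``run_linear_track`` reproduces the goal-directed workflow: segment
reward-to-reward runs, exclude +/-0.5 s around reward stimulation, bin
speed/power/coherence by distance from reward in 1 cm occupancy-normalized
bins, and pool theta coherence over the (-60, -20) cm approach window.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import preprocess as prep
from . import spectral as spec
from . import stats as tstats
from .core import (
    DEFAULT_BANDS,
    BandDefinition,
    DegenerateInputError,
    IntervalSet,
    ParameterError,
    SessionBundle,
    SignalTrace,
)
from .synthdata import CEREBELLAR_ROLES, HIPPOCAMPAL_ROLES

__all__ = ["AnalysisConfig", "run_homecage", "run_linear_track", "cli"]


@dataclass
class AnalysisConfig:
    """All analysis parameters, serialized alongside every output."""

    window_s: float = 1.0
    step_s: float = 0.1
    n_tapers: int = 4
    notch_hz: float = 50.0
    notch_q: float = 30.0
    detrend_window_s: float = 1.0
    detrend_step_s: float = 0.5
    artifact_band: tuple[float, float] = (0.5, 5.0)
    artifact_z: float = 4.0
    line_mask: tuple[float, float] = (48.0, 52.0)
    zscore_range: tuple[float, float] = (0.1, 500.0)
    speed_threshold_cm_s: float = 3.0
    min_epoch_s: float = 4.0
    speed_rate_hz: float = 10.0
    block_s: float = 720.0
    peri_stim_pad_s: float = 0.5
    bin_cm: float = 1.0
    pooling_window_cm: tuple[float, float] = (-60.0, -20.0)
    n_shuffles: int = 1000
    alpha: float = 0.05
    max_freq_hz: float = 120.0
    seed: int = 0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: (b.f_lo, b.f_hi) for k, b in DEFAULT_BANDS.items()}
    )

    def band(self, name: str) -> BandDefinition:
        lo, hi = self.bands[name]
        return BandDefinition(name, lo, hi)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("artifact_band", "line_mask", "zscore_range", "pooling_window_cm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        return cls(**raw)


def _nanmean(arr, axis=None):
    """nanmean tolerating all-NaN slices (e.g. the masked 48-52 Hz band)."""
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(arr, axis=axis)


def _classify_channels(bundle: SessionBundle):
    roles = bundle.channel_roles
    hpc = {lab: roles[lab] for lab in bundle.signals if roles.get(lab) in HIPPOCAMPAL_ROLES}
    cereb = {lab: roles[lab] for lab in bundle.signals if roles.get(lab) in CEREBELLAR_ROLES}
    if not hpc:
        raise ParameterError("session has no hippocampal channel")
    if not cereb:
        raise ParameterError("session has no cerebellar channel")
    return hpc, cereb


def _preprocess_all(bundle: SessionBundle, config: AnalysisConfig):
    clean = {}
    artifact_mask = IntervalSet.empty()
    for label, trace in bundle.signals.items():
        conditioned = prep.preprocess_lfp(
            trace,
            notch_center=config.notch_hz,
            notch_q=config.notch_q,
            detrend_window=config.detrend_window_s,
            detrend_step=config.detrend_step_s,
        )
        clean[label] = conditioned
        artifact_mask = artifact_mask.union(
            prep.detect_artifact_intervals(
                conditioned,
                band=config.artifact_band,
                z_threshold=config.artifact_z,
                window=config.window_s,
                step=config.step_s,
                n_tapers=config.n_tapers,
            )
        )
    return clean, artifact_mask


def _speed_on_grid(bundle: SessionBundle, config: AnalysisConfig, t_grid: np.ndarray):
    if bundle.tracking is None:
        return None
    return bhv.compute_speed(bundle.tracking, out_rate=config.speed_rate_hz, t_grid=t_grid)


def _grid_from_map(tfmap: spec.TimeFrequencyMap) -> np.ndarray:
    return tfmap.window_centers


def _block_slices(valid_idx: np.ndarray, windows_per_block: int):
    """Group retained window indices into consecutive blocks of fixed size."""
    blocks = []
    for i in range(0, valid_idx.size, windows_per_block):
        chunk = valid_idx[i : i + windows_per_block]
        if chunk.size >= windows_per_block // 2:  # keep a >= half-full tail block
            blocks.append(chunk)
    if not blocks and valid_idx.size:
        blocks = [valid_idx]
    return blocks


def _hemisphere_average(per_pair: dict[tuple[str, str], np.ndarray], hpc: dict, cereb: dict):
    """Average coherence summaries over hippocampal hemispheres per cerebellar site."""
    out = {}
    for clab in cereb:
        parts = [v for (h, c), v in per_pair.items() if c == clab]
        if not parts:
            continue
        out[clab] = parts[0] if len(parts) == 1 else np.nanmean(np.stack(parts), axis=0)
    return out


def run_homecage(bundle: SessionBundle, config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Home-cage analysis; returns a dict of result tables."""
    hpc, cereb = _classify_channels(bundle)
    clean, artifact_mask = _preprocess_all(bundle, config)
    any_label = next(iter(clean))
    duration = clean[any_label].duration

    # spectrograms (shared window grid) and active-movement mask
    specs = {
        lab: spec.multitaper_spectrogram(
            tr, config.window_s, config.step_s, config.n_tapers,
            exclude=artifact_mask, max_freq=config.max_freq_hz,
        )
        for lab, tr in clean.items()
    }
    t_grid = _grid_from_map(specs[any_label])
    speed = _speed_on_grid(bundle, config, t_grid)
    if speed is None:
        raise ParameterError("home-cage analysis requires tracking (EMG fallback not configured)")
    active = bhv.detect_active_epochs(speed, config.speed_threshold_cm_s, config.min_epoch_s)

    warnings: list[str] = []
    if active.total_duration == 0:
        warnings.append("no active-movement epochs >= min duration; results empty")

    win_starts = t_grid - config.window_s / 2
    win_ends = t_grid + config.window_s / 2
    retained = active.contains_times(t_grid) & ~artifact_mask.overlaps_window(win_starts, win_ends)
    valid_idx = np.flatnonzero(retained)
    windows_per_block = int(round(config.block_s / config.step_s))
    blocks = _block_slices(valid_idx, windows_per_block)

    theta = config.band("theta")

    # --- z-scored mean power spectra per channel (retained windows)
    power_rows = []
    for lab, sp_map in specs.items():
        if valid_idx.size == 0:
            continue
        mean_spec = _nanmean(sp_map.values[valid_idx], axis=0)
        zf, zvals = spec.zscore_power_spectrum(
            sp_map.freqs, mean_spec, *config.zscore_range
        )
        for f, v in zip(zf, zvals):
            power_rows.append({"channel": lab, "freq_hz": f, "z_power": v})
    power_table = pd.DataFrame(power_rows)

    # --- coherence per cerebello-hippocampal combination
    # the per-window coherogram (4 tapers) gives the study-scale "overall"
    # coherence (biased floor ~0.457); the pooled estimator (spectra averaged
    # over all retained windows before normalizing) is the low-variance,
    # near-unbiased read-out of the same coupling
    drop_mask = artifact_mask.union(active.complement(t_grid[0], t_grid[-1] + config.step_s))
    pair_coh_spectra: dict[tuple[str, str], np.ndarray] = {}
    pair_pooled_theta: dict[tuple[str, str], float] = {}
    pair_theta_series: dict[tuple[str, str], SignalTrace] = {}
    freqs_out = None
    for hlab in hpc:
        for clab in cereb:
            cohg = spec.multitaper_coherogram(
                clean[hlab], clean[clab], config.window_s, config.step_s,
                config.n_tapers, exclude=artifact_mask, max_freq=config.max_freq_hz,
            )
            cohg = spec.mask_line_band(cohg, config.line_mask)
            freqs_out = cohg.freqs
            block_means = [_nanmean(cohg.values[idx], axis=0) for idx in blocks]
            pair_coh_spectra[(hlab, clab)] = (
                _nanmean(np.stack(block_means), axis=0)
                if block_means
                else np.full(freqs_out.size, np.nan)
            )
            ts = spec.band_series(cohg, theta)
            vals = np.where(retained, ts.values, np.nan)
            pair_theta_series[(hlab, clab)] = ts.with_values(vals)
            try:
                fp, cp, _ = spec.pooled_coherence(
                    clean[hlab], clean[clab], window=config.window_s,
                    step=config.window_s, exclude=drop_mask,
                )
                psel = (fp >= theta.f_lo) & (fp <= theta.f_hi)
                pair_pooled_theta[(hlab, clab)] = float(cp[psel].mean())
            except DegenerateInputError:
                pair_pooled_theta[(hlab, clab)] = float("nan")

    coh_by_site = _hemisphere_average(pair_coh_spectra, hpc, cereb)
    coh_rows = []
    for clab, vals in coh_by_site.items():
        for f, v in zip(freqs_out, vals):
            coh_rows.append({"site": clab, "freq_hz": f, "coherence": v})
    coherence_table = pd.DataFrame(coh_rows)

    # --- instantaneous theta power / coherence distributions + speed bootstraps
    shape_rows, corr_rows = [], []
    rng_seed = config.seed
    for lab, sp_map in specs.items():
        ts = spec.band_series(sp_map, theta)
        vals = np.where(retained, ts.values, np.nan)
        finite = vals[~np.isnan(vals)]
        # instantaneous theta power standardized across time (z-units)
        if finite.size >= 8:
            z = (finite - finite.mean()) / finite.std()
            shape = tstats.distribution_shape(z)
            shape_rows.append(
                {"series": f"theta_power:{lab}", "skewness": shape.skewness,
                 "normality_p": shape.normality_p, "modality": shape.modality_note,
                 "n": finite.size}
            )
        try:
            res = tstats.speed_correlation_bootstrap(
                ts.with_values(vals), speed, mask=active,
                n_shuffles=config.n_shuffles, alpha=config.alpha, seed=rng_seed,
            )
            corr_rows.append(
                {"series": f"theta_power:{lab}", "rho": res.rho_observed,
                 "lower": res.lower, "upper": res.upper,
                 "significant": res.significant, "n": res.n_samples}
            )
        except DegenerateInputError as err:
            warnings.append(f"speed correlation skipped for {lab}: {err}")
        rng_seed += 1

    site_theta = _hemisphere_average(
        {k: v.values for k, v in pair_theta_series.items()}, hpc, cereb
    )
    any_series = next(iter(pair_theta_series.values()))
    for clab, vals in site_theta.items():
        finite = vals[~np.isnan(vals)]
        if finite.size >= 8:
            shape = tstats.distribution_shape(finite)
            shape_rows.append(
                {"series": f"theta_coherence:{clab}", "skewness": shape.skewness,
                 "normality_p": shape.normality_p, "modality": shape.modality_note,
                 "n": finite.size}
            )
        try:
            res = tstats.speed_correlation_bootstrap(
                any_series.with_values(vals), speed, mask=active,
                n_shuffles=config.n_shuffles, alpha=config.alpha, seed=rng_seed,
            )
            corr_rows.append(
                {"series": f"theta_coherence:{clab}", "rho": res.rho_observed,
                 "lower": res.lower, "upper": res.upper,
                 "significant": res.significant, "n": res.n_samples}
            )
        except DegenerateInputError as err:
            warnings.append(f"speed correlation skipped for {clab}: {err}")
        rng_seed += 1

    theta_sel = (freqs_out >= theta.f_lo) & (freqs_out <= theta.f_hi)
    pooled_by_site = _hemisphere_average(pair_pooled_theta, hpc, cereb)
    summary_rows = [
        {
            "site": clab,
            "theta_coherence": float(_nanmean(vals[theta_sel])),
            "theta_coherence_pooled": float(pooled_by_site.get(clab, float("nan"))),
            "n_blocks": len(blocks),
            "active_s": active.total_duration,
            "retained_windows": int(valid_idx.size),
        }
        for clab, vals in coh_by_site.items()
    ]
    return {
        "power_spectra": power_table,
        "coherence_spectra": coherence_table,
        "theta_distributions": pd.DataFrame(shape_rows),
        "speed_correlations": pd.DataFrame(corr_rows),
        "summary": pd.DataFrame(summary_rows),
        "warnings": pd.DataFrame({"warning": warnings}),
    }


def run_linear_track(bundle: SessionBundle, config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Linear-track analysis; returns a dict of result tables."""
    hpc, cereb = _classify_channels(bundle)
    if bundle.tracking is None:
        raise ParameterError("linear-track analysis requires tracking")
    rewards = bundle.events.get("reward")
    warnings: list[str] = []
    meta = bundle.metadata
    track_length = float(meta.get("track_length", 100.0))
    goal_offset = float(meta.get("goal_zone_offset", 10.0))
    goal_width = float(meta.get("goal_zone_width", 5.0))

    clean, artifact_mask = _preprocess_all(bundle, config)
    if rewards is None or len(rewards) < 2:
        warnings.append("fewer than 2 rewards: no runs to analyze")
        return {"warnings": pd.DataFrame({"warning": warnings})}
    peri_stim = prep.build_exclusion_mask(rewards, pad=config.peri_stim_pad_s)
    exclude = artifact_mask.union(peri_stim)

    runs = bhv.segment_runs(bundle.tracking, rewards, track_length, goal_offset, goal_width)
    if not runs:
        warnings.append("no valid runs between rewards")
        return {"warnings": pd.DataFrame({"warning": warnings})}

    theta = config.band("theta")
    specs = {
        lab: spec.multitaper_spectrogram(
            tr, config.window_s, config.step_s, config.n_tapers,
            exclude=exclude, max_freq=config.max_freq_hz,
        )
        for lab, tr in clean.items()
    }
    any_label = next(iter(specs))
    t_grid = _grid_from_map(specs[any_label])
    speed = _speed_on_grid(bundle, config, t_grid)

    # distance-aligned speed profile
    speed_profile = bhv.bin_by_distance(speed, runs, config.bin_cm, max_distance=-track_length)
    profile_rows = [
        {"series": "speed", "distance_cm": c, "value": v, "occupancy_s": o}
        for c, v, o in zip(speed_profile.bin_centers, speed_profile.values,
                           speed_profile.occupancy)
    ]

    # per-channel theta power profiles
    for lab, sp_map in specs.items():
        ts = spec.band_series(sp_map, theta)
        prof = bhv.bin_by_distance(ts, runs, config.bin_cm, max_distance=-track_length)
        profile_rows += [
            {"series": f"theta_power:{lab}", "distance_cm": c, "value": v, "occupancy_s": o}
            for c, v, o in zip(prof.bin_centers, prof.values, prof.occupancy)
        ]

    # per-combination coherence and imaginary-coherency profiles
    pooled_rows = []
    pair_profiles: dict[tuple[str, str], bhv.DistanceProfile] = {}
    pair_imag: dict[tuple[str, str], bhv.DistanceProfile] = {}
    for hlab in hpc:
        for clab in cereb:
            for mode, store in (("magnitude", pair_profiles), ("imaginary", pair_imag)):
                cohg = spec.multitaper_coherogram(
                    clean[hlab], clean[clab], config.window_s, config.step_s,
                    config.n_tapers, exclude=exclude, mode=mode,
                    max_freq=config.max_freq_hz,
                )
                cohg = spec.mask_line_band(cohg, config.line_mask)
                ts = spec.band_series(cohg, theta)
                if mode == "imaginary":
                    ts = ts.with_values(np.abs(ts.values))
                store[(hlab, clab)] = bhv.bin_by_distance(
                    ts, runs, config.bin_cm, max_distance=-track_length
                )

    for tag, store in (("theta_coherence", pair_profiles), ("theta_imag_coherency", pair_imag)):
        values_by_site = _hemisphere_average(
            {k: v.values for k, v in store.items()}, hpc, cereb
        )
        occ_any = next(iter(store.values())).occupancy
        centers = next(iter(store.values())).bin_centers
        for clab, vals in values_by_site.items():
            profile_rows += [
                {"series": f"{tag}:{clab}", "distance_cm": c, "value": v, "occupancy_s": o}
                for c, v, o in zip(centers, vals, occ_any)
            ]
            pooled = spec.pool_profile(
                bhv.DistanceProfile(centers, vals, occ_any, freqs=None, label=clab),
                config.pooling_window_cm,
            )
            pooled_rows.append({"series": tag, "site": clab, "pooled_value": pooled})

    run_rows = [
        {
            "run": i,
            "start_s": r.interval[0],
            "end_s": r.interval[1],
            "direction": r.direction,
            "monotonic": r.monotonic,
            "duration_s": r.interval[1] - r.interval[0],
        }
        for i, r in enumerate(runs)
    ]
    return {
        "distance_profiles": pd.DataFrame(profile_rows),
        "pooled_approach": pd.DataFrame(pooled_rows),
        "runs": pd.DataFrame(run_rows),
        "warnings": pd.DataFrame({"warning": warnings}),
    }


def summarize_day(session_tables: list[dict[str, pd.DataFrame]]) -> pd.DataFrame:
    """Per-day summary: mean pooled approach coherence over the day's sessions."""
    frames = [t["pooled_approach"] for t in session_tables if "pooled_approach" in t]
    if not frames:
        return pd.DataFrame()
    allp = pd.concat(frames, ignore_index=True)
    return (
        allp.groupby(["series", "site"], as_index=False)["pooled_value"]
        .mean()
        .rename(columns={"pooled_value": "day_mean"})
    )


# ---------------------------------------------------------------------------
# CLI


def cli(argv=None) -> int:
    """Thin command-line entry point over the library."""
    import click

    @click.group()
    def main():
        """Cerebello-hippocampal LFP analysis pipeline."""

    @main.command()
    @click.option("--seed", type=int, default=0)
    @click.option("--mode", type=click.Choice(["homecage", "linear_track"]), default="homecage")
    @click.option("--duration", type=float, default=720.0)
    @click.option("--out", type=click.Path(), required=True)
    def simulate(seed, mode, duration, out):
        """Generate a synthetic session directory."""
        from .sessionio import write_session
        from .synthdata import SessionSpec, generate_session

        lt = mode == "linear_track"
        sp = SessionSpec(duration=duration, behavior_mode=mode, seed=seed,
                         artifact_rate=0.5 if not lt else 0.0)
        bundle, _ = generate_session(sp)
        write_session(bundle, out, force=True)
        click.echo(f"wrote session to {out}")

    def _load(session, config):
        from .sessionio import read_session

        cfg = AnalysisConfig.from_yaml(config) if config else AnalysisConfig()
        return read_session(session), cfg

    @main.command()
    @click.argument("session", type=click.Path(exists=True))
    @click.option("--config", type=click.Path(exists=True), default=None)
    @click.option("--out", type=click.Path(), required=True)
    def homecage(session, config, out):
        """Run the home-cage analysis on a session directory."""
        from .sessionio import write_results

        bundle, cfg = _load(session, config)
        tables = run_homecage(bundle, cfg)
        write_results(tables, out, params=cfg.to_dict())
        click.echo(f"wrote {len(tables)} tables to {out}")

    @main.command()
    @click.argument("session", type=click.Path(exists=True))
    @click.option("--config", type=click.Path(exists=True), default=None)
    @click.option("--out", type=click.Path(), required=True)
    def lineartrack(session, config, out):
        """Run the linear-track analysis on a session directory."""
        from .sessionio import write_results

        bundle, cfg = _load(session, config)
        tables = run_linear_track(bundle, cfg)
        write_results(tables, out, params=cfg.to_dict())
        click.echo(f"wrote {len(tables)} tables to {out}")

    @main.command()
    @click.argument("session", type=click.Path(exists=True))
    @click.option("--hpc-channel", default=None, help="hippocampal channel label")
    @click.option("--out", type=click.Path(), required=True)
    def phaselock(session, hpc_channel, out):
        """Spike-LFP theta phase-locking for every unit in a session."""
        from .phaselock import instantaneous_theta_phase, phase_locking_stats
        from .sessionio import write_results

        bundle, cfg = _load(session, None)
        hpc, _ = _classify_channels(bundle)
        label = hpc_channel or next(iter(hpc))
        lfp = prep.preprocess_lfp(bundle.signals[label])
        phase = instantaneous_theta_phase(lfp)
        rows = []
        for uid, train in bundle.spikes.items():
            r = phase_locking_stats(train, phase, lfp.sample_rate, t0=lfp.t0)
            rows.append(dataclasses.asdict(r))
        write_results({"phase_locking": pd.DataFrame(rows)}, out, params=cfg.to_dict())
        click.echo(f"wrote phase-locking results for {len(rows)} units to {out}")

    @main.command()
    @click.argument("run_dirs", nargs=-1, type=click.Path(exists=True))
    @click.option("--out", type=click.Path(), required=True)
    def report(run_dirs, out):
        """Collate summary CSVs from several run directories into one table."""
        frames = []
        for d in run_dirs:
            d = Path(d)
            for name in ("summary", "pooled_approach"):
                f = d / f"{name}.csv"
                if f.exists():
                    df = pd.read_csv(f)
                    df.insert(0, "run_dir", str(d))
                    frames.append(df)
        combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        Path(out).parent.mkdir(parents=True, exist_ok=True)
        combined.to_csv(out, index=False)
        click.echo(f"collated {len(frames)} tables into {out}")

    try:
        return main.main(args=argv, standalone_mode=False) or 0
    except click.ClickException as err:
        err.show()
        return err.exit_code
    except click.exceptions.Abort:
        return 1


if __name__ == "__main__":
    sys.exit(cli())
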