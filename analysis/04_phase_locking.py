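"""Spike-LFP theta phase-locking of the home-cage units.

For each unit recorded in the home-cage session: extract hippocampal theta
phase (6-12 Hz analytic signal) from the preprocessed LFP, restrict to
active-movement epochs, and compute the circular summary with Rayleigh
significance.  Tables go to results/phase_locking/.
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

from thetalink.behavior import compute_speed, detect_active_epochs
from thetalink.phaselock import instantaneous_theta_phase, phase_locking_stats
from thetalink.pipeline import AnalysisConfig
from thetalink.preprocess import preprocess_lfp
from thetalink.sessionio import read_session, write_results

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    sess_dir = ROOT / "scratch" / "sessions" / "homecage"
    if not sess_dir.exists():
        print("run analysis/01_simulate_sessions.py first", file=sys.stderr)
        return 1
    bundle = read_session(sess_dir)
    cfg = AnalysisConfig(seed=3)

    lfp = preprocess_lfp(bundle.signals["hpc_l"])
    speed = compute_speed(bundle.tracking, out_rate=cfg.speed_rate_hz)
    active = detect_active_epochs(speed, cfg.speed_threshold_cm_s, cfg.min_epoch_s)
    phase = instantaneous_theta_phase(lfp, band=cfg.bands["theta"], restrict=active)

    rows = []
    for uid, train in sorted(bundle.spikes.items()):
        res = phase_locking_stats(train, phase, lfp.sample_rate, t0=lfp.t0)
        rows.append(dataclasses.asdict(res))
        tag = "phase-locked" if res.significant else "not locked"
        print(f"{uid}: n={res.n_spikes} spikes in active epochs, "
              f"angle={res.mean_angle_deg:.0f} deg, R={res.resultant_length:.3f}, "
              f"p={res.rayleigh_p:.2g} -> {tag}")

    out = ROOT / "results" / "phase_locking"
    write_results({"phase_locking": pd.DataFrame(rows)}, out, params=cfg.to_dict())
    print(f"tables written to {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
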