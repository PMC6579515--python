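"""Generate the synthetic study sessions used by the downstream analyses.

Writes session directories under scratch/sessions/:

* ``homecage`` — 24 min of home-cage exploration, four LFP channels
  (hippocampus + Crus I, lobule VI, lobule II/III) with theta-band
  coherence targets {Crus I: 0.50, lob VI: 0.50, lob II/III: 0.46}, 50 Hz
  line noise, ~1 artifact/min, and two recorded units (one phase-locked at
  231 deg with kappa=2, one unmodulated).
* ``track_s1..s3`` — one training day of three 12-min goal-directed
  linear-track sessions with a Crus I coherence increment (0.46 -> 0.65)
  inside the (-60, -20) cm approach zone.
"""

import sys
from pathlib import Path

import numpy as np

from thetalink.sessionio import write_session
from thetalink.synthdata import SessionSpec, generate_session

OUT = Path(__file__).resolve().parents[1] / "scratch" / "sessions"
SEED = 20260926


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)

    homecage = SessionSpec(
        duration=1440.0,
        behavior_mode="homecage",
        seed=SEED,
        coherence_targets={
            ("hpc_l", "crus1"): 0.50,
            ("hpc_l", "lob6"): 0.50,
            ("hpc_l", "lob23"): 0.46,
        },
        line_noise_amplitude=0.2,
        artifact_rate=1.0,
        spike_units=[
            {"unit_id": "pc_locked", "base_rate": 40.0, "kappa": 2.0,
             "mu": float(np.deg2rad(231.0))},
            {"unit_id": "pc_flat", "base_rate": 40.0, "kappa": 0.0, "mu": 0.0},
        ],
    )
    bundle, _ = generate_session(homecage)
    write_session(bundle, OUT / "homecage", force=True)
    print(f"homecage: {len(bundle.signals)} LFP channels, "
          f"{sum(len(s) for s in bundle.spikes.values())} spikes")

    for i in range(3):
        spec = SessionSpec(
            duration=720.0,
            behavior_mode="linear_track",
            seed=SEED + 1 + i,
            coherence_targets={
                ("hpc_l", "crus1"): 0.46,
                ("hpc_l", "lob6"): 0.46,
                ("hpc_l", "lob23"): 0.46,
            },
            coherence_boost={"crus1": (0.65, (-60.0, -20.0))},
            line_noise_amplitude=0.2,
        )
        bundle, _ = generate_session(spec)
        write_session(bundle, OUT / f"track_s{i + 1}", force=True)
        print(f"track_s{i + 1}: {len(bundle.events['reward'])} rewards")

    print(f"sessions written under {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
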