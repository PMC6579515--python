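import numpy as np
import pytest

from thetalink.synthdata import SessionSpec, generate_session


@pytest.fixture(scope="session")
def homecage_session():
    """One 3-minute home-cage session with known coherence targets, artifacts
    and a phase-locked unit; shared across tests that only read it."""
    spec = SessionSpec(
        duration=180.0,
        behavior_mode="homecage",
        seed=11,
        coherence_targets={
            ("hpc_l", "crus1"): 0.5,
            ("hpc_l", "lob6"): 0.5,
            ("hpc_l", "lob23"): 0.46,
        },
        artifact_rate=1.0,
        spike_units=[
            {"unit_id": "locked", "base_rate": 20.0, "kappa": 2.0, "mu": np.deg2rad(231.0)},
            {"unit_id": "flat", "base_rate": 20.0, "kappa": 0.0, "mu": 0.0},
        ],
    )
    return generate_session(spec)


@pytest.fixture(scope="session")
def track_session():
    """One 6-minute goal-directed linear-track session."""
    spec = SessionSpec(
        duration=360.0,
        behavior_mode="linear_track",
        seed=13,
        coherence_targets={
            ("hpc_l", "crus1"): 0.46,
            ("hpc_l", "lob6"): 0.46,
            ("hpc_l", "lob23"): 0.46,
        },
        coherence_boost={"crus1": (0.65, (-60.0, -20.0))},
    )
    return generate_session(spec)
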