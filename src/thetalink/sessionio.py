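"""On-disk session layout and result tables.

A session is a directory with a YAML manifest (``manifest.yaml``) naming
each stream, its kind (lfp | emg | tracking | events | spikes), its file,
sample rate and units.  Continuous signals are flat little-endian float64
binaries (or CSV); tracking/events/spikes are CSV with columns
``time_s, x_cm, y_cm`` / ``time_s`` / ``unit_id, time_s``.  The manifest
carries SHA-256 checksums so round trips are verifiable.

Result tables are CSVs with a JSON sidecar recording every analysis
parameter and seed, so a re-run with identical inputs reproduces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    EventSeries,
    FormatError,
    SessionBundle,
    SignalTrace,
    SpikeTrain,
    TrackingTrace,
)

__all__ = ["read_session", "write_session", "write_results", "MANIFEST_NAME"]

MANIFEST_NAME = "manifest.yaml"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_session(bundle: SessionBundle, path: str | Path, force: bool = False) -> Path:
    """Lay out a session directory; returns the manifest path.

    Refuses to overwrite an existing manifest unless ``force`` is set.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    path.mkdir(parents=True, exist_ok=True)
    streams = []

    for label, sig in bundle.signals.items():
        fname = f"signal_{label}.bin"
        sig.values.astype("<f8").tofile(path / fname)
        streams.append(
            {
                "name": label,
                "kind": "lfp" if sig.units != "V_emg" else "emg",
                "path": fname,
                "format": "f8le",
                "sample_rate_hz": float(sig.sample_rate),
                "t0_s": float(sig.t0),
                "n_samples": int(sig.n),
                "units": sig.units,
                "sha256": None,  # filled below
            }
        )
        streams[-1]["sha256"] = _sha256(path / fname)

    if bundle.tracking is not None:
        fname = "tracking.csv"
        pd.DataFrame(
            {"time_s": bundle.tracking.times, "x_cm": bundle.tracking.x, "y_cm": bundle.tracking.y}
        ).to_csv(path / fname, index=False)
        streams.append(
            {
                "name": "tracking",
                "kind": "tracking",
                "path": fname,
                "format": "csv",
                "sample_rate_hz": float(bundle.tracking.source_rate),
                "units": "cm",
                "sha256": _sha256(path / fname),
            }
        )

    for name, ev in bundle.events.items():
        fname = f"events_{name}.csv"
        pd.DataFrame({"time_s": ev.times}).to_csv(path / fname, index=False)
        streams.append(
            {
                "name": name,
                "kind": "events",
                "path": fname,
                "format": "csv",
                "units": "s",
                "sha256": _sha256(path / fname),
            }
        )

    if bundle.spikes:
        fname = "spikes.csv"
        frames = [
            pd.DataFrame({"unit_id": uid, "time_s": train.times})
            for uid, train in sorted(bundle.spikes.items())
        ]
        pd.concat(frames, ignore_index=True).to_csv(path / fname, index=False)
        streams.append(
            {
                "name": "spikes",
                "kind": "spikes",
                "path": fname,
                "format": "csv",
                "units": "s",
                "sha256": _sha256(path / fname),
            }
        )

    manifest = {"streams": streams, "metadata": _jsonable(bundle.metadata)}
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def read_session(path: str | Path, lenient_events: bool = False) -> SessionBundle:
    """Load a session directory written by :func:`write_session`.

    Missing optional streams (tracking, events, spikes) yield absent
    fields.  A declared sample count inconsistent with the binary length,
    or unsorted event times (without ``lenient_events``), is a
    :class:`FormatError` naming the stream.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"missing manifest at {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    bundle = SessionBundle(metadata=manifest.get("metadata", {}))
    for st in manifest.get("streams", []):
        kind = st["kind"]
        fpath = path / st["path"]
        if not fpath.exists():
            raise FormatError(f"stream '{st['name']}': file {st['path']} missing")
        if kind in ("lfp", "emg"):
            if st.get("format", "f8le") == "f8le":
                vals = np.fromfile(fpath, dtype="<f8")
            else:
                vals = pd.read_csv(fpath).iloc[:, 0].to_numpy(dtype=float)
            declared = st.get("n_samples")
            if declared is not None and declared != vals.size:
                raise FormatError(
                    f"stream '{st['name']}': {vals.size} samples on disk but "
                    f"manifest declares {declared}"
                )
            bundle.signals[st["name"]] = SignalTrace(
                vals,
                sample_rate=float(st["sample_rate_hz"]),
                t0=float(st.get("t0_s", 0.0)),
                label=st["name"],
                units=st.get("units", ""),
            )
        elif kind == "tracking":
            df = pd.read_csv(fpath)
            bundle.tracking = TrackingTrace(
                times=df["time_s"].to_numpy(),
                x=df["x_cm"].to_numpy(),
                y=df["y_cm"].to_numpy() if "y_cm" in df else np.zeros(len(df)),
                source_rate=float(st.get("sample_rate_hz", 30.0)),
            )
        elif kind == "events":
            times = pd.read_csv(fpath)["time_s"].to_numpy(dtype=float)
            if times.size >= 2 and np.any(np.diff(times) < 0):
                if lenient_events:
                    times = np.sort(times)
                else:
                    raise FormatError(f"stream '{st['name']}': event times not sorted")
            bundle.events[st["name"]] = EventSeries(name=st["name"], times=times)
        elif kind == "spikes":
            df = pd.read_csv(fpath)
            for uid, grp in df.groupby("unit_id"):
                times = grp["time_s"].to_numpy(dtype=float)
                if times.size >= 2 and np.any(np.diff(times) <= 0):
                    if lenient_events:
                        times = np.sort(times)
                    else:
                        raise FormatError(f"spike stream unit '{uid}': times not sorted")
                bundle.spikes[str(uid)] = SpikeTrain(unit_id=str(uid), times=times)
        else:
            raise FormatError(f"stream '{st['name']}': unknown kind '{kind}'")
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_results(tables: dict[str, pd.DataFrame], path: str | Path,
                  params: dict | None = None) -> None:
    """Emit result tables as CSV plus one JSON parameter sidecar.

    CSV formatting is pinned (fixed float representation, no index) so a
    deterministic analysis reproduces byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(path / f"{name}.csv", index=False, float_format="%.10g")
    sidecar = {"parameters": _jsonable(params or {}), "tables": sorted(tables)}
    (path / "parameters.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
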