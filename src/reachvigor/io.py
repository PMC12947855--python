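"""Readers and writers for the trial-record CSV and the HDF5 trace container.

CSV dialect: UTF-8, comma separators, header row, '.' decimal; times in ms,
velocities in m/s.  Unknown columns round-trip untouched.  The HDF5 container
stores one group per trial with float32 channels (x, y, radial_pos,
radial_vel) and event timestamps as attributes; a file-level schema version
guards against silent format drift.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .kinematics import VelocityTrace

SCHEMA_VERSION = "1"
_REQUIRED_COLUMNS = ("subject", "block", "trial", "trial_type", "target",
                     "reward", "familiarization")


class SchemaError(ValueError):
    """Raised on a container/table that does not match the expected schema."""


def write_trial_records(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"trial table missing required columns: {missing}")
    records.to_csv(path, index=False, float_format="%.6f")
    return path


def read_trial_records(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as err:  # carries the offending line number
        raise SchemaError(f"malformed trial CSV {path}: {err}") from err
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is not a trial table (missing {missing})")
    df["familiarization"] = df["familiarization"].astype(bool)
    return df


def write_traces(traces: dict, path: str | Path) -> Path:
    """Store traces keyed by (subject, trial-row) tuples or strings."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for key, tr in traces.items():
            name = key if isinstance(key, str) else "_".join(str(k) for k in key)
            g = f.create_group(name)
            for ch in ("x", "y", "radial_pos"):
                g.create_dataset(ch, data=np.asarray(getattr(tr, ch), np.float32),
                                 compression="gzip", compression_opts=4)
            if tr.radial_vel is not None:
                g.create_dataset("radial_vel",
                                 data=np.asarray(tr.radial_vel, np.float32),
                                 compression="gzip", compression_opts=4)
            for ev, t in tr.events.items():
                g.attrs[f"event_{ev}"] = float(t)
    return path


def read_traces(path: str | Path) -> dict[str, VelocityTrace]:
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"{path}: trace container schema "
                f"{f.attrs.get('schema_version')!r} != {SCHEMA_VERSION!r}")
        out = {}
        for name, g in f.items():
            events = {k[len("event_"):]: float(v) for k, v in g.attrs.items()
                      if k.startswith("event_")}
            if "cue" not in events:
                raise SchemaError(f"{path}:{name} has no cue event")
            x = np.asarray(g["x"], float)
            out[name] = VelocityTrace(
                t=np.arange(x.size, dtype=float),
                x=x, y=np.asarray(g["y"], float),
                radial_pos=np.asarray(g["radial_pos"], float),
                radial_vel=(np.asarray(g["radial_vel"], float)
                            if "radial_vel" in g else None),
                events=events)
    return out


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
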