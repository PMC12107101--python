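"""Trace and configuration I/O.

Traces travel as CSV with columns ``time_s`` and ``fluorescence_norm`` plus
an optional JSON sidecar holding provenance (model, parameters, seed).
Configurations are YAML or JSON mappings mirroring the parameter dataclass
field names; unknown keys are rejected.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Type, TypeVar

import numpy as np
import pandas as pd
import yaml

from .trace import DecayTrace

__all__ = [
    "read_trace",
    "write_trace",
    "load_config",
    "build_dataclass",
    "write_manifest",
]

TRACE_COLUMNS = ("time_s", "fluorescence_norm")

T = TypeVar("T")


class TraceParseError(ValueError):
    """A trace file violates the expected format."""


def read_trace(path: str | Path, renormalize: bool = False) -> DecayTrace:
    """Read a two-column decay trace, validating and sorting by time.

    Raises :class:`TraceParseError` for missing columns, NaNs, negative or
    duplicate times.  With ``renormalize`` the values are rescaled to the
    first sample.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing column(s) {missing}; expected {TRACE_COLUMNS}")
    df = df[list(TRACE_COLUMNS)]
    if df.isna().any().any():
        raise TraceParseError(f"{path}: NaN values in trace")
    df = df.sort_values("time_s", kind="stable")
    t = df["time_s"].to_numpy(float)
    v = df["fluorescence_norm"].to_numpy(float)
    if t.size and t[0] < 0:
        raise TraceParseError(f"{path}: negative time value {t[0]}")
    if np.any(np.diff(t) <= 0):
        raise TraceParseError(f"{path}: duplicate time values")
    meta: dict[str, Any] = {"path": str(path)}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    trace = DecayTrace(t, v, meta)
    return trace.normalize() if renormalize else trace


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_trace(trace: DecayTrace, path: str | Path, sidecar: bool = True) -> Path:
    """Write a trace as CSV (+ JSON metadata sidecar next to it)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": trace.times, "fluorescence_norm": trace.values}).to_csv(
        path, index=False
    )
    if sidecar and trace.meta:
        path.with_suffix(".json").write_text(json.dumps(_jsonable(trace.meta), indent=1))
    return path


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


def build_dataclass(cls: Type[T], mapping: dict[str, Any]) -> T:
    """Instantiate a parameter dataclass, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - names)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {unknown}; valid keys: {sorted(names)}")
    return cls(**mapping)


def write_manifest(out_dir: str | Path, config: dict[str, Any], seed: int | None) -> Path:
    """Record the resolved configuration, its hash, the seed, and versions."""
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = _jsonable(config)
    blob = json.dumps(payload, sort_keys=True).encode()
    manifest = {
        "config": payload,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "mantchase": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
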