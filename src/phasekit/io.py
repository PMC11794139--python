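"""Shared table readers, report writers and run configuration.

Conventions: all user-facing lengths are in um or nm, times in seconds
(minutes accepted where a column/key name says so), forces in nN,
temperatures in K; SI conversion happens only inside computations. Reports
are JSON with an accompanying tidy CSV so downstream plotting never has to
parse the structured file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import SchemaError, ValidationError

__all__ = ["RunConfig", "read_table", "write_report", "read_report", "file_checksum"]

#: Column schemas per stage: name -> (required columns, dtypes).
STAGE_SCHEMAS = {
    "fusion_trace": {"event_id": str, "time_s": float, "aspect_ratio": float},
    "fusion_events": {"tau_s": float, "l_um": float},
    "frap_trace": {"time_s": float, "roi": float, "ref": float},
    "onset_trace": {"time_min": float, "intensity": float},
    "phase_observations": {"axis1": float, "axis2": float, "call": bool},
}

_KNOWN_CONFIG_KEYS = {
    "stage", "input_path", "output_path", "seed", "log_level",
    "pixel_size_um", "frame_interval_s", "temperature_K",
    "omega_sq_um2", "hydrodynamic_radius_m", "tip_radius_nm",
    "tail_fraction", "ph", "window", "z_threshold", "min_run",
    "length_convention", "omega_convention", "contact_area_model",
    "inverse_capillary_velocity_s_per_um",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated stage configuration; unknown keys are rejected."""

    stage: str
    input_path: str | None = None
    output_path: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    parameters: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.parameters) - _KNOWN_CONFIG_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        stage = data.pop("stage", None)
        if stage is None:
            raise ValidationError("config must name a stage")
        return cls(
            stage=stage,
            input_path=data.pop("input_path", None),
            output_path=data.pop("output_path", None),
            seed=int(data.pop("seed", 0)),
            log_level=data.pop("log_level", "INFO"),
            parameters=data,
        )


def read_table(path: str | Path, schema: str | Mapping[str, type]) -> pd.DataFrame:
    """Read a delimited text table (comma or tab, auto-detected) and validate.

    ``schema`` is either a stage name from :data:`STAGE_SCHEMAS` or a
    mapping column -> dtype. Missing required columns raise
    :class:`SchemaError` naming them; extra columns are kept (callers may
    ignore them) — they are harmless metadata.
    """
    if isinstance(schema, str):
        try:
            schema = STAGE_SCHEMAS[schema]
        except KeyError as exc:
            raise SchemaError(f"unknown schema {schema!r}") from exc
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = set(schema) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    for col, typ in schema.items():
        try:
            if typ is bool:
                if df[col].dtype != bool:
                    df[col] = (
                        df[col].astype(str).str.strip().str.lower()
                        .map({"true": True, "false": False, "1": True, "0": False,
                              "yes": True, "no": False})
                    )
                    if df[col].isna().any():
                        raise ValueError("unrecognised boolean value")
            elif typ is float:
                df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
            elif typ is str:
                df[col] = df[col].astype(str)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {col!r} not coercible to "
                              f"{typ.__name__} ({exc})") from exc
    return df


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file's bytes, for report provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(
    results: Any,
    path: str | Path,
    parameters: Mapping[str, Any] | None = None,
    seed: int | None = None,
    input_paths: Mapping[str, str] | None = None,
) -> Path:
    """Write a structured JSON report plus a tidy CSV table.

    ``results`` is any object exposing ``to_report_dict()`` (all phasekit
    Results do), a mapping, or a list of either. The report records the
    package version, the seed, every parameter in force (including the
    length-/omega-convention switches a caller passes) and SHA-256
    checksums of the input files. A flat ``metric,value`` CSV is written
    alongside (same stem, ``.csv``).
    """
    path = Path(path)

    def as_dict(r: Any) -> dict:
        return dict(r.to_report_dict()) if hasattr(r, "to_report_dict") else dict(r)

    if isinstance(results, (list, tuple)):
        payload = [as_dict(r) for r in results]
    else:
        payload = as_dict(results)
    report = {
        "phasekit_version": __version__,
        "seed": seed,
        "parameters": _jsonable(dict(parameters or {})),
        "input_checksums": {
            name: file_checksum(p) for name, p in (input_paths or {}).items()
        },
        "results": _jsonable(payload),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")

    rows = []
    entries = payload if isinstance(payload, list) else [payload]
    for i, entry in enumerate(entries):
        for key, val in entry.items():
            if isinstance(val, (int, float, str)) or val is None:
                rows.append({"record": i, "metric": key, "value": val})
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)
    return path


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
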