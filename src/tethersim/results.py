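"""Result serialization: tidy CSV tables and JSON run manifests."""

from __future__ import annotations

import dataclasses
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["RunManifest", "write_results", "dose_response_frame", "switch_frame"]

SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit.

    ``parameters`` holds the fully resolved parameter set (including table
    defaults), ``derived`` any computed quantities worth auditing (converted
    rates, calibrated epsilon/lambda, molecule counts).
    """

    command: str
    parameters: dict[str, Any]
    base_seed: int
    derived: dict[str, Any] = dataclasses.field(default_factory=dict)
    package_version: str = __version__
    schema_version: int = SCHEMA_VERSION
    created: str = ""
    python: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()
        if not self.python:
            self.python = platform.python_version()

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonify)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(
    frame: pd.DataFrame,
    path: str | Path,
    fmt: str = "csv",
    manifest: RunManifest | None = None,
) -> list[Path]:
    """Write a tidy result table (one observation per row) plus manifest.

    Floats are written at full round-trip precision.  Returns the list of
    files written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt == "csv":
        frame.to_csv(path, index=False)
        written.append(path)
    elif fmt == "json":
        frame.to_json(path, orient="records", indent=2, double_precision=15)
        written.append(path)
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
    if manifest is not None:
        mpath = path.with_suffix(".manifest.json")
        manifest.to_json(mpath)
        written.append(mpath)
    return written


def dose_response_frame(result) -> pd.DataFrame:
    """Tidy frame for a DoseResponseResult: one row per grid point."""
    return pd.DataFrame(
        {
            "concentration": result.concentrations,
            "fraction": result.fractions,
            "sem": result.sems,
            "n_trajectories": result.n_trajectories,
            "direction": result.direction,
            "half_max": result.half_max,
        }
    )


def switch_frame(results: dict) -> pd.DataFrame:
    """Tidy frame for switch_experiment output keyed by (L, D)."""
    rows = [
        {"reach_nm": L, "D_um2_s": D, "fraction": f, "sem": s}
        for (L, D), (f, s) in sorted(results.items())
    ]
    return pd.DataFrame(rows)
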