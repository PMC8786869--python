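"""Readers, writers, unit conversions and run configuration.

The canonical on-disk measurement format is a comma-separated, UTF-8 CSV
with header ``spheroid_id,cell_line,initial_cells,time_days,measurement,
radius_um`` and measurement labels exactly "outer" | "inhibited" |
"necrotic".  Times are days since the end of spheroid formation (day 0);
inputs are assumed pre-aligned to that clock.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .evaluate import DesignReport
from .inference import MLEResult, ProfileCurve
from .observation import CSV_COLUMNS, MEASUREMENT_TYPES, MeasurementTable

__all__ = [
    "read_measurements",
    "write_measurements",
    "area_to_radius",
    "RunConfig",
    "write_profile_csv",
    "write_json",
]

logger = logging.getLogger("spheroidfit")


def read_measurements(path, column_map: Mapping[str, str] | None = None
                      ) -> MeasurementTable:
    """Load a measurement CSV, optionally renaming columns first.

    ``column_map`` maps on-disk column names to the canonical schema, for
    files deposited with different headers.  Rows with non-finite time or
    radius are dropped with a logged count (excluded measurements); unknown
    measurement labels are an error naming the offending row.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["spheroid_id", "time_days", "measurement", "radius_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_type = ~df["measurement"].isin(MEASUREMENT_TYPES)
    if bad_type.any():
        row = int(df.index[bad_type][0])
        raise ValueError(
            f"{path}: unknown measurement label "
            f"{df.loc[row, 'measurement']!r} in row {row + 2} "
            f"(expected one of {MEASUREMENT_TYPES})")
    vals = pd.to_numeric(df["radius_um"], errors="coerce")
    times = pd.to_numeric(df["time_days"], errors="coerce")
    keep = np.isfinite(vals) & np.isfinite(times)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-finite values",
                       path, n_dropped)
        df = df[keep].reset_index(drop=True)
    return MeasurementTable(df)


def write_measurements(table: MeasurementTable, path) -> None:
    """Write a table in the canonical column order (extra columns kept)."""
    df = table.data
    cols = [c for c in CSV_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def area_to_radius(area):
    """Equivalent radius of a projected area: r = sqrt(A / pi) [um].

    Converts automated-imaging area masks (um^2) to the radius of the
    circle of equal area.  Accepts scalars or arrays; negative areas are a
    domain error.
    """
    a = np.asarray(area, dtype=float)
    if np.any(a < 0):
        raise ValueError("area must be non-negative")
    r = np.sqrt(a / np.pi)
    return float(r) if np.isscalar(area) or a.ndim == 0 else r


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run; serialised into every output
    directory so results can be regenerated exactly."""

    command: str = ""
    design: str = "design3_resA"
    seed: int = 0
    grid_size: int = 40
    n_starts: int = 10
    threshold: float = 0.15
    bounds: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    theta: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


def write_profile_csv(curve: ProfileCurve, path) -> None:
    """Profile curve as CSV: grid value, normalised likelihood, nuisance."""
    from .model import PARAM_NAMES
    nuis_names = [p for p in PARAM_NAMES if p != curve.parameter]
    df = pd.DataFrame({curve.parameter: curve.grid,
                       "profile_likelihood": curve.Lp})
    for j, n in enumerate(nuis_names):
        df[f"nuisance_{n}"] = curve.nuisance[:, j]
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    """Serialise an MLE result, design report or plain mapping to JSON."""
    if isinstance(obj, (MLEResult, DesignReport)):
        obj = obj.to_dict()
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
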