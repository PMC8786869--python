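"""Synthetic measurement tables with realistic experimental structure.

Datasets are Greenspan trajectories observed under a Design — a choice of
measurement types (outer / necrotic / inhibited), sampling days and
replicate counts — with additive zero-mean Gaussian noise per type.  Noise
is drawn from independent substreams keyed by (seed, type, day) so that
adding a measurement type to a design never perturbs the values of the
types already present; a Design-1 table is byte-identical to the outer
subset of the Design-3 table for the same seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ReducedParameters, Trajectory, simulate
from .observation import MEASUREMENT_TYPES, MeasurementTable, NoiseModel

__all__ = [
    "Design",
    "GeneratorConfig",
    "RESOLUTIONS",
    "DESIGN_TYPES",
    "make_design",
    "generate_dataset",
    "truth_record",
]

#: sampling days of the three temporal resolutions
RESOLUTIONS: dict[str, tuple[int, ...]] = {
    "A": (1, 3, 8, 12, 17),
    "B": (1, 3, 6, 8, 10, 12, 14, 17, 19),
    "C": tuple(range(20)),
}

#: measurement types of the three designs (increasing experimental effort)
DESIGN_TYPES: dict[int, tuple[str, ...]] = {
    1: ("outer",),
    2: ("outer", "necrotic"),
    3: ("outer", "necrotic", "inhibited"),
}

#: default true parameters for synthetic studies: a 5000-cell-seeded-like
#: spheroid whose trajectory reaches phase 3 well inside a 20-day experiment
DEFAULT_THETA = ReducedParameters(Ro0=120.0, Rc=150.0, s=0.3, gamma=1.0,
                                  Q=0.7)

#: default noise: ~10 um standard deviations, internal types noisier than
#: the automated outer-radius imaging
DEFAULT_NOISE = NoiseModel(sigma2_outer=81.0, sigma2_inhibited=144.0,
                           sigma2_necrotic=144.0)

_TYPE_CODE = {t: i for i, t in enumerate(MEASUREMENT_TYPES)}
_NAME_RE = re.compile(r"^design([123])_res([ABC])$")


@dataclass(frozen=True)
class Design:
    """A measurement plan: what is measured, when, and how many times."""

    name: str
    types: tuple[str, ...]
    times: Mapping[str, tuple[float, ...]]
    replicates: Mapping[str, int]
    seeding_cells: int = 5000

    def __post_init__(self):
        if not self.types:
            raise ValueError("design must include at least one type")
        for t in self.types:
            if t not in MEASUREMENT_TYPES:
                raise ValueError(f"unknown measurement type {t!r}")
            if not self.times.get(t):
                raise ValueError(f"design has no observation times for {t!r}")
            if self.replicates.get(t, 0) < 1:
                raise ValueError(f"design needs >= 1 replicate for {t!r}")

    def all_times(self) -> np.ndarray:
        return np.unique(np.concatenate(
            [np.asarray(self.times[t], dtype=float) for t in self.types]))

    def n_rows(self) -> int:
        return sum(len(self.times[t]) * self.replicates[t]
                   for t in self.types)


def make_design(name: str | None = None, *,
                types: Sequence[str] | None = None,
                times: Mapping[str, Sequence[float]] | None = None,
                replicates: Mapping[str, int] | None = None,
                outer_replicates: int = 24,
                internal_replicates: int = 10,
                seeding_cells: int = 5000) -> Design:
    """Build a design, either a named built-in or a custom specification.

    Built-in names are ``design{1,2,3}_res{A,B,C}``: Design 1 observes only
    the outer radius, 2 adds the necrotic radius, 3 adds the inhibited
    radius; resolutions A/B/C are the sparse/medium/daily day schedules.
    Outer measurements default to 24 replicates (one imaging plate of 24
    spheroids followed longitudinally); necrotic and inhibited measurements
    are destructive end-point measurements with a configurable per-day
    count (default 10).
    """
    if name is not None and types is None:
        m = _NAME_RE.match(name)
        if not m:
            raise ValueError(
                f"unknown design {name!r}; expected design<1|2|3>_res<A|B|C>")
        dtypes = DESIGN_TYPES[int(m.group(1))]
        days = tuple(float(d) for d in RESOLUTIONS[m.group(2)])
        times = {t: days for t in dtypes}
        replicates = {t: (outer_replicates if t == "outer"
                          else internal_replicates) for t in dtypes}
        return Design(name=name, types=dtypes, times=times,
                      replicates=replicates, seeding_cells=seeding_cells)
    if types is None:
        raise ValueError("provide a built-in name or a custom type set")
    dtypes = tuple(types)
    times = {t: tuple(float(x) for x in (times or {}).get(t, ()))
             for t in dtypes}
    replicates = {t: int((replicates or {}).get(
        t, outer_replicates if t == "outer" else internal_replicates))
        for t in dtypes}
    return Design(name=name or "custom", types=dtypes, times=times,
                  replicates=replicates, seeding_cells=seeding_cells)


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to regenerate a synthetic dataset exactly."""

    theta: ReducedParameters = DEFAULT_THETA
    noise: NoiseModel = DEFAULT_NOISE
    design: Design = field(default_factory=lambda: make_design("design3_resA"))
    seed: int = 0
    clip_negative: bool = True

    def to_dict(self) -> dict:
        return {
            "theta": {n: float(getattr(self.theta, n))
                      for n in ("Ro0", "Rc", "s", "gamma", "Q")},
            "noise": {f"sigma2_{t}": getattr(self.noise, f"sigma2_{t}")
                      for t in MEASUREMENT_TYPES},
            "design": {
                "name": self.design.name,
                "types": list(self.design.types),
                "times": {t: list(self.design.times[t])
                          for t in self.design.types},
                "replicates": {t: self.design.replicates[t]
                               for t in self.design.types},
                "seeding_cells": self.design.seeding_cells,
            },
            "seed": self.seed,
            "clip_negative": self.clip_negative,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        des = d["design"]
        design = Design(name=des["name"], types=tuple(des["types"]),
                        times={t: tuple(v) for t, v in des["times"].items()},
                        replicates=dict(des["replicates"]),
                        seeding_cells=int(des.get("seeding_cells", 5000)))
        return cls(theta=ReducedParameters(**d["theta"]),
                   noise=NoiseModel(**d["noise"]), design=design,
                   seed=int(d["seed"]),
                   clip_negative=bool(d.get("clip_negative", True)))


def _stream(seed: int, mtype: str, day: float) -> np.random.Generator:
    # independent substream per (seed, type, day); day keyed at micro-day
    # resolution so non-integer schedules remain distinct
    key = [int(seed) % (2 ** 31), _TYPE_CODE[mtype],
           int(round(float(day) * 1e6))]
    return np.random.default_rng(np.random.SeedSequence(key))


def _truth_by_type(config: GeneratorConfig):
    design = config.design
    traj = simulate(config.theta, design.all_times())
    lookup = {"outer": traj.Ro, "inhibited": traj.Ri, "necrotic": traj.Rn}
    t_all = traj.times
    truth = {}
    for mtype in design.types:
        days = np.asarray(design.times[mtype], dtype=float)
        truth[mtype] = lookup[mtype][np.searchsorted(t_all, days)]
    return traj, truth


def _rows(config: GeneratorConfig, noisy: bool):
    design = config.design
    _, truth = _truth_by_type(config)
    records = []
    for mtype in design.types:
        n_rep = design.replicates[mtype]
        sd = config.noise.sd(mtype) if noisy else 0.0
        for j, day in enumerate(design.times[mtype]):
            mu = truth[mtype][j]
            eps = (_stream(config.seed, mtype, day).normal(0.0, sd, n_rep)
                   if noisy and sd > 0 else np.zeros(n_rep))
            vals = mu + eps
            if config.clip_negative:
                vals = np.maximum(vals, 0.0)
            for r in range(n_rep):
                if mtype == "outer":
                    sid = f"inc_{r + 1:02d}"   # longitudinal imaging plate
                else:
                    sid = f"{mtype[:3]}_d{day:g}_{r + 1:02d}"  # end point
                records.append((sid, "synthetic", design.seeding_cells,
                                float(day), mtype, float(vals[r])))
    return pd.DataFrame.from_records(
        records, columns=["spheroid_id", "cell_line", "initial_cells",
                          "time_days", "measurement", "radius_um"])


def generate_dataset(config: GeneratorConfig) -> MeasurementTable:
    """Noisy synthetic measurement table for one design and seed.

    Row count is sum over types of (number of days x replicates); identical
    configs produce identical tables.
    """
    return MeasurementTable(_rows(config, noisy=True))


def truth_record(config: GeneratorConfig
                 ) -> tuple[Trajectory, MeasurementTable]:
    """The noiseless counterpart: reference trajectory at the design's
    times plus a zero-noise table aligned row-for-row with the noisy one."""
    traj, _ = _truth_by_type(config)
    return traj, MeasurementTable(_rows(config, noisy=False))
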