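"""Gaussian observation model linking radius measurements to the model.

Measurements of the outer, inhibited and necrotic radii are treated as
independent noisy observations of the deterministic trajectory: additive
zero-mean Gaussian noise with one variance per measurement type.  The
variances are plug-in constants estimated by pooling replicate sample
variances across time points, not free parameters of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import ReducedParameters, outer_radii

__all__ = [
    "MEASUREMENT_TYPES",
    "MeasurementTable",
    "NoiseModel",
    "LikelihoodResult",
    "pooled_variance",
    "log_likelihood",
    "LikelihoodEvaluator",
]

MEASUREMENT_TYPES = ("outer", "inhibited", "necrotic")

#: canonical CSV schema (see io.read_measurements / write_measurements)
CSV_COLUMNS = ("spheroid_id", "cell_line", "initial_cells", "time_days",
               "measurement", "radius_um")

_REQUIRED = ("spheroid_id", "time_days", "measurement", "radius_um")


@dataclass
class MeasurementTable:
    """Long-format radius observations.

    One row per measurement: (spheroid_id, time_days, measurement,
    radius_um) with optional metadata columns (cell_line, initial_cells).
    Zero radii are valid observations — an absent inhibited or necrotic
    region is recorded as radius 0.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        bad = ~df["measurement"].isin(MEASUREMENT_TYPES)
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"unknown measurement type {df.loc[row, 'measurement']!r} "
                f"in row {row}; expected one of {MEASUREMENT_TYPES}")
        vals = pd.to_numeric(df["radius_um"], errors="coerce")
        times = pd.to_numeric(df["time_days"], errors="coerce")
        if not np.isfinite(vals).all() or not np.isfinite(times).all():
            raise ValueError("non-finite time or radius values in table")
        if (vals < 0).any() or (times < 0).any():
            raise ValueError("times and radii must be non-negative")
        df["radius_um"] = vals.astype(float)
        df["time_days"] = times.astype(float)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def types(self) -> tuple[str, ...]:
        present = self.data["measurement"].unique()
        return tuple(t for t in MEASUREMENT_TYPES if t in present)

    def times(self) -> np.ndarray:
        return np.unique(self.data["time_days"].to_numpy())

    def subset(self, types: Iterable[str]) -> "MeasurementTable":
        types = tuple(types)
        return MeasurementTable(
            self.data[self.data["measurement"].isin(types)]
            .reset_index(drop=True).copy())

    def n_obs(self) -> dict[str, int]:
        counts = self.data["measurement"].value_counts()
        return {t: int(counts.get(t, 0)) for t in self.types}

    @classmethod
    def from_records(cls, records) -> "MeasurementTable":
        return cls(pd.DataFrame.from_records(records))


@dataclass(frozen=True)
class NoiseModel:
    """Per-type observation variances (um^2)."""

    sigma2_outer: float | None = None
    sigma2_inhibited: float | None = None
    sigma2_necrotic: float | None = None

    def variance(self, mtype: str) -> float:
        v = getattr(self, f"sigma2_{mtype}")
        if v is None or v <= 0:
            raise ValueError(
                f"no positive observation variance configured for "
                f"{mtype!r} measurements")
        return float(v)

    def sd(self, mtype: str) -> float:
        """Noise standard deviation for generation; zero is allowed here
        (an exact, noise-free design), unlike in the likelihood."""
        v = getattr(self, f"sigma2_{mtype}")
        if v is None or v < 0:
            raise ValueError(f"no variance configured for {mtype!r}")
        return float(np.sqrt(v))

    @classmethod
    def from_table(cls, table: MeasurementTable,
                   overrides: Mapping[str, float] | None = None
                   ) -> "NoiseModel":
        """Pooled-variance plug-in estimates for every type in the table."""
        overrides = dict(overrides or {})
        kw = {}
        for t in table.types:
            v = overrides.get(t)
            if v is None:
                v = pooled_variance(table, t)
            kw[f"sigma2_{t}"] = float(v)
        return cls(**kw)


@dataclass(frozen=True)
class LikelihoodResult:
    """Log-likelihood of a table, with observation counts per type."""

    loglik: float
    n_obs: Mapping[str, int]

    def normalised(self, max_loglik: float) -> float:
        """Likelihood relative to a supplied maximum (1 at the maximum)."""
        return float(np.exp(self.loglik - max_loglik))


def pooled_variance(table: MeasurementTable, mtype: str) -> float:
    """Pooled sample variance of one measurement type across time points.

    sum_j (n_j - 1) s_j^2 / sum_j (n_j - 1) over time points j with at
    least two replicates (s_j^2 the unbiased within-time sample variance);
    time points with a single replicate carry no variance information and
    are excluded.
    """
    sub = table.data[table.data["measurement"] == mtype]
    num = 0.0
    dof = 0
    for _, grp in sub.groupby("time_days"):
        n = len(grp)
        if n >= 2:
            num += (n - 1) * grp["radius_um"].var(ddof=1)
            dof += n - 1
    if dof == 0:
        raise ValueError(
            f"cannot pool variances for {mtype!r}: no time point has >= 2 "
            "replicates; supply a variance explicitly")
    return float(num / dof)


class LikelihoodEvaluator:
    """Pre-grouped likelihood of a fixed table under a fixed noise model.

    Building the evaluator once per fit avoids re-grouping the DataFrame on
    every optimiser step: observations are flattened into per-type arrays
    indexed into the sorted union of observation times, and each likelihood
    evaluation is a single trajectory solve plus vectorised residuals.
    """

    def __init__(self, table: MeasurementTable, noise: NoiseModel, *,
                 include_zero_internal: bool = True,
                 rtol: float = 1e-6, atol: float = 1e-6):
        df = table.data
        if not include_zero_internal:
            keep = (df["measurement"] == "outer") | (df["radius_um"] > 0)
            df = df[keep]
        if df.empty:
            raise ValueError("empty measurement table")
        self.times = np.unique(df["time_days"].to_numpy())
        self.rtol = rtol
        self.atol = atol
        self._groups = []
        self.n_obs: dict[str, int] = {}
        self._const = 0.0
        for mtype in MEASUREMENT_TYPES:
            sub = df[df["measurement"] == mtype]
            if sub.empty:
                continue
            sigma2 = noise.variance(mtype)
            idx = np.searchsorted(self.times, sub["time_days"].to_numpy())
            vals = sub["radius_um"].to_numpy()
            self._groups.append((mtype, idx, vals, sigma2))
            self.n_obs[mtype] = len(sub)
            self._const -= 0.5 * len(sub) * np.log(2.0 * np.pi * sigma2)

    def loglik(self, params: ReducedParameters) -> float:
        Ro, Ri, Rn = outer_radii(params, self.times,
                                 rtol=self.rtol, atol=self.atol)
        pred = {"outer": Ro, "inhibited": Ri, "necrotic": Rn}
        ll = self._const
        for mtype, idx, vals, sigma2 in self._groups:
            r = vals - pred[mtype][idx]
            ll -= 0.5 * float(r @ r) / sigma2
        return ll

    def __call__(self, params: ReducedParameters) -> LikelihoodResult:
        return LikelihoodResult(loglik=self.loglik(params),
                                n_obs=dict(self.n_obs))


def log_likelihood(params: ReducedParameters, table: MeasurementTable,
                   noise: NoiseModel, *,
                   include_zero_internal: bool = True) -> LikelihoodResult:
    """Gaussian log-likelihood of a measurement table given parameters.

    The trajectory is solved once at the union of observation times; each
    row contributes a normal log-density of its residual with its type's
    variance.  ``include_zero_internal=False`` drops zero-valued inhibited/
    necrotic rows (pre-onset "absence" observations) from the likelihood.
    """
    ev = LikelihoodEvaluator(table, noise,
                             include_zero_internal=include_zero_internal)
    return ev(params)
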