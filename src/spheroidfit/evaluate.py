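"""Quantitative comparison of experimental designs.

For a measurement table conforming to one design, run the full calibration
(MLE plus profile likelihood for each of the five parameters), summarise
per-parameter confidence intervals, widths and identifiability, and check
the fitted model predictively against held-out data — including prediction
across seeding sizes by swapping only the initial radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .inference import (DEFAULT_THRESHOLD, ConfidenceInterval, MLEResult,
                        ParameterBounds, ProfileCurve, fit_mle, profile)
from .model import PARAM_NAMES, ReducedParameters, outer_radii
from .observation import MeasurementTable, NoiseModel

__all__ = [
    "DesignReport",
    "PredictiveCheck",
    "evaluate_design",
    "predictive_check",
    "cross_size_prediction",
]


@dataclass
class PredictiveCheck:
    """Residuals of model predictions against a (held-out) table, split at
    the last fitted time into the fitted range and the extrapolated range."""

    residuals: pd.DataFrame     # time_days, measurement, observed, predicted,
                                # residual, window
    rmse: dict                  # {(type, window): rmse}

    def rmse_for(self, mtype: str, window: str = "fitted") -> float | None:
        return self.rmse.get((mtype, window))


@dataclass
class DesignReport:
    """Calibration summary for one design: MLE, per-parameter CI and
    identifiability, and optional predictive residual summaries."""

    design_name: str
    mle: MLEResult
    profiles: Mapping[str, ProfileCurve]
    cis: Mapping[str, ConfidenceInterval]
    threshold: float
    predictive: PredictiveCheck | None = None

    @property
    def identifiable(self) -> dict[str, bool]:
        """A parameter is identifiable when both CI endpoints are closed,
        i.e. the profile crosses the threshold strictly inside the bounds."""
        return {p: not (ci.open_lo or ci.open_hi)
                for p, ci in self.cis.items()}

    @property
    def widths(self) -> dict[str, float | None]:
        return {p: ci.width for p, ci in self.cis.items()}

    def to_dict(self) -> dict:
        out = {
            "design": self.design_name,
            "threshold": self.threshold,
            "mle": self.mle.to_dict(),
            "parameters": {},
        }
        for p, ci in self.cis.items():
            out["parameters"][p] = {
                "ci_lo": ci.lo, "ci_hi": ci.hi,
                "open_lo": ci.open_lo, "open_hi": ci.open_hi,
                "width": ci.width,
                "identifiable": not (ci.open_lo or ci.open_hi),
            }
        if self.predictive is not None:
            out["predictive_rmse"] = {
                f"{t}:{w}": v for (t, w), v in self.predictive.rmse.items()}
        return out


def evaluate_design(table: MeasurementTable, noise: NoiseModel,
                    bounds: ParameterBounds | None = None, *,
                    design_name: str = "unnamed",
                    grid_size: int = 40, n_starts: int = 10,
                    seed: int | None = None,
                    threshold: float = DEFAULT_THRESHOLD,
                    holdout: MeasurementTable | None = None,
                    include_zero_internal: bool = True) -> DesignReport:
    """Full identifiability analysis of one design's data."""
    bounds = bounds or ParameterBounds()
    mle = fit_mle(table, noise, bounds, n_starts=n_starts, seed=seed,
                  include_zero_internal=include_zero_internal)
    profiles = {}
    cis = {}
    for p in PARAM_NAMES:
        curve = profile(p, table, noise, bounds, grid_size=grid_size,
                        mle=mle, seed=seed, threshold=threshold,
                        include_zero_internal=include_zero_internal)
        profiles[p] = curve
        cis[p] = curve.ci
    pred = predictive_check(mle, holdout) if holdout is not None else None
    return DesignReport(design_name=design_name, mle=mle, profiles=profiles,
                        cis=cis, threshold=threshold, predictive=pred)


def _residual_summary(theta: ReducedParameters, table: MeasurementTable,
                      split_time: float | None) -> PredictiveCheck:
    df = table.data
    t_union = np.unique(df["time_days"].to_numpy())
    Ro, Ri, Rn = outer_radii(theta, t_union)
    pred_lookup = {"outer": Ro, "inhibited": Ri, "necrotic": Rn}
    idx = np.searchsorted(t_union, df["time_days"].to_numpy())
    pred = np.array([pred_lookup[m][i]
                     for m, i in zip(df["measurement"], idx)])
    obs = df["radius_um"].to_numpy()
    if split_time is None:
        window = np.full(len(df), "fitted")
    else:
        window = np.where(df["time_days"].to_numpy() <= split_time,
                          "fitted", "extrapolated")
    res = pd.DataFrame({
        "time_days": df["time_days"].to_numpy(),
        "measurement": df["measurement"].to_numpy(),
        "observed": obs,
        "predicted": pred,
        "residual": obs - pred,
        "window": window,
    })
    rmse = {}
    for (m, w), grp in res.groupby(["measurement", "window"]):
        rmse[(m, w)] = float(np.sqrt(np.mean(grp["residual"] ** 2)))
    return PredictiveCheck(residuals=res, rmse=rmse)


def predictive_check(mle: MLEResult, full_table: MeasurementTable,
                     fitted_until: float | None = None) -> PredictiveCheck:
    """Simulate at the MLE over a full table's times and summarise
    residuals, split into the fitted window (times up to the last time used
    in the fit) and the extrapolated window beyond it."""
    if fitted_until is None:
        fitted_until = mle.max_fit_time
    return _residual_summary(mle.theta_hat, full_table, fitted_until)


def cross_size_prediction(mle_from: MLEResult, Ro0_target: float,
                          target_table: MeasurementTable,
                          bounds: ParameterBounds | None = None
                          ) -> PredictiveCheck:
    """Predict another seeding size's data by changing only the initial
    radius: (Rc, s, gamma, Q) are carried over from the source MLE."""
    bounds = bounds or ParameterBounds()
    lo, hi = bounds.Ro0
    if not lo < Ro0_target < hi:
        raise ValueError(
            f"Ro0_target={Ro0_target} outside bounds ({lo}, {hi})")
    theta = mle_from.theta_hat.with_Ro0(Ro0_target)
    return _residual_summary(theta, target_table,
                             float(mle_from.max_fit_time))
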