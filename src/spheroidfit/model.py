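"""Reduced Greenspan model of avascular tumour-spheroid growth.

The model tracks three concentric free boundaries of a spherically symmetric
spheroid: the outer radius Ro(t), the inhibited radius Ri(t) (living cells
that no longer proliferate) and the necrotic radius Rn(t) (dead core).
Nutrient diffuses in from the surface and is consumed by living cells; the
internal boundaries sit where the (quasi-steady) nutrient concentration
crosses the inhibition and necrosis thresholds.  Conservation of mass gives
a single ODE for the outer radius,

    Ro^2 dRo/dt = (s/3) (Ro^3 - Ri^3) - lambda Rn^3,

with Ri and Rn algebraic functions of Ro.  Rescaling the eight dimensional
quantities leaves five identifiable parameters:

    theta = (Ro0, Rc, s, gamma, Q)

where Rc is the outer radius at necrotic onset (Rc^2 = (6k/alpha)(c_inf -
c_n)), Q^2 = (c_inf - c_i)/(c_inf - c_n), and gamma = lambda / s is the
ratio of necrotic volume loss to mitotic volume production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _kernel

__all__ = [
    "DimensionalParameters",
    "ReducedParameters",
    "SpheroidStructure",
    "Trajectory",
    "reduce_parameters",
    "classify_phase",
    "necrotic_radius",
    "inhibited_radius",
    "growth_rate",
    "nutrient_deficit",
    "simulate",
]

PARAM_NAMES = ("Ro0", "Rc", "s", "gamma", "Q")


@dataclass(frozen=True)
class DimensionalParameters:
    """The eight dimensional unknowns of the full model.

    s       volumetric mitosis rate per unit living volume [1/day]
    lam     necrotic volume-loss proportionality constant lambda [1/day]
            (the loss term in the conservation law carries a factor 3 for
            algebraic convenience; ``lam`` is the per-unit-volume rate)
    alpha   nutrient consumption rate per unit volume [mol/um^3/day]
    k       nutrient diffusivity [um^2/day]
    c_inf   external nutrient concentration [mol/um^3]
    c_i     inhibition threshold concentration [mol/um^3]
    c_n     necrosis threshold concentration [mol/um^3]
    Ro0     initial outer radius [um]
    """

    s: float
    lam: float
    alpha: float
    k: float
    c_inf: float
    c_i: float
    c_n: float
    Ro0: float

    def __post_init__(self):
        for name in ("s", "alpha", "k", "c_inf", "Ro0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if not (0 < self.c_n <= self.c_i <= self.c_inf):
            raise ValueError(
                "thresholds must satisfy 0 < c_n <= c_i <= c_inf "
                "(inhibition occurs at higher nutrient than necrosis)")


@dataclass(frozen=True)
class ReducedParameters:
    """The five reduced parameters theta = (Ro0, Rc, s, gamma, Q)."""

    Ro0: float
    Rc: float
    s: float
    gamma: float
    Q: float

    def __post_init__(self):
        if self.Ro0 <= 0 or self.Rc <= 0 or self.s <= 0:
            raise ValueError("Ro0, Rc and s must be strictly positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.Q <= 0:
            raise ValueError("Q must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.Ro0, self.Rc, self.s, self.gamma, self.Q])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "ReducedParameters":
        return cls(*(float(v) for v in x))

    def with_Ro0(self, Ro0: float) -> "ReducedParameters":
        return replace(self, Ro0=Ro0)


@dataclass(frozen=True)
class SpheroidStructure:
    """Radii of the three regions at one instant, plus the growth phase.

    phase 1: uniform proliferation (Ri = Rn = 0); phase 2: inhibited region
    only (Ri > 0, Rn = 0); phase 3: inhibited plus necrotic (Rn > 0).
    """

    Ro: float
    Ri: float
    Rn: float
    phase: int


@dataclass(frozen=True)
class Trajectory:
    """Solution of the outer-radius ODE sampled at requested times."""

    times: np.ndarray
    states: tuple[SpheroidStructure, ...]
    params: ReducedParameters

    @property
    def Ro(self) -> np.ndarray:
        return np.array([st.Ro for st in self.states])

    @property
    def Ri(self) -> np.ndarray:
        return np.array([st.Ri for st in self.states])

    @property
    def Rn(self) -> np.ndarray:
        return np.array([st.Rn for st in self.states])


def reduce_parameters(theta_dim: DimensionalParameters) -> ReducedParameters:
    """Map the eight dimensional parameters to the five reduced ones.

    Rc = sqrt((6k/alpha)(c_inf - c_n)), Q = sqrt((c_inf - c_i)/(c_inf - c_n)),
    gamma = lam / s; the initial radius passes through unchanged.
    """
    d = theta_dim
    denom = d.c_inf - d.c_n
    if denom <= 0:
        raise ValueError("c_n must be below c_inf for a finite Rc")
    Rc = math.sqrt(6.0 * d.k / d.alpha * denom)
    Q = math.sqrt((d.c_inf - d.c_i) / denom)
    return ReducedParameters(Ro0=d.Ro0, Rc=Rc, s=d.s, gamma=d.lam / d.s, Q=Q)


def classify_phase(Ro: float, params: ReducedParameters) -> int:
    """Growth phase at outer radius Ro.

    Boundaries are assigned to the lower phase: a spheroid exactly at the
    onset radius has a zero-size new region.
    """
    if Ro <= 0:
        raise ValueError("Ro must be positive")
    if Ro > params.Rc:
        return 3
    if Ro > min(params.Q, 1.0) * params.Rc:
        return 2
    return 1


def necrotic_radius(Ro: float, params: ReducedParameters) -> float:
    """Necrotic radius Rn for a given outer radius.

    Zero until Ro exceeds Rc; beyond onset, Rn = n*Ro with n the unique root
    in (0, 1) of 2n^3 - 3n^2 + 1 = (Rc/Ro)^2, obtained by eliminating the
    nutrient profile between the surface condition and the necrosis
    threshold at the core edge.
    """
    if Ro <= 0:
        raise ValueError("Ro must be positive")
    _, Rn = _kernel.internal_radii(Ro, params.Rc, params.Q)
    return Rn


def inhibited_radius(Ro: float, Rn: float, params: ReducedParameters) -> float:
    """Inhibited radius Ri for given outer and necrotic radii.

    Phase 1: 0.  Phase 2: sqrt(Ro^2 - Q^2 Rc^2) (parabolic nutrient profile
    with no core).  Phase 3: root of (Ro^2 - Ri^2) + 2 Rn^3 (1/Ro - 1/Ri) =
    Q^2 Rc^2 on [Rn, Ro].  For Q > 1 there is no inhibited region (Ri = 0).
    """
    if Ro <= 0:
        raise ValueError("Ro must be positive")
    if Rn >= Ro:
        raise ValueError("Rn must be smaller than Ro")
    expected_Rn = necrotic_radius(Ro, params)
    if abs(Rn - expected_Rn) > 1e-6 * max(1.0, Ro):
        raise ValueError(
            "Rn is inconsistent with Ro under these parameters "
            f"(expected {expected_Rn:.6g}, got {Rn:.6g})")
    Ri, _ = _kernel.internal_radii(Ro, params.Rc, params.Q)
    return Ri


def growth_rate(Ro: float, params: ReducedParameters) -> float:
    """dRo/dt [um/day]: mitosis in the proliferating shell minus necrotic
    volume loss, divided by the surface factor Ro^2."""
    if Ro <= 0:
        raise ValueError("Ro must be positive")
    return _kernel.growth_rate(Ro, params.Rc, params.s, params.gamma,
                               params.Q)


def nutrient_deficit(r, Ro: float, Rn: float):
    """Scaled nutrient deficit u(r) = (6k/alpha)(c_inf - c(r)) [um^2].

    In the consuming shell, u(r) = Ro^2 - r^2 + 2 Rn^3 (1/Ro - 1/r); inside
    the necrotic core consumption stops and u is constant at u(Rn).  Exactly
    zero at the surface.  Accepts scalar or array ``r``.
    """
    if not 0 <= Rn < Ro:
        raise ValueError("require 0 <= Rn < Ro")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > Ro * (1 + 1e-12)):
        raise ValueError("r must lie in [0, Ro]")
    rc = np.clip(r_arr, Rn, Ro)  # core values evaluate at the core edge
    with np.errstate(divide="ignore"):
        inv = np.where(rc > 0, 1.0 / np.maximum(rc, 1e-300), 0.0)
    u = Ro ** 2 - rc ** 2 + 2.0 * Rn ** 3 * (1.0 / Ro - inv)
    u = np.where(r_arr >= Ro, 0.0, u)
    return float(u) if np.isscalar(r) or r_arr.ndim == 0 else u


def _structure(Ro: float, params: ReducedParameters) -> SpheroidStructure:
    Ri, Rn = _kernel.internal_radii(Ro, params.Rc, params.Q)
    return SpheroidStructure(Ro=Ro, Ri=Ri, Rn=Rn,
                             phase=classify_phase(Ro, params))


def simulate(params: ReducedParameters, times, *, rtol: float = 1e-10,
             atol: float = 1e-10) -> Trajectory:
    """Integrate the outer-radius ODE from t = 0 and evaluate the full
    structure (Ro, Ri, Rn, phase) at each requested time.

    ``times`` must be non-empty, strictly increasing and non-negative.  The
    right-hand side is continuous across phase transitions, so an adaptive
    embedded Runge-Kutta pair handles them without event detection.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing and >= 0")
    Ro = _kernel.integrate_outer(params.Ro0, params.Rc, params.s,
                                 params.gamma, params.Q, t, rtol, atol)
    states = tuple(_structure(float(r), params) for r in Ro)
    return Trajectory(times=t, states=states, params=params)


def outer_radii(params: ReducedParameters, times: np.ndarray, *,
                rtol: float = 1e-10, atol: float = 1e-10):
    """Fast path used by the likelihood: (Ro, Ri, Rn) arrays at ``times``
    (assumed validated, sorted, >= 0) without building containers."""
    Ro = _kernel.integrate_outer(params.Ro0, params.Rc, params.s,
                                 params.gamma, params.Q, times, rtol, atol)
    Ri, Rn = _kernel.radii_along(Ro, params.Rc, params.Q)
    return Ro, Ri, Rn
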