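"""Compiled numerical core of the reduced Greenspan model.

Everything here is scalar double-precision math compiled with numba so that
the likelihood (one trajectory solve per evaluation) stays cheap inside the
multistart / profile-likelihood loops.  The Python-facing API in
:mod:`spheroidfit.model` wraps these kernels with validation and containers.

Conventions: lengths in micrometres, time in days, rates per day.  The
reduced parameter vector is (Ro0, Rc, s, gamma, Q) with lambda = gamma * s.
"""

import numpy as np
from numba import njit

# Interval-halving tolerance in the dimensionless radius variable.
_BISECT_TOL = 1e-14


@njit(cache=True)
def necrotic_fraction(B):
    """Root n in [0, 1] of 2n^3 - 3n^2 + 1 = B for B in [0, 1].

    B = (Rc/Ro)^2.  The left side is strictly decreasing on (0, 1) (its
    derivative 6n(n-1) is negative there), from 1 at n=0 to 0 at n=1, so the
    root is unique; bracketed bisection is guaranteed to converge.
    """
    if B >= 1.0:
        return 0.0
    if B <= 0.0:
        return 1.0
    a = 0.0
    b = 1.0
    while b - a > _BISECT_TOL:
        m = 0.5 * (a + b)
        fm = ((2.0 * m - 3.0) * m * m + 1.0) - B
        if fm > 0.0:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


@njit(cache=True)
def internal_radii(Ro, Rc, Q):
    """(Ri, Rn) for an outer radius Ro under reduced parameters (Rc, Q).

    Solves the piecewise steady-state nutrient profile: zero consumption and
    zero flux in the necrotic core, uniform consumption in the living shell,
    concentration c_inf at the surface.  In the scaled deficit variable
    u(r) = (6k/alpha)(c_inf - c(r)) the shell profile is

        u(r) = Ro^2 - r^2 + 2 Rn^3 (1/Ro - 1/r),   Rn <= r <= Ro,

    and the internal boundaries satisfy u(Rn) = Rc^2, u(Ri) = Q^2 Rc^2.
    For Q > 1 the nutrient floor (c_n at the core edge) never reaches the
    inhibition threshold, so Ri = 0 while Rn evolves as for Q = 1.
    """
    if Ro <= Rc:
        Rn = 0.0
    else:
        ratio = Rc / Ro
        Rn = Ro * necrotic_fraction(ratio * ratio)

    if Q > 1.0:
        return 0.0, Rn
    if Q == 1.0:
        return Rn, Rn

    QRc = Q * Rc
    if Ro <= QRc:
        return 0.0, Rn
    if Rn == 0.0:
        return np.sqrt(Ro * Ro - QRc * QRc), Rn

    # Phase 3: u(Ri) = Q^2 Rc^2 on [Rn, Ro]; u is strictly decreasing there
    # (du/dr = -2r + 2Rn^3/r^2 < 0 for r > Rn), bracketed bisection again.
    target = QRc * QRc
    two_rn3 = 2.0 * Rn * Rn * Rn
    a = Rn
    b = Ro
    tol = _BISECT_TOL * Ro
    while b - a > tol:
        m = 0.5 * (a + b)
        um = Ro * Ro - m * m + two_rn3 * (1.0 / Ro - 1.0 / m)
        if um > target:
            a = m
        else:
            b = m
    return 0.5 * (a + b), Rn


@njit(cache=True)
def growth_rate(Ro, Rc, s, gamma, Q):
    """dRo/dt from conservation of mass: proliferation in the living,
    non-inhibited shell minus volume loss from the necrotic core.

    The proliferating shell is bounded below by max(Ri, Rn): for Q <= 1
    that is Ri (necrotic cells are inside the inhibited boundary), while
    for Q > 1 the inhibited region is empty (Ri = 0) and proliferation
    stops only at the necrotic edge — which makes the Ro and Rn dynamics
    identical for Q = 1 and Q > 1.
    """
    Ri, Rn = internal_radii(Ro, Rc, Q)
    Rp = Ri if Ri > Rn else Rn
    return (s / 3.0 * (Ro * Ro * Ro - Rp * Rp * Rp)
            - gamma * s * Rn * Rn * Rn) / (Ro * Ro)


# Dormand-Prince 5(4) coefficients.
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (19372.0 / 6561.0, -25360.0 / 2187.0,
                          64448.0 / 6561.0, -212.0 / 729.0)
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0,
                                46732.0 / 5247.0, 49.0 / 176.0,
                                -5103.0 / 18656.0)
_B1, _B3, _B4, _B5, _B6 = (35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
                           -2187.0 / 6784.0, 11.0 / 84.0)
# 5th-order minus embedded 4th-order weights (error estimator).
_E1 = 35.0 / 384.0 - 5179.0 / 57600.0
_E3 = 500.0 / 1113.0 - 7571.0 / 16695.0
_E4 = 125.0 / 192.0 - 393.0 / 640.0
_E5 = -2187.0 / 6784.0 + 92097.0 / 339200.0
_E6 = 11.0 / 84.0 - 187.0 / 2100.0
_E7 = -1.0 / 40.0


@njit(cache=True)
def integrate_outer(Ro0, Rc, s, gamma, Q, t_out, rtol, atol):
    """Integrate dRo/dt from t=0, returning Ro at each time in t_out.

    Adaptive embedded Runge-Kutta 5(4).  The right-hand side is continuous
    across phase transitions (Ri, Rn enter with zero value at onset), so no
    event handling is needed; the kinks are resolved by step-size control.
    t_out must be sorted ascending with t_out[0] >= 0.
    """
    n_out = t_out.shape[0]
    out = np.empty(n_out)
    t = 0.0
    y = Ro0
    f = growth_rate(y, Rc, s, gamma, Q)
    h = 1e-3
    for i in range(n_out):
        tt = t_out[i]
        while tt - t > 1e-12 * max(1.0, tt):
            hs = h
            if t + hs > tt:
                hs = tt - t
            k1 = f
            k2 = growth_rate(y + hs * _A21 * k1, Rc, s, gamma, Q)
            k3 = growth_rate(y + hs * (_A31 * k1 + _A32 * k2), Rc, s, gamma, Q)
            k4 = growth_rate(y + hs * (_A41 * k1 + _A42 * k2 + _A43 * k3),
                             Rc, s, gamma, Q)
            k5 = growth_rate(y + hs * (_A51 * k1 + _A52 * k2 + _A53 * k3
                                       + _A54 * k4), Rc, s, gamma, Q)
            k6 = growth_rate(y + hs * (_A61 * k1 + _A62 * k2 + _A63 * k3
                                       + _A64 * k4 + _A65 * k5),
                             Rc, s, gamma, Q)
            y5 = y + hs * (_B1 * k1 + _B3 * k3 + _B4 * k4 + _B5 * k5
                           + _B6 * k6)
            if not np.isfinite(y5) or y5 <= 0.0:
                raise ValueError(
                    "trajectory integration failed: outer radius left the "
                    "positive domain (check parameters)")
            k7 = growth_rate(y5, Rc, s, gamma, Q)
            err = hs * abs(_E1 * k1 + _E3 * k3 + _E4 * k4 + _E5 * k5
                           + _E6 * k6 + _E7 * k7)
            tol = atol + rtol * max(abs(y), abs(y5))
            if err <= tol:
                t = t + hs
                y = y5
                f = k7
                if err == 0.0:
                    fac = 5.0
                else:
                    fac = 0.9 * (tol / err) ** 0.2
                    if fac > 5.0:
                        fac = 5.0
                    elif fac < 0.2:
                        fac = 0.2
                h = hs * fac
            else:
                fac = 0.9 * (tol / err) ** 0.2
                if fac < 0.1:
                    fac = 0.1
                h = hs * fac
                if h < 1e-12:
                    raise ValueError(
                        "trajectory integration failed: step size underflow")
        out[i] = y
    return out


@njit(cache=True)
def radii_along(Ro_arr, Rc, Q):
    """Vectorised internal_radii over an array of outer radii."""
    n = Ro_arr.shape[0]
    Ri = np.empty(n)
    Rn = np.empty(n)
    for i in range(n):
        Ri[i], Rn[i] = internal_radii(Ro_arr[i], Rc, Q)
    return Ri, Rn
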