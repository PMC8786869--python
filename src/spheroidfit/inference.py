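"""Maximum likelihood calibration and profile-likelihood identifiability.

The five reduced parameters are estimated by bounded multistart Nelder-Mead
on the log-likelihood.  Identifiability is assessed one parameter at a time
with profile likelihoods: the interest parameter is fixed on a grid across
its bounds, the four nuisance parameters are re-optimised at each grid
point (warm-started from the neighbouring point and the MLE), and the curve
is normalised by its maximum.  Approximate confidence intervals are the
region where the normalised profile exceeds a chi-squared-derived
threshold (0.1465 for 95%, conventionally quoted as 0.15).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .model import PARAM_NAMES, ReducedParameters
from .observation import LikelihoodEvaluator, MeasurementTable, NoiseModel

__all__ = [
    "ParameterBounds",
    "MLEResult",
    "ProfileCurve",
    "ConfidenceInterval",
    "fit_mle",
    "profile",
    "confidence_interval",
    "ci_threshold",
]

DEFAULT_THRESHOLD = 0.15

# Fraction of the bound range used as an interior margin where a bound of 0
# would make the model degenerate (Ro0, Rc, s cannot be 0).
_EDGE = 1e-3


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds for (Ro0, Rc, s, gamma, Q); defaults are the wide,
    design-independent boxes used throughout: radii bounded by plate
    geometry, s by a 12 h minimum doubling time, Q <= 1 because the
    inhibited region forms before the necrotic core."""

    Ro0: tuple[float, float] = (0.0, 350.0)
    Rc: tuple[float, float] = (0.0, 250.0)
    s: tuple[float, float] = (0.0, 1.0)
    gamma: tuple[float, float] = (0.0, 6.0)
    Q: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([getattr(self, n)[0] for n in PARAM_NAMES])
        hi = np.array([getattr(self, n)[1] for n in PARAM_NAMES])
        return lo, hi

    def interior(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounds shrunk away from degenerate edges for the optimiser."""
        lo, hi = self.arrays()
        w = hi - lo
        return lo + _EDGE * w, hi - 0.0 * w

    def contains(self, params: ReducedParameters) -> bool:
        lo, hi = self.arrays()
        x = params.as_array()
        return bool(np.all(x >= lo) and np.all(x <= hi))


@dataclass(frozen=True)
class MLEResult:
    """Best multistart endpoint, with the per-start optimisation trace."""

    theta_hat: ReducedParameters
    loglik_hat: float
    trace: tuple[dict, ...]
    max_fit_time: float

    def to_dict(self) -> dict:
        return {
            "theta_hat": dict(zip(PARAM_NAMES, self.theta_hat.as_array())),
            "loglik_hat": self.loglik_hat,
            "n_starts": len(self.trace),
            "n_converged": sum(1 for t in self.trace if t["success"]),
            "max_fit_time": self.max_fit_time,
        }


class ConfidenceInterval(NamedTuple):
    lo: float
    hi: float
    open_lo: bool
    open_hi: bool

    @property
    def width(self) -> float | None:
        """Interval width; undefined (None) when an endpoint is open."""
        if self.open_lo or self.open_hi:
            return None
        return self.hi - self.lo


@dataclass
class ProfileCurve:
    """Gridded profile likelihood for one interest parameter."""

    parameter: str
    grid: np.ndarray
    loglik: np.ndarray
    nuisance: np.ndarray          # (grid, 4) optimised nuisance values
    threshold: float = DEFAULT_THRESHOLD
    n_failed: int = 0

    @property
    def Lp(self) -> np.ndarray:
        """Normalised profile likelihood (max over the grid = 1)."""
        return np.exp(self.loglik - np.max(self.loglik))

    @property
    def ci(self) -> ConfidenceInterval:
        return confidence_interval(self, self.threshold)


def _objective(evaluator: LikelihoodEvaluator):
    def negloglik(x: np.ndarray) -> float:
        try:
            params = ReducedParameters.from_array(x)
            return -evaluator.loglik(params)
        except (ValueError, FloatingPointError):
            return 1e12
    return negloglik


def _minimize(fun, x0, lo, hi, maxiter):
    return optimize.minimize(
        fun, np.clip(x0, lo, hi), method="Nelder-Mead",
        bounds=optimize.Bounds(lo, hi),
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": maxiter,
                 "adaptive": True})


def _draw_starts(rng, lo, hi, n):
    u = rng.uniform(0.05, 0.95, size=(n, lo.size))
    return lo + u * (hi - lo)


def fit_mle(table: MeasurementTable, noise: NoiseModel,
            bounds: ParameterBounds | None = None, *,
            n_starts: int = 10, seed: int | None = None,
            extra_starts: Sequence[Sequence[float]] = (),
            include_zero_internal: bool = True,
            maxiter: int = 3000) -> MLEResult:
    """Bounded multistart maximum likelihood estimate of theta.

    Starts are drawn uniformly inside the bounds from a seeded generator
    (plus any user-supplied starts); each runs a bounded Nelder-Mead search,
    the best endpoint is polished by a restart from itself, and the overall
    best is returned.  Deterministic for a fixed seed.
    """
    if len(table) == 0:
        raise ValueError("empty measurement table")
    bounds = bounds or ParameterBounds()
    ev = LikelihoodEvaluator(table, noise,
                             include_zero_internal=include_zero_internal)
    fun = _objective(ev)
    lo, hi = bounds.interior()
    rng = np.random.default_rng(seed)
    starts = list(_draw_starts(rng, lo, hi, n_starts))
    starts += [np.asarray(s, dtype=float) for s in extra_starts]

    trace = []
    best = None
    for x0 in starts:
        res = _minimize(fun, x0, lo, hi, maxiter)
        trace.append({"x0": x0.tolist(), "x": res.x.tolist(),
                      "fun": float(res.fun), "success": bool(res.success),
                      "nfev": int(res.nfev)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all optimisation starts failed: {trace}")
    # polish: restart the simplex at the incumbent optimum
    for _ in range(2):
        res = _minimize(fun, best.x, lo, hi, maxiter)
        if res.fun < best.fun:
            best = res
    theta = ReducedParameters.from_array(best.x)
    return MLEResult(theta_hat=theta, loglik_hat=-float(best.fun),
                     trace=tuple(trace),
                     max_fit_time=float(ev.times.max()))


def profile(parameter: str, table: MeasurementTable, noise: NoiseModel,
            bounds: ParameterBounds | None = None, *,
            grid_size: int = 40, seed: int | None = None,
            mle: MLEResult | None = None, n_starts: int = 10,
            nuisance_restarts: int = 1,
            threshold: float = DEFAULT_THRESHOLD,
            include_zero_internal: bool = True,
            maxiter: int = 2000) -> ProfileCurve:
    """Profile likelihood of one interest parameter over a uniform grid.

    At each grid value the four nuisance parameters are re-optimised from
    several starts — the neighbouring grid point's optimum (sweeping
    outward from the MLE), the MLE's nuisance values, and
    ``nuisance_restarts`` seeded random interior points — and the best
    endpoint is kept.  The extra restarts matter on practically
    non-identifiable ridges, where the compensating nuisance optimum can
    sit far from the warm start.  The curve is normalised by its own
    maximum.
    """
    if parameter not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    if grid_size < 8:
        raise ValueError("grid_size must be at least 8")
    bounds = bounds or ParameterBounds()
    if mle is None:
        mle = fit_mle(table, noise, bounds, n_starts=n_starts, seed=seed,
                      include_zero_internal=include_zero_internal)
    ev = LikelihoodEvaluator(table, noise,
                             include_zero_internal=include_zero_internal)
    k = PARAM_NAMES.index(parameter)
    nuis_idx = [i for i in range(5) if i != k]
    lo, hi = bounds.interior()
    grid = np.linspace(lo[k], hi[k], grid_size)

    def nuis_obj(psi):
        def f(phi):
            x = np.empty(5)
            x[k] = psi
            x[nuis_idx] = phi
            try:
                return -ev.loglik(ReducedParameters.from_array(x))
            except (ValueError, FloatingPointError):
                return 1e12
        return f

    phi_mle = mle.theta_hat.as_array()[nuis_idx]
    lo_n, hi_n = lo[nuis_idx], hi[nuis_idx]
    loglik = np.full(grid_size, -np.inf)
    nuisance = np.zeros((grid_size, 4))
    n_failed = 0

    rng = np.random.default_rng(0 if seed is None else seed)
    rand_starts = lo_n + rng.uniform(
        0.05, 0.95, size=(grid_size, max(nuisance_restarts, 0), 4)) \
        * (hi_n - lo_n)

    opts = {"xatol": 1e-5, "fatol": 1e-7, "maxiter": maxiter,
            "adaptive": True}
    nm_bounds = optimize.Bounds(lo_n, hi_n)
    i_mle = int(np.argmin(np.abs(grid - mle.theta_hat.as_array()[k])))
    order = list(range(i_mle, grid_size)) + list(range(i_mle - 1, -1, -1))
    warm = {i_mle: phi_mle, i_mle - 1: phi_mle}
    quick_opts = dict(opts, maxiter=min(maxiter, 600))
    for i in order:
        fun = nuis_obj(grid[i])
        res = optimize.minimize(fun, np.clip(warm.get(i, phi_mle),
                                             lo_n, hi_n),
                                method="Nelder-Mead", bounds=nm_bounds,
                                options=opts)
        # the MLE's nuisance values must never beat the warm-started
        # optimum; re-optimise from them if they do
        if fun(phi_mle) < res.fun:
            r = optimize.minimize(fun, phi_mle, method="Nelder-Mead",
                                  bounds=nm_bounds, options=opts)
            if r.fun < res.fun:
                res = r
        # seeded random restarts guard against losing a compensating
        # nuisance ridge along the sweep (short runs, polished on success)
        for x0 in rand_starts[i]:
            r = optimize.minimize(fun, np.clip(x0, lo_n, hi_n),
                                  method="Nelder-Mead", bounds=nm_bounds,
                                  options=quick_opts)
            if r.fun < res.fun:
                r = optimize.minimize(fun, r.x, method="Nelder-Mead",
                                      bounds=nm_bounds, options=opts)
                if r.fun < res.fun:
                    res = r
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            n_failed += 1
            continue
        loglik[i] = -float(res.fun)
        nuisance[i] = res.x
        step = 1 if i >= i_mle else -1
        warm[i + step] = res.x
    if n_failed > grid_size // 4:
        raise RuntimeError(
            f"profile of {parameter!r} failed at {n_failed}/{grid_size} "
            "grid points")
    return ProfileCurve(parameter=parameter, grid=grid, loglik=loglik,
                        nuisance=nuisance, threshold=threshold,
                        n_failed=n_failed)


def confidence_interval(curve: ProfileCurve,
                        threshold: float = DEFAULT_THRESHOLD
                        ) -> ConfidenceInterval:
    """Approximate confidence interval from a normalised profile curve.

    Endpoints interpolate the threshold crossing linearly in Lp between
    adjacent grid points on each side of the maximum.  A side that never
    drops below the threshold before hitting its bound is reported open
    (practically non-identifiable in that direction).
    """
    Lp = curve.Lp
    g = curve.grid
    i_max = int(np.argmax(Lp))

    def cross(indices):
        prev = i_max
        for j in indices:
            if Lp[j] < threshold:
                x0, x1 = g[prev], g[j]
                y0, y1 = Lp[prev], Lp[j]
                return x0 + (threshold - y0) * (x1 - x0) / (y1 - y0), False
            prev = j
        return g[indices[-1]] if indices else g[i_max], True

    left = list(range(i_max - 1, -1, -1))
    right = list(range(i_max + 1, len(g)))
    lo, open_lo = cross(left) if left else (g[0], True)
    hi, open_hi = cross(right) if right else (g[-1], True)
    return ConfidenceInterval(float(lo), float(hi), open_lo, open_hi)


def ci_threshold(confidence: float) -> float:
    """Normalised-likelihood threshold for a given confidence level.

    exp(-q/2) with q the chi-squared(1) quantile: 0.1465 at 95%, the value
    conventionally rounded to 0.15.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    return float(np.exp(-stats.chi2.ppf(confidence, df=1) / 2.0))
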