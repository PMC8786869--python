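# Methods

## The growth model

`spheroidfit` implements the classical three-phase free-boundary model of
avascular tumour-spheroid growth.  A spheroid is assumed spherically
symmetric at all times, described by three concentric radii: the outer
radius Ro(t), the inhibited radius Ri(t) enclosing living cells that no
longer proliferate, and the necrotic radius Rn(t) enclosing the dead core.
Nutrient (e.g. oxygen) enters at the surface at external concentration
c_inf, diffuses with diffusivity k, and is consumed at a constant
volumetric rate alpha by living cells.  Because nutrient diffusion is fast
relative to growth, the concentration profile c(r) is at quasi-steady
state on the current geometry:

    (1/r^2) d/dr ( r^2 dc/dr ) = (alpha/k) * 1[Rn < r < Ro],   c(Ro) = c_inf,

with zero flux at the centre and no consumption in the dead core.  The
internal boundaries sit where c crosses the inhibition threshold c_i
(cells stop cycling) and the necrosis threshold c_n < c_i (cells die).

Mass balance of living volume gives a single ODE for the outer radius:

    Ro^2 dRo/dt = (s/3) (Ro^3 - Ri^3) - lambda Rn^3,

where s is the volumetric mitosis rate per unit living volume [1/day] and
3*lambda the volume-loss rate of the necrotic core (debris dissolving and
escaping).  Ri and Rn are *algebraic* functions of Ro, so the model is a
scalar ODE despite its three moving boundaries.

### Reduced parameterisation

Solving the nutrient problem piecewise and working in the scaled deficit
u(r) = (6k/alpha)(c_inf - c(r)) eliminates the dimensional nutrient
quantities.  In the consuming shell,

    u(r) = Ro^2 - r^2 + 2 Rn^3 (1/Ro - 1/r),

constant for r < Rn, zero at the surface.  Imposing u(Rn) = Rc^2 and
u(Ri) = Q^2 Rc^2 leaves five identifiable parameters

    theta = (Ro(0), Rc, s, gamma, Q),

with Rc^2 = (6k/alpha)(c_inf - c_n) the outer radius at necrotic onset,
Q^2 = (c_inf - c_i)/(c_inf - c_n) in (0, 1], and gamma = lambda/s the
ratio of necrotic volume loss to mitotic volume production.  Setting
r = Rn in the shell profile yields the necrotic condition

    2 n^3 - 3 n^2 + 1 = (Rc/Ro)^2,   n = Rn/Ro,

whose left side is strictly decreasing on (0, 1): Rn is the unique root,
zero until Ro exceeds Rc.  Ri solves u(Ri) = Q^2 Rc^2 on [Rn, Ro]
(closed-form sqrt(Ro^2 - Q^2 Rc^2) while no core exists).  Growth phases
follow: phase 1 (uniform proliferation) for Ro <= Q*Rc, phase 2
(inhibited region only) up to Rc, phase 3 beyond.  A radius exactly at a
threshold is assigned the lower phase (the new region has zero size
there); nothing measurable depends on this convention.

Two edge conventions: at Q = 1 the two thresholds coincide and Ri = Rn
identically.  Inputs with Q > 1 are rejected by the calibration bounds
but accepted by the simulator, with Ri = 0 (the nutrient floor in the
living region is c_n > c_i, so no cell is merely inhibited) and the
proliferating shell bounded below by max(Ri, Rn) — hence Ro(t) and Rn(t)
for Q > 1 coincide with the Q = 1 dynamics and only the reported Ri
differs.

## Observation model and likelihood

Measurements are treated as independent additive-Gaussian observations of
the deterministic trajectory, with one variance per measurement type
(outer / inhibited / necrotic).  Variances are plug-in constants: pooled
sample variances across time points, sum_j (n_j-1) s_j^2 / sum_j (n_j-1),
using only time points with at least two replicates.  They are not free
parameters of the fit.

Zero-valued inhibited/necrotic observations recorded before onset are
included in the likelihood by default — the model predicts exactly zero
there, so absence of a region is informative — with a switch
(`include_zero_internal=False`) to drop them.  The likelihood does not
truncate at zero: it is a plain Gaussian density even though radii are
non-negative, consistent with the generator's default clipping being a
property of the data, not of the model.

## Calibration and identifiability

The MLE maximises the log-likelihood over the box

    0 < Ro(0) < 350,  0 < Rc < 250 [um],  0 < s < 1 [1/day],
    0 < gamma < 6,    0 < Q <= 1,

by bounded Nelder–Mead from 10 uniform random starts (seeded), with the
best endpoint polished by simplex restarts.  Derivative-free search is
deliberate: the ODE right-hand side is continuous but kinked at phase
transitions, so gradient-based methods gain little.

Profile likelihoods fix one parameter on a uniform grid across its bounds
(default 40 points) and re-optimise the remaining four at each point.
Nuisance optimisation is warm-started from the neighbouring grid point,
sweeping outward from the MLE in both directions, with the MLE's nuisance
values as a guard.  One seeded random restart per grid point (short run,
polished when it wins) protects against losing a *compensating ridge*:
on practically non-identifiable profiles the nuisance optimum can jump
far across the box (e.g. trading necrotic loss against inhibition), and a
purely local warm start then under-maximises the profile and reports a
spuriously narrow interval.

The normalised profile Lp(psi) = exp(l_p(psi) - max l_p) is compared with
the threshold exp(-q(0.95)/2) = 0.1465 (chi-squared, 1 df), conventionally
0.15; interval endpoints interpolate the crossing linearly in Lp between
adjacent grid points.  An endpoint whose profile never drops below the
threshold before the bound is reported *open*, and a parameter is called
identifiable only when both endpoints are closed.  Widths of open
intervals are undefined; design comparisons use the endpoint span
(clipped at the bounds) where an extent is needed.

## Synthetic data

The generator emulates the structure of 4D spheroid measurement tables:
three nested designs (outer only; outer+necrotic; outer+necrotic+
inhibited), day schedules A = {1,3,8,12,17}, B = {1,3,6,8,10,12,14,17,19},
C = daily 0–19, 24 longitudinally imaged spheroids for the outer radius
and 10 destructive end-point measurements per day for each internal type,
for seeding sizes labelled 1250–10000 cells.  Noise is zero-mean Gaussian
per type; defaults are standard deviations of 9 um (outer) and 12 um
(inhibited, necrotic), of the order of the replicate scatter such
experiments show, with the internal types noisier because they come from
segmentation of stained equatorial sections.  Negative draws are clipped
at zero by default (radii are non-negative); clipping can be disabled for
distributional checks.

Noise substreams are keyed by (seed, type, day), so adding a measurement
type to a design never perturbs the others: a Design-1 table is
byte-identical to the outer subset of the Design-3 table at the same
seed, which keeps design comparisons free of Monte-Carlo confounding.

What the generator does **not** emulate: spheroid formation dynamics
before day 0, measurement dropout (excluded spheroids), spheroid-level
random effects (replicates are i.i.d. around the common trajectory),
correlated errors between types measured on the same spheroid, and any
departure of real spheroids from the model (asymmetry, late-time
shrinkage).  Passing recovery and coverage tests therefore demonstrates
correctness of the inference machinery under the model's own assumptions,
not adequacy of the model for any particular cell line.

Two reference truths are used in the test-bench experiments:
(120, 150, 0.3, 1.0, 0.7) — a fast-growing spheroid reaching phase 3 by
day ~3, used for recovery/coverage; and (120, 180, 0.14, 1.0, 0.9) — a
slower spheroid that starts in phase 1, reaches phase 3 at day ~9 and
stays below the Rc bound, used for the design comparison.  The second
choice matters: the outer-only non-identifiability of gamma requires that
a no-necrosis explanation (Rc above the largest observed radius) remain
admissible within the bounds, which is the regime the three-design
comparison probes.

## Numerical choices

- Internal radii: bracketed bisection on provably monotone functions
  (the cubic in n on [0,1]; the deficit equation on [Rn, Ro]) to 1e-14
  relative in the dimensionless variable — convergence is guaranteed and
  derivative bookkeeping avoided.
- Trajectory: an embedded Dormand–Prince 5(4) pair with proportional step
  control, compiled with numba; the RHS is continuous across phase
  transitions so no event handling is required.  Defaults rtol = atol =
  1e-10 for simulation; the likelihood path uses 1e-6, which keeps the
  radius error ~1e-4 um — four orders below the observation noise — and
  halves the cost of an optimiser step.  The solver is cross-checked
  against scipy's integrator and the phase-1 closed form Ro0*exp(st/3)
  in the tests.
- Optimiser tolerances: xatol 1e-8 / fatol 1e-10 for the MLE,
  1e-5 / 1e-7 for nuisance re-optimisation (profile values matter at the
  ~1e-3 level of Lp).
- All likelihood arithmetic in log space; normalisation subtracts the
  maximum log-likelihood.
- Every random choice (starts, synthetic noise, restarts) flows from an
  explicit integer seed; identical inputs give bit-identical outputs.

## Problem sizes in the acceptance script

`scripts/acceptance.py` reruns: the solver-vs-oracle comparison over 100
random geometries against a 20001-point finite-volume free-boundary
solve; recovery/coverage over 10 synthetic Design-3/Resolution-A datasets
(profile grid 25); the three-design comparison at Resolution C (grid 40);
and the reproducibility check.  The test suite runs the coverage
experiment at 20 replicates.

## Known limitations

- The nuisance-restart heuristic makes profiles robust, not provably
  global; pathological multi-ridge likelihoods could still be
  under-profiled (symptom: a CI that shrinks when `nuisance_restarts` is
  increased).
- Pooled variances are per-table; pooling across seeding sizes or cell
  lines is the caller's responsibility (concatenate tables first).
- The Gaussian likelihood is untruncated, so for internal radii near
  onset (mean near zero) the model puts mass on negative values that the
  clipped generator never produces; at the default noise levels the
  effect on estimates is negligible.
- Day-0 alignment (end of spheroid formation) is assumed done upstream;
  the loaders do not infer it.
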