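# spheroidfit

Calibration and identifiability analysis for avascular tumour-spheroid
experiments, built around the classical three-phase (Greenspan) growth
model.

Tumour spheroids are 3D in-vitro aggregates of cancer cells used to study
avascular growth and treatment response.  As a spheroid grows, nutrient
depletion creates internal structure: an outer proliferating rim, an
inhibited region of living but non-cycling cells, and a necrotic core.
Experiments differ widely in what they measure (just the outer radius, or
also the necrotic and inhibited radii via staining and cell-cycle
reporters), when they measure, and how many cells they seed.  This
package lets experimentalists and modellers ask, quantitatively, *which
of those design choices buy information*: it fits the model to radius
measurements by maximum likelihood, profiles each parameter to get
approximate 95% confidence intervals, and compares designs by which
parameters they render identifiable.

## Model

Spherical symmetry and quasi-steady nutrient diffusion reduce the model
to one ODE for the outer radius Ro(t),

    Ro² dRo/dt = (s/3)(Ro³ − Ri³) − λ Rn³,

where the inhibited radius Ri and necrotic radius Rn are algebraic
functions of Ro obtained from the nutrient profile.  Five reduced
parameters govern everything:

| parameter | meaning | units | bounds |
|---|---|---|---|
| Ro(0) | initial outer radius | μm | (0, 350) |
| Rc | outer radius at necrotic onset | μm | (0, 250) |
| s | volumetric mitosis rate | day⁻¹ | (0, 1) |
| γ = λ/s | necrotic loss / mitotic production | – | (0, 6) |
| Q, Q² = (c∞−c_i)/(c∞−c_n) | threshold ratio | – | (0, 1] |

Observations are modelled as the deterministic trajectory plus additive
zero-mean Gaussian noise with a pooled plug-in variance per measurement
type.  Profile likelihoods use the chi-squared threshold
exp(−3.8415/2) ≈ 0.15 on the normalised likelihood for approximate 95%
intervals; a profile that never crosses the threshold inside the bounds
flags the parameter as practically non-identifiable.

See `docs/methods.md` for the full statistical and numerical details.

## Worked example

Generate a synthetic Design-3 dataset (outer + necrotic + inhibited radii
on days 1, 3, 8, 12, 17; true parameters θ\* = (120, 150, 0.3, 1.0, 0.7)),
fit it, and profile two parameters:

```sh
$ spheroidfit synth --design design3_resA --seed 1 -o demo/synth
220 rows written to demo/synth/data.csv

$ spheroidfit fit demo/synth/data.csv --seed 0 --starts 6 -o demo/fit
{
  "Ro0": 118.28992863535635,
  "Rc": 148.56400797714625,
  "s": 0.32152714515002123,
  "gamma": 0.9178930233734707,
  "Q": 0.6795386445602863
}

$ spheroidfit profile demo/synth/data.csv -p s -p Q --grid-size 25 \
      --starts 6 -o demo/prof
{
  "s":  {"lo": 0.2688, "hi": 0.3714, "open_lo": false, "open_hi": false},
  "Q":  {"lo": 0.6315, "hi": 0.7071, "open_lo": false, "open_hi": false}
}
```

The fitted values sit close to the generating ones and both 95% intervals
cover them — with all three measurement types, every model parameter is
identifiable.  Refitting the *outer-radius-only* subset of the same data
(Design 1) leaves γ and Q with flat profiles and open intervals: outer
measurements alone say almost nothing about internal structure.  That
contrast is the package's core use case, automated by
`spheroidfit evaluate-design` (per-parameter intervals, identifiability
flags and predictive residuals as JSON/CSV) and by
`cross_size_prediction`, which tests a fit's transferability to another
seeding size by swapping only the initial radius.

The library API mirrors the CLI: `simulate`, `generate_dataset`,
`fit_mle`, `profile`, `evaluate_design`, `predictive_check`.

## Real data

Loaders accept CSV tables with columns
`spheroid_id,cell_line,initial_cells,time_days,measurement,radius_um`
(measurement ∈ outer|inhibited|necrotic; times in days after the end of
spheroid formation; `read_measurements(..., column_map=...)` adapts other
headers).  IncuCyte-style projected areas convert with
`area_to_radius` (r = √(A/π)).  Deposited experimental datasets are not
redistributed here; the real-data regression test looks for
`data/real/wm793b_5000cells.csv` and reports how to supply it.

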