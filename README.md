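# glacierlake

Watershed-scale biogeochemistry of glacier-fed Arctic lakes: a tested Python
pipeline for snowpack/tracer hydrology, rating-curve constituent loads, lake
input-output mass balances, sediment oxygen-microprofile inverse modelling,
land-to-ocean stoichiometric summaries and plankton-community ordination.

## Who this is for

Limnologists and biogeochemists working on proglacial lake systems — places
where sparse summer samplings of glacial rivers, a few water-column
profiles, weighed snow cores and a handful of sediment microprofiles must be
assembled into annual nutrient budgets and a mechanistic picture of where a
lake retains or releases carbon, nitrogen, phosphorus, silica and iron. The
worked example throughout is the world's largest High Arctic lake
(Lake Hazen, Ellesmere Island): a 7516 km² watershed, 40.9% glacierized,
draining through a 544 km², 267 m deep lake to the coast.

## The models at the core

* **Snow hydrology.** Areal water volume from weighed cores,
  `AWV = w / (π r²)` (1 kg snow = 1 L water), and a conservative-tracer
  partition of landscape snowmelt: if sulfate is conserved in the pack while
  water sublimates, the overland-flow fraction is
  `f = c_snowpack / c_snowmelt` and `1 − f` sublimated.
* **Rating-curve loads.** Per river × dissolved species,
  `ln L = a0 + a1 lnQ' (+ a2 lnQ'²)` with lnQ' centered so the linear and
  quadratic terms are orthogonal, Duan smearing retransformation, selection
  of form 1 vs 2 by minimum absolute load-bias percentage, annual
  integration over the daily hydrograph, and residual-bootstrap SEs.
* **Mass balance.** `ΔStorage = Σ outputs − Σ inputs` over three input
  compartments (snow on the lake, landscape snowmelt runoff, glacial
  rivers) and one outflow; SEs of sums add linearly; a budget is a
  significant sink/source when the k·SE intervals of inputs and outputs are
  disjoint (k = 1 by default).
* **Sediment diagenesis.** Steady-state `d/dz(φ Ds dC/dz) = R(z)` with
  `Ds = D0 / (1 + 3(1 − φ))` and porosity from wet/dry section weights;
  piecewise-constant consumption zones fitted by linear least squares with
  F-test zone reduction; depth-integrated rate = SWI diffusive flux.
* **Stoichiometry.** Trapezoid depth-weighted profile means, Poole–Atkins
  extinction `k = 1.7 / z_SD`, DIN:TP mass-ratio limitation classes
  (1.5/3.4 thresholds), freshwater carbonate speciation for % CO₂
  saturation, and ordered mean ± SE tables along the land-to-ocean aquatic
  continuum.
* **Ordination.** Hellinger transform (`sqrt` of relative abundance), PCA,
  RDA as the PCA of fitted values of the community on standardized
  environmental predictors, VIF collinearity screening, greedy forward
  selection under AIC, and PC1-versus-environment regression.
* **Synthetic watershed.** A seeded generator for every input above with
  serialized ground truth (`truth.json`), so each stage has a
  parameter-recovery test without any field data.

## Worked example

```python
import numpy as np
from glacierlake import synth, loads as ld, snow as sn

# conservative-tracer partition of landscape snowmelt
f = sn.tracer_runoff_fraction(1.82, 14.9)   # snowpack vs snowmelt SO4, mg/L
print(f"runoff {100*f:.1f}%, sublimated {100*(1-f):.1f}%")

# one synthetic river-year, fitted and integrated
cfg = synth.ScenarioConfig(seed=42)
rng = np.random.default_rng(42)
qs = synth.gen_melt_hydrograph(cfg, 2015, rng)
calib, daily, true_tons = synth.gen_chemistry(qs, cfg, "SO4", rng)
fit = ld.select_rating_model(calib)
load = ld.annual_load(fit, qs, calib, n_boot=500, seed=rng)
print(f"form={fit.form} r2={fit.r2:.3f} Bp={fit.bp:.2f}%")
print(f"true {true_tons:.1f} t, estimated {load.tons:.1f} ± {load.se:.1f} t")
```

prints

```
runoff 12.2%, sublimated 87.8%
form=2 r2=0.935 Bp=-0.06%
true 1435.4 t, estimated 1549.7 ± 132.5 t
```

The tracer partition says only 12.2% of the landscape snowpack reaches the
lake as overland flow. The rating curve explains 93.5% of the log-load
variance with essentially no calibration bias, and the bootstrapped annual
load covers the generator's true load within one standard error.

The same stages are scriptable from the shell:

```sh
glacierlake simulate --seed 7 --out scenario/
glacierlake loads --data scenario/ --out annual_loads.csv
glacierlake budget --data scenario/
glacierlake sediment --data scenario/ --max-zones 4
glacierlake ordinate --data scenario/
```

## Reference dataset

`glacierlake.datasets` embeds the published 2015/2016 annual budget table
for the Lake Hazen watershed (component loads ± SE for six dissolved
species plus water) as the standard cross-check and worked example for the
budget machinery.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the tracer-derived overland-flow percentage from the published
snowpack and snowmelt sulfate means through the package's partition
function, writes it as JSON, and logs a seeded end-to-end sanity run
(synthetic conservative-tracer budget closure) to stderr.

## Documentation

`docs/methods.md` describes the models, their assumptions, the numerical
choices and the limits of what the synthetic-data tests establish.
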