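# Methods

This note documents the models implemented in `glacierlake`, their
assumptions, the tunable parameters, the numerical choices, and — because
the package validates itself against a synthetic watershed rather than
field data — what a green test does and does not establish.

## Snow hydrology

A snow survey is a set of sites, each with replicate weighed cores. The
areal water volume of a core is `AWV = w / (π r²)` (L/m²), taking 1 kg of
snow as 1 L of water. Replicates are averaged within site first; the survey
mean and standard error are then taken over site means, matching the
sampling design (three cores per site). Snow melting on the lake surface
contributes its full AWV × lake area; no sublimation correction is applied
there because melt on ice is fast and in place.

Landscape snow mostly sublimates in a polar desert. The overland-flow
fraction is inferred from a conservative tracer (sulfate): if all tracer
mass stays in the pack while water is lost to the atmosphere, the melt
stream is enriched by exactly the inverse of the runoff fraction, so
`f = c_snowpack / c_snowmelt`. The assumptions are complete tracer
conservation (no mineral sulfate dissolution in the flow path) and a
homogeneous pack. The estimate is scale-invariant in the concentrations.
With the published sulfate means (1.82 and 14.9 mg/L) this gives 12.2%
runoff / 87.8% sublimation; a config override exists because budget tables
in the literature sometimes assume a rounder ratio (e.g. 16%).

## Rating-curve loads

For each river × dissolved species, sparse concentration samplings are
regressed against the modelled daily hydrograph as

```
ln L = a0 + a1 lnQ' (+ a2 lnQ'²),   L = c·q (mg/s),  lnQ' = ln q − c0
```

The centering constant `c0` solves `Σ (ln q_i − c0)³ = 0` over the
calibration set, which makes the linear and quadratic regressors orthogonal
(the convention of the classical load-estimation software); the sum is
monotone in `c0`, so the root is unique and bracketed by the extremes of
`ln q`. A plain-mean centering is available by option; annual loads are
invariant to the choice (reparameterization), which is property-tested.

Fitting is ordinary least squares. Because censored concentrations are
replaced upstream by half their detection limit, the log-scale likelihood
is Gaussian and maximum-likelihood reduces to OLS — a deliberate,
documented simplification relative to censored-likelihood (AMLE) fitting.
Retransformation from the log scale uses Duan's smearing estimator (mean of
`exp` residuals). Between forms 1 and 2 the package keeps the fit with the
smaller absolute load-bias percentage

```
Bp = 100 · (Σ estimated − Σ observed) / Σ observed
```

over the calibration points, with near-ties (< 0.1 percentage points)
broken by r², then by parsimony. Form 2 requires at least 5 points (one
residual degree of freedom past the quadratic).

Annual loads integrate the smearing-corrected daily predictions
(`86 400 s/day`, mg → metric tons); days with zero discharge contribute
zero. Standard errors come from a seeded residual bootstrap: residuals are
leverage-adjusted (`r_i / sqrt(1 − h_ii)`, then centered) before
resampling — the standard correction for the variance absorbed by OLS
fitting, which matters at calibration sizes like n = 11 — and each
replicate refits the fixed design and re-integrates the year. The refits
are a single vectorized least-squares solve, so 500 replicates are cheap.

Particulate species are deliberately out of scope: their
concentration-discharge relations in braided proglacial rivers are too
irregular for defensible rating curves, so no particulate budgets are
attempted.

## Lake mass balance

`ΔStorage = Σ outputs − Σ inputs` per species × year, with exactly three
input compartments (snow on lake, snow from land, glacial rivers) and one
outflow. Outflow discharge is approximated by the summed inflows — valid
for a lake that is ice-covered most of the year, where evaporation is
negligible; the assumption is recorded with the result.

SEs of sums add **linearly**, not in quadrature, by default. The component
errors share the same hydrograph and chemistry campaigns and are strongly
dependent, and linear addition reproduces the published reference table's
total-SE column; quadrature is available by option. A budget is classified
a significant sink or source when the `k·SE` intervals of total inputs and
outputs are disjoint (k = 1 default), with the sign of ΔStorage choosing
sink vs source; otherwise neutral. The percent-difference column is
reported as `100·(out − in)/in` and explicitly does *not* reproduce the
printed "% diff." column of the reference table, whose formula is not
recoverable from its own printed loads. Two reference cells are knowingly
inconsistent with any single interval rule (see the test suite's
classification cases); the rule is kept as stated rather than tuned.

## Sediment O₂ diagenesis

Porosity per 1-cm section: `φ = (wet − dry) / V_section` with water density
1 g/cm³ and `V_section = π (8.6/2)² × 1 = 58.09 cm³` from the core-tube
geometry. Diffusivity: `Ds = D0 / (1 + 3(1 − φ))`. `D0` for O₂ comes from
a small temperature table (0–25 °C, linear interpolation, compiled from
standard microsensor references; ~1.25e-5 cm²/s at the 3.76 °C bottom-water
temperature used as default); the table is replaceable in config because
published inversions rarely state their exact value.

The steady-state profile solves `d/dz(φ Ds dC/dz) = R(z)` by double
integration with cumulative trapezoids on a fine grid (0.1 mm native):

```
w C'(z) = J0 + F(z),  C(z) = C(0) + J0 H(z) + G(z)
F = ∫R, H = ∫dz/w, G = ∫F/w,  w = φDs
```

Boundary conditions are either measured top and bottom concentrations
("conc-conc") or `C(L) = 0` with zero bottom flux ("bottomzero") for cores
in which O₂ is fully consumed. `F` and `H` are accumulated exactly for
piecewise-constant `R` and `w`; only `G` is discretized, and halving the
grid moves fitted rates by < 0.5% (tested).

Because the forward map is linear in the zone rates, inversion is linear
least squares on the unit-rate responses of each zone. Zone boundaries are
fixed equal-thickness partitions (the classical tool also optimizes their
placement; this simplification is intentional and documented). The zone
count is reduced stepwise from `max_zones` while a nested F-test is
non-significant (α = 0.05 default). On noiseless input all SSEs are solver
round-off, where an F-statistic is meaningless, so any reduced model with
SSE below a numerical floor (`n·(1e-4·max|C|)²`) is accepted outright; the
floor sits ~4 orders of magnitude below the SSE at the 2 µmol/L noise level
the generator uses. Negative fitted rates (net production) are allowed but
should be treated as diagnostic. The depth-integrated rate `Σ R_i·Δz_i`
equals the net diffusive supply `flux(0) − flux(L)` identically at steady
state; the test suite checks the conservation on every fitted model.

## Profiles and stoichiometry

Depth-integrated means are trapezoid integrals divided by the depth span —
geometric depth weighting, not hypsographic volume weighting, since no
hypsometry is assumed; a config switch to plain arithmetic means exists
because published "depth-integrated" values are sometimes that. Light
extinction uses the Poole–Atkins relation `k = 1.7 / z_SD`. DIN:TP
mass-ratio limitation thresholds are 1.5 and 3.4 (boundaries inclusive to
co-limitation), configurable. CO₂ saturation speciates DIC at measured pH
and temperature with the classical freshwater K1/K2 (conductance
determinations) and the Henry constant from the standard temperature
polynomial, then compares dissolved CO₂* with the atmospheric equilibrium
(400 ppm default). The land-to-ocean summary orders compartments
terminus → delta → shoreline → lake surface → lake bottom → outflow →
fjord inflow and reports mean ± SE of concentrations, DIN (= NH₄ + NO₃NO₂),
TC (= DIC + DOC + PC), mass DIN:TP and molar TC:TP, TN:TP.

## Ordination

Hellinger transform: `y'ᵢⱼ = sqrt(yᵢⱼ / Σⱼ yᵢⱼ)`; transformed rows have unit
sum of squares, making Euclidean/linear ordination appropriate for species
abundances. PCA eigen-decomposes the column-centered covariance; the sign
convention makes each axis's largest-magnitude loading positive. RDA is
implemented as the PCA of the fitted values of the centered multivariate
regression of the community on standardized predictors; its eigenvalues are
raw covariance eigenvalues (the proportion-of-variance scaling is also
reported), and they can never exceed the unconstrained total — an identity
the tests verify against the definitional oracle to 1e-10. Predictors are
screened with VIFs (`1/(1 − R²ⱼ)`); forward selection greedily adds the
predictor that lowers an AIC computed from the pooled residual sum of
squares (`n·ln(RSS/n) + 2(q + 1)`), a documented convention that orders
nested models like the per-response AICs do but is not numerically
identical to any particular R package default. Ties go to the earlier
input column.

## The synthetic watershed

The generator's defaults are the stated world of the study design it
emulates, fixed before any acceptance threshold was measured: seven glacial
rivers flowing June 15 – August 31, two summers (the second at 45% of peak
flow), 11 calibration samplings per river × species across the two years,
20 lake-surface + 13 landscape snow sites with three cores each, AWV
145 ± 25 L/m², the 1.82 mg/L snowpack sulfate and 12.2% true runoff
fraction, two sediment consumption zones (1.5e-3 and 3e-4 nmol/cm³/s over
0–15 and 15–30 mm, φ = 0.93, 3.76 °C, 2 µmol/L profile noise), and 24
community samples along a DIN:TP gradient from 2 to 60 with logistic group
responses (mixotroph-capable flagellates declining, diatoms/chlorophytes/
cyanobacteria increasing) and Poisson counts.

Hydrographs are Gaussian melt pulses with mean-one lognormal day-to-day
noise. Concentration noise is mean-one lognormal applied to calibration
*observations*; the daily true concentrations are the noise-free
concentration-discharge law, so the recorded true annual load is the exact
summation of daily concentration × discharge, and the smearing-corrected
estimator is unbiased for it. A single master seed expands into named
per-component substreams (`SeedSequence.spawn`), so any component can be
regenerated independently.

What the green tests establish: that the estimators recover known
parameters at the study's sample sizes and noise levels (annual loads
within 2 bootstrap SEs in ≥ 90% of seeds; |Bp| < 16% in ≥ 95%; zone rates
within 2 SE in ≥ 90%; conservative budgets neutral in ≥ 95%). What they do
not establish: behaviour under real braided-river chemistry (serially
correlated, heteroscedastic, occasionally censored), non-steady sediment
profiles, bioirrigation, taxonomic misassignment, or hydrograph model error
— the discharge series is treated as exogenous truth here, as it is in the
original analyses.

## Known limitations

* No censored-likelihood load fitting; DL/2 substitution is applied
  uniformly and flagged per value.
* Zone boundaries are not optimized; strongly non-uniform consumption with
  thin layers may need more zones than the F-test retains at α = 0.05.
* The budget classification inherits the linear-SE convention; with
  genuinely independent component errors it is conservative.
* Percent CO₂ saturation assumes freshwater activity ≈ concentration and
  1 atm total pressure.
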