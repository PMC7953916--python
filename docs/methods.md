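# Methods

This note documents the models and procedures `regenscore` implements,
the defaults it ships, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## Composite practice score

The score is a deliberately simple composite indicator: an unweighted
sum of coded practice items. Cropland items are binary (eliminating
synthetic fertilizers, herbicides, fungicides, insecticides and tillage
each score 1; including cover crops or deliberately fostered resident
vegetation, diversified field margins/hedgerows, organic amendments and
livestock each score 1; maximum 9). Corn surveys omit fungicides, field
margins and organic amendments; those items are excluded from the sum
and the maximum (6), never imputed. A normalized score
(composite/maximum) is available for cross-system display but is never
used for classification, because a 5/6 corn operation and a 5/9 orchard
are not the same evidence.

Rangeland items are ordinal 0–2: ivermectin use (none → 2; a single
annual application outside the grazing period → 1; multiple
applications, or any application during grazing → 0 — the timing flag
dominates the count because suppressing dung fauna during the grazing
season is the harm the item tracks), stocking density (< 5 AU/ha → 0,
5–10 → 1, > 10 → 2; high density here indicates adaptive multi-paddock
management, where large herds graze small paddocks briefly), rotation
frequency (≥ 30 d → 0, 10–30 d → 1, < 10 d → 2; never-rotated pastures
code 0) and rest period (continuous grazing → 0, 1–30 d → 1, > 30 d →
2).

Bin edges not fixed by the wording of the questionnaire are resolved as
follows and asserted in tests: stocking density is a closed middle bin
([5, 10] → 1); rotation at exactly 30 d codes 0 and exactly 10 d codes
1 (honouring the strict/weak inequalities that are stated); rest at
exactly 30 d codes 1. A rest period strictly between 0 and 1 day is
coded 1 (rested) with a warning, since the smallest stated bin edge is
one day. No item is weighted and there is no partial credit for
reduced-rate chemical use.

The packaged practice matrices (36 cropland operations, 52 ranches)
carry each row's item codes and printed composite. Two rows of the
source tables are arithmetic errata — their own codes sum to a value one
higher than the printed composite — and are recorded as such in
`regenscore.datasets.ERRATA`; recomputation reproduces the other 86
rows exactly.

## Gap-threshold classification

Observed composite scores are bimodal, so the classifier is exactly what
the eye does: sort the distinct scores, find the widest gap between
consecutive values, and divide at the midpoint rounded half up. Ties
between equally wide gaps break toward the higher gap, keeping the
conventional cluster anchored at zero; the rule is deterministic and
invariant to input order and duplication. On the packaged matrices the
dividing scores are 3 (rangeland, gap 2–4) and 5 (almond orchards, gap
3–6, midpoint 4.5). The corn subset's widest gap is (1, 3): the midpoint
rule gives 2 while the gap's upper edge is 3; both conventions are
exposed (`dividing_score` and `gap_high`) rather than silently choosing.
Thresholds are fitted per system — scores with different maxima are
never pooled. A score landing strictly inside a fitted gap (possible
only for operations scored after fitting) is labelled by the dividing
score and flagged `in_gap`. No model-based clustering is used: the claim
being operationalized is a visible gap, and fitting mixtures would
manufacture precision the data do not contain.

## Soil metrics

All desk formulas start from reported masses and volumes; lab protocol
(drying temperatures, sieving, grinding) is upstream of this package.

* **Loss-on-ignition organic matter**: `100·(dry − ignited)/dry` %.
* **fPOM**: the organic share of the sieved 53–500 µm fraction as a
  percent of initial soil mass, `100·(fraction_dry − fraction_ash)/
  initial`.
* **Bulk density**: core dry mass over cylinder volume, g/cm³.
* **Infiltration**: a single-ring kit pours 444 mL into a 15-cm ring
  (≈ 2.513 cm of water, the one-inch standard); the rate is
  depth/time·3600 cm/hr. Both pours are computed; the second (wet-soil)
  pour is the headline rate.
* **Haney soil-health score**: 1-day CO₂-C/10 + WEOC/50 + WEON/10, in
  ppm; linear and additive by construction.
* **Equivalent-soil-mass (ESM) stocks**: cumulative soil mass and
  cumulative element mass (both Mg/ha; 1 g/cm³ over 1 cm = 100 Mg/ha)
  are accumulated at layer boundaries from (0, 0), interpolated with a
  monotone cubic (PCHIP), and evaluated at a reference soil mass
  (default 6,000 Mg/ha). Comparing stocks at equal mass rather than
  equal depth removes compaction bias. Profiles holding less soil than
  the reference raise an error — stocks are never extrapolated. The
  depth at which the reference mass is reached is reported as a
  diagnostic.

**Why a monotone cubic.** Cumulative mass curves are physically
non-decreasing; a natural cubic spline can overshoot knots and produce
locally decreasing stock estimates on contrasting layers. PCHIP is exact
at every knot, strictly monotone between them, and bounded by the
bracketing knot totals. A natural-cubic option (`spline="natural"`)
exists for sensitivity checks. Between knots a cubic models curvature
that a piecewise-linear interpolation cannot: on sparse profiles the two
can differ by several percent mid-interval (e.g. 78.125 vs 75.0 Mg/ha at
a reference between the knots of a two-layer profile with 2% over 1% C).
This is an intrinsic property of splining sparse cumulative data, not an
implementation artifact; the test suite asserts the knot-exactness,
monotonicity and bracketing guarantees, and documents the spline-vs-
linear difference.

Per-field values are arithmetic means of core replicates.

## Community metrics

Shannon diversity uses the natural log (H = −Σ p·ln p); "DS" is the
Gini–Simpson index 1 − Σ p², with the inverse form 1/Σ p² behind a flag.
Richness counts morphospecies with at least one specimen; guild
abundances (coprophage, predator, parasitoid, herbivore, pest, other)
partition total abundance exactly. Morphospecies identifiers are opaque
keys — no taxonomic normalization is attempted. Per-operation indices
are computed on counts pooled across replicate samples (replicates
composited into one value per operation); a per-sample-then-average mode
exists for sensitivity, since the original compositing convention is
ambiguous. Ground cover is binned into half-open classes [0,25), [25,50),
[50,75) and the closed top bin [75,100] — the printed class labels
overlap at their edges, so the half-open convention is fixed here. The
disc-pasture-meter biomass index is the mean compression height in cm,
an index rather than calibrated mass.

## Validation statistics

Each response is regressed on the composite score:

* **OLS** (`fit_score_regression`): outcome on intercept + score
  (+ clay % untransformed, where soil texture confounds carbon
  measures). Replicate rows are composited to one value per operation by
  default; score enters as an integer covariate, never as a factor.
  Reports per-term estimates/SE/t/p, overall F with (k, n−k−1) df, R².
* **Linear mixed models** (`fit_mixed_model`): raw replicate rows with a
  random farm intercept, optionally field nested within farm (variance
  component) and a month fixed factor; REML estimation via statsmodels
  MixedLM. Fixed-effect p-values are Wald (z-based); the containment-df
  F convention is approximated by t², so small p-value differences from
  other software are expected and documented. When the random variance
  estimates to zero the GLS fit is the OLS fit; because numerical
  optimizers stop just short of the boundary, the boundary case is
  detected by a restricted-likelihood-ratio comparison against the
  zero-variance model (statistic < 1e-3 → refit as OLS, noted in the
  result). If every farm has a single observation the variance is
  inestimable: the fit warns and falls back to OLS.
* **Variability trend** (`variability_trend`): the coefficient of
  variation (sample SD over mean) of operation-composited outcomes per
  integer score level, regressed on the level; requires ≥ 3 levels with
  ≥ 2 operations each, df = (levels − 2). A level with zero mean has an
  undefined CV and raises.

`run_validation` drives a list of model specs, captures per-entry
failures without aborting the batch, and labels each score slope
positive/negative/ns at two-sided α = 0.05 (a "marginal" flag covers
0.05 < p ≤ 0.10 as presentation only). No multiple-testing correction is
applied; the report carries the number of models fitted so readers can
apply their own.

## Synthetic data generator

The generator produces data with the structure the analysis assumes, so
calibration claims are testable end to end:

* **Profiles.** Each operation is latently regenerative with probability
  `p_regenerative` (default 0.5). Its per-practice adoption propensity is
  a Beta draw whose mean is the class base rate (defaults 0.90
  regenerative, 0.08 conventional) pulled toward the class extreme as
  `adoption_coupling` grows, and whose spread grows with coupling: at
  coupling 0 practices are adopted independently at the base rate, at
  infinite coupling every operation adopts all-or-nothing. The default
  (coupling 1) yields the strongly bimodal score distribution seen on
  real operations, separable by the gap threshold with ≥ 95% agreement
  to the latent class at n = 200. Rangeland ordinal items are
  Binomial(2, propensity) draws; coded answers are converted back to
  representative natural-unit questionnaire answers so the full rubric
  path is exercised.
* **Outcomes.** `outcome = intercept + slope·score + clay_slope·clay +
  farm_effect (+ field_effect + month_offset) + ε`, with clay drawn once
  per operation (a soil property), farm/field effects Normal, and
  ε ~ N(0, (residual_sd·(1 + inflation·score))²). The default effect set
  reproduces the qualitative sign pattern the score is meant to predict
  — soil carbon up (+2 Mg/ha per point, clay co-factor 0.4), yield
  slightly down (−0.15 per point), pests flat, profit up (+60 per point)
  with score-inflated variability — at field-plausible magnitudes.
  Magnitudes are not calibrated to any particular dataset. For profit,
  the SD inflation (0.4 per point) deliberately outpaces the relative
  mean growth (60/250 = 0.24 per point): SD/mean must rise with the
  score for the generator to emulate growing variability among more
  regenerative operations, and inflation below that ratio would shrink
  the CV instead.
* **Communities.** Per-operation species count Poisson around
  `base_richness + richness_slope·score` (defaults 8 + 1.5/point,
  floored at one species), per-species abundances log-normal (µ = 1.5,
  σ = 1.0 — heavy-tailed counts with a long right tail, as specimen
  counts are), guilds assigned by configurable proportions.
* **Soil profiles.** Probe-style layered profiles: even-with-jitter
  depth increments, surface %C uniform in 1.2–3.0% declining
  exponentially with depth (decay 0.015–0.035 /cm, each layer carrying
  its analytic depth-mean), bulk density 1.0–1.3 g/cm³ rising slowly
  with depth, %N at a 10:1 C:N ratio. Early drafts drew layer %C
  independently, which produced un-soil-like several-fold jumps between
  adjacent layers; the exponential-decline model matches how carbon is
  actually distributed in mineral soils.

All draws descend from one integer seed through named substreams (one
per sub-generator and per outcome), so adding an outcome never perturbs
another's draws and every bundle is byte-reproducible under (config,
seed).

**What the generator does not emulate:** spatial structure and
autocorrelation, weather and season beyond additive month offsets,
market/price dynamics, measurement error in the questionnaire answers,
missing data, and any correlation between outcomes within an operation
beyond what the shared score induces. Passing calibration tests on this
generator therefore shows the estimators are correct and calibrated
under the assumed model — not that the model captures every feature of
real farm data.

## Calibration results the tests compute

The suite verifies, by Monte Carlo on the generator: type-I error of the
score test at α = 0.05 within 5% ± 2% over 2,000 null replicates
(n = 24 operations each); mean OLS slope within 5% of the generating
slope over 500 replicates (n = 40); exact agreement (±1e-6) between the
mixed-model and OLS fixed effects when the farm variance estimates to
the zero boundary; a positive CV-vs-score slope in > 90% of replicates
under score-proportional SD and a mean slope within 3 standard errors of
zero under homoscedasticity (200 replicates each, n = 80); and the full
simulate → score → classify → validate round at n = 200 recovering the
generating sign pattern and ≥ 95% latent-class agreement. Problem sizes
were chosen to give these checks adequate power while keeping the whole
suite around half a minute on one CPU.

## Known limitations

* The rubric is practice-based by design: it measures management
  choices, not outcomes, and inherits the questionnaire's honesty.
* The gap threshold is undefined when all operations share one score and
  is sensitive to single operations landing inside a former gap; the
  `in_gap` flag marks such cases rather than hiding them.
* Mixed-model inference uses Wald z p-values, not Satterthwaite or
  Kenward–Roger degrees of freedom; with few farms the p-values are
  anti-conservative.
* ESM stocks between layer boundaries depend on the interpolant (see
  above); reported stocks at a reference mass within the sampled range
  are bounded by data, but sparse profiles make mid-interval values
  interpolation-dependent by a few percent.
* Net profitability is direct costs and revenues only — no overheads,
  depreciation, inflation or discounting; currency is unit-agnostic.
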