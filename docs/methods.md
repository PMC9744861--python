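# Methods

## Study design emulated by the package

The pipeline mirrors a national-scale analysis of opportunistic insect
records: 1x1 km squares are stratified into bioclimatic zones defined by
biogeographic region and an elevation split at 1000 m a.s.l. (squares with
mean elevation below 1000 m are "low"); separate occupancy-detection models
per species yield annual mean occupancy per zone and country-wide; trends
over the full period and over consecutive 5-year intervals feed a
hierarchical regression on climate-change and land-use-change variables;
and counterfactual scenarios decompose how much of the long-term trends
each driver explains.

## Occupancy-detection model

One model per species.  Latent occupancy `z[i,t] ~ Bern(psi[i,t])`,
detections `y[i,t,j] | z ~ Bern(z * p[i,t,j])`.  Occupancy: global
intercept, linear and quadratic scaled elevation, fine-region and square
random intercepts, and zone-wise random-walk year effects
`gamma[r,1] ~ N(0, 1.5^2)`, `gamma[r,t] ~ N(gamma[r,t-1], sigma_gamma_r^2)`
with `sigma_gamma_r ~ half-Cauchy(0,1)` (truncated to the positive half
since it is a standard deviation).  Detection: scaled day-of-year (linear +
quadratic), list-length classes 1 / 2-3 / >3 as two dummies, a five-level
source factor (common naturalist as reference; expert naturalist, project,
species-targeted project, red-list inventory), and a year random intercept.

Priors: intercepts and slopes `Normal(0, 1.5)` — wide on the logit scale
without piling mass at 0/1 — hierarchical SDs `half-Normal(0,1)` except the
random-walk SD above.  All are configurable through the `priors` argument;
the defaults are deliberate, not fitted.

The latent state is marginalized analytically: a site-year with visits
contributes `psi * prod_j Bern(y_j|p_j) + (1-psi) * 1{all y_j = 0}`; a
site-year without visits contributes nothing to the likelihood but still
enters derived occupancy.  Marginalization makes the likelihood exactly
testable against brute-force enumeration over latent configurations (the
test-suite does this on hundreds of random tiny instances to 1e-10).

### Sampling

With no probabilistic-programming backend in the dependency stack, the
sampler is a blocked adaptive Metropolis-within-Gibbs scheme written for
this likelihood's structure:

* square effects, fine-region effects, zone-year effects and detection-year
  effects are updated as *vectorized independent Metropolis steps*: each
  site-year belongs to exactly one unit of each block, so all units of a
  block can be proposed and accepted/rejected simultaneously;
* zone-year effects alternate even/odd years so that random-walk prior
  neighbours are held fixed within a sweep;
* global occupancy and detection coefficient blocks use joint random-walk
  proposals; SD parameters are updated on the log scale (with Jacobian);
* proposal scales adapt by Robbins-Monro during warm-up only (targets 0.44
  scalar / 0.25 block), keeping the post-warm-up chain valid.

Defaults follow a 4-chain scheme with 1000 warm-up and 1000 kept sweeps;
the demo pipeline and tests run 2 chains x (300-500 post-warm-up sweeps),
which recovers a known constant occupancy of 0.7 to within 0.01 with
nominal interval coverage (see `scripts/acceptance.py` output).  Split-R̂
is computed with arviz for every derived mean-occupancy value and reported
per species; values above 1.1 are flagged, never silently accepted.  A
simulation-based-calibration test (single-zone reduced design, parameters
drawn from the priors, 100 replicates) checks that 90% central intervals
for the occupancy intercept cover at the nominal rate.

### Derived occupancy

Per posterior draw, `psi` is evaluated for every included square and year
(psi-based rather than finite-sample z: smoother and exact per draw).  Zone
series are means over the zone's squares; the country-wide series is the
square-count-weighted mean with squares in zones lacking any record of the
species contributing zero occupancy — consistent with the per-species zone
filter, which withholds such zones from the model.

## Record and visit preparation

A visit is all records by one observer or project on one day in one square.
Filters: non-adult records dropped; squares recorded in a single year
dropped (no information about change); records outside the study range
dropped, with an optional warm-up decade per group (fitted but trimmed from
derived series); species kept only if recorded in >= 25% of analysed years.
Per species, visits are excluded when (a) they come from a project whose
taxonomic focus excludes the species, (b) they fall outside the 5-95%
empirical quantile range of the species' recorded day-of-year (type-7
quantiles, boundaries inclusive, pooled over years and zones), or (c) they
come from a zone without any record of the species.  Expert naturalists are
observers in the top 2.5% by total records who made at least one visit in
the top 2.5% of visits by record count; with heavily tied count
distributions the inclusive quantile cut can admit boundary ties, which is
the documented tie policy.

## Trends

Per-draw OLS slopes of mean occupancy on year, expressed as change over the
window (slope x window length): one 40-year national trend and 5-year
(optionally 10-year) interval trends per zone.  Summaries follow the
draws: counts of increasing/decreasing species per draw with HDIs;
declining/increasing quarters fixed by posterior-mean ranking with
uncertainty propagated by averaging inside the fixed set per draw; percent
change relative to the species' 40-year mean occupancy; a bootstrap
(n = 9999) CI for the rank where trends change sign, resampling species
point estimates; and the mean-occupancy comparison of increasing versus
decreasing species.  Exact zero trends count as negative (deterministic
tie-break).  All intervals are highest-density intervals (shortest interval
with the requested mass).

## Drivers and traits

Climate per zone-year from monthly series: BIO1 (mean of monthly means),
BIO4 (standard deviation of the 12 monthly means, not x100), BIO18
(precipitation of the warmest consecutive 3-month window, December-January
wrap allowed, the standard bioclim convention).  Interval climate change is
the OLS slope over the interval extended 5 years backwards (10-year
window), scaled by the interval length — the longer window buffers single
extreme years.  Land-use series (agricultural area, grassland area,
livestock units, crop areas with per-crop insecticide application rates
from a config table) are gap-filled with a GCV smoothing spline — exact
through dense noise-free data, smooth in gaps, linear-interpolation
fallback below 4 points — then converted to agricultural-area proportion,
grassland-use intensity (LSU per grassland area) and crop-use intensity
(area-weighted application rate over zone area).  Land-use change is the
interval endpoint difference of the smoothed series (a slope-based variant
is available); climate uses the regression form as described.  All change
variables are centred and scaled over their zone x interval replicates and
the constants stored, so the scenarios' "absolute zero" maps exactly to
`-mean/sd` in standardized space.

Traits: the temperature niche is the unweighted mean temperature of the
grid cells where a species was ever recorded (duplicates within a cell do
not count twice); habitat specialisation is `1 - n_i / N_group`, min-max
rescaled within each insect group to [0, 1].

## Trend regression

Response: sign-preserving square root of the 5-year trend (normalises
residuals; inverted exactly by sign-preserving squaring).  The response is
the posterior mean of the trend; measurement error in the trend estimates
is not propagated into the regression (extension point).  Fixed effects and
the interaction structure are enumerated and test-pinned (41 columns at 3
groups x 8 intervals): group and interval factors in sum-to-zero coding,
elevation coded -0.5/+0.5 so driver main effects average over elevations,
no elevation x crop-use-intensity term (crop fields are too scarce at high
elevation to identify it).  Zone random intercepts; species random
intercepts plus independent random slopes for the six drivers and the nine
climate x land-use interactions (independent rather than fully correlated:
at 16 slope dimensions a full covariance is not identifiable at desk
scale).  Priors: `Normal(0,1)` fixed effects, `half-Normal(0,1)` SDs.

Three versions handle species not associated with agriculturally influenced
habitats: version 1 zeroes the agricultural-area and grassland-intensity
columns (fixed and random-slope) for those species, which under linearity
restricts those parameters' likelihood contributions to agri species in a
single fit; version 2 drops non-agri species; version 3 uses everything.
Sensitivity refits drop flagged species plus the lowest 20% of species per
group by records, or species-zone combinations with fewer than 41 records.

Inference is blocked Gibbs: coefficients, zone intercepts and per-species
effect vectors have conjugate Gaussian full conditionals (species blocks
drawn with batched Cholesky solves), SDs are slice-sampled.  Residual
normality and lag-1 autocorrelation diagnostics are reported.

## Scenarios

17 scenarios: all drivers zeroed; each single driver restored; each
climate x land-use pair; all drivers.  Zeroing replaces the uncentred
change by 0 via the stored scaling constants, identically across zones and
intervals; elevation, interval factor, traits and all random effects stay
at their observed/draw values, isolating the drivers' contributions.
Predictions are made per (species, zone, interval) on the transformed
scale, back-transformed by signed squaring, summed over the intervals per
species x zone, and averaged over zones weighted by the number of squares
per zone — back-transform strictly before aggregation, which a test pins.
Observed long-term trends for the R² comparison are the same aggregation
applied to the estimated short-term trends.  Scenario predictions use the
agri-species-only model version so land-use effects are not diluted.
Draws with numerically constant predictions score R² = 0 by convention.

## Synthetic study system

The generator emulates the statistical structure the analysis assumes, with
known ground truth:

* **Landscape**: 9 zones (5 regions x 2 elevation classes, the lowland
  region low-only), 50 squares/zone by default, continuous elevations drawn
  within class ranges, 2-3 fine regions per region.
* **Drivers**: monthly temperature/precipitation per zone with zone-specific
  trends (defaults 0.02-0.07 °C/yr warming, modest seasonality and summer
  precipitation trends) plus noise, including a 5-year lead-in so interval
  regressions have full windows; land-use series with smooth multi-decadal
  change and missing years in the pre-census era (gap fraction 0.5) to
  exercise gap-filling.
* **Species**: three groups (defaults 20/10/7 species), temperature niches
  around group means (dragonflies and grasshoppers warmer-adapted than
  butterflies), specialisation from simulated habitat lists through the
  real index, agri-association in butterflies/grasshoppers only.
* **Occupancy dynamics**: the ground-truth driver signal enters through the
  zone-year effect (drift per year = sum of standardized driver changes x
  effect sizes x trait modulation, plus random-walk noise), *not* through
  per-square covariates — the fitted occupancy model is driver-blind and
  estimates year effects freely, so this is where recoverable signal must
  live.  True trends are OLS slopes of the generated mean-psi series.
* **Observation**: visits per square-year are Poisson (default intensity 2),
  days uniform in group season windows, observers drawn with power-law
  activity weights (guaranteeing an expert tail for the 2.5% rules), five
  source categories with targeted projects recording only their focal
  species; detection is Bernoulli(z x p) with a latent visit-effort term,
  observer skill correlated with activity, and year noise; list length is
  recomputed from the emitted records, so the effort covariate is
  endogenous exactly as in real opportunistic data.

What the generator does *not* emulate: phenological dynamics beyond the
season window, spatial autocorrelation beyond square effects, observer
misidentification, and drifting data-source composition.  Passing tests
therefore demonstrate that the machinery recovers truth under the model's
own assumptions plus realistic observation heterogeneity — not that those
assumptions hold for any particular real dataset.

## Numerical choices and problem sizes

Quantiles are empirical type-7 with inclusive boundaries.  Constant-series
standardization raises an error naming the variable.  Degenerate designs
(single year, zero detections) are rejected with explicit messages.  The
test-suite and acceptance script use reduced problem sizes chosen for
desk-scale runs: occupancy recovery at 100 squares x 10 years x 3 visits
with 2 chains; regression recovery at 200 species x 9 zones x 8 intervals;
the demo pipeline at 3 zones x 40 squares x 21 years x 12 species.  These
sizes give Monte Carlo error comfortably inside the asserted tolerances.

## Known limitations

Trend measurement error is not propagated into the regression; random
slopes are independent; the occupancy sampler is tuned for the model's
blocked structure and would mix poorly if visits informed strong
cross-block posterior correlations (e.g., extremely sparse detections with
very strong covariate effects); and the scenario R² inherits the
regression's linearity on the signed-sqrt scale.
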