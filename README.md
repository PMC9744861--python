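# occutrend

Occupancy-detection modelling and driver attribution for opportunistic
species records.

Opportunistic biodiversity records — sightings reported by naturalists,
surveys, and projects with wildly uneven effort — are the only long-term,
large-scale data source for most insect groups. `occutrend` reconstructs
species distribution trends from such records while correcting for imperfect
and heterogeneous detection, and then asks *why* distributions changed, by
relating short-term trends to climate and land-use changes and by predicting
long-term trends under counterfactual driver scenarios.

The package is aimed at quantitative ecologists working with faunistic
record databases (butterflies, grasshoppers, dragonflies and similar
groups), and at anyone who wants a fully synthetic, ground-truthed testbed
for occupancy-trend attribution methods: every stage runs end-to-end on
simulated data with known truth, no restricted data downloads required.

## The model

For each species, square *i* and year *t* carry a latent occupancy state
and each visit *j* a detection:

```
z[i,t]   ~ Bernoulli(psi[i,t])
y[i,t,j] | z[i,t] ~ Bernoulli(z[i,t] * p[i,t,j])

logit(psi[i,t]) = mu_o + b_o1*elev_i + b_o2*elev_i^2
                  + a_region(i) + a_square(i) + gamma[r(i), t]
logit(p[i,t,j]) = mu_d + b_d1*yday_j + b_d2*yday_j^2
                  + b_d3*shortlist_j + b_d4*longlist_j
                  + b_d5*expert_j + b_d6*project_j
                  + b_d7*targeted_project_j + b_d8*redlist_j + a_dyear(t)
```

The year effect `gamma[r,t]` is a separate random walk per bioclimatic zone
(`gamma[r,t] ~ Normal(gamma[r,t-1], sigma_gamma_r^2)`), which lets each
zone's trajectory move freely while smoothing year-to-year jumps.  The
latent states are marginalized analytically and the model is sampled by a
blocked adaptive MCMC scheme (see `docs/methods.md`).

Derived annual mean occupancy series (per zone and country-wide) are
reduced to linear trends: one 40-year national trend per species and
short-term trends over consecutive 5-year intervals per zone.  Signed-sqrt
transformed short-term trends are regressed on standardized climate-change
(annual mean temperature, temperature seasonality, summer precipitation)
and land-use-change variables (agricultural-area proportion, grassland-use
intensity, crop-use intensity), species traits (temperature niche, habitat
specialisation), elevation and their interactions, with zone and species
random effects including per-species driver slopes.  Finally, 17
counterfactual scenarios (every driver zeroed, single drivers restored,
climate x land-use pairs, all drivers) are pushed through the fitted
regression to ask which drivers explain the observed 40-year trends,
measured as squared Pearson correlation (R²) between predicted and observed
species trends.

## Worked example

```python
from occutrend.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    outdir="runs/quickstart", seed=42,
    sim=dict(n_zones=3, n_squares_per_zone=40, n_years=21, start_year=1980,
             n_species_per_group=(5, 4, 3)),
    occ_mcmc=dict(chains=2, n_iter=300, warmup=300, thin=2),
    reg_mcmc=dict(chains=2, n_iter=300, warmup=250, thin=1))
res = run_pipeline(cfg)

summ = res["trend_summary"]
print(f"species fitted: {summ['n_species']}")
print(f"increasing: {summ['n_positive']['mean']:.1f} "
      f"[{summ['n_positive']['hdi_low']:.0f}, {summ['n_positive']['hdi_high']:.0f}]")
print(f"declining quarter change: {summ['declining_quarter']['change']['mean']:.4f}")
print(f"increasing quarter change: {summ['increasing_quarter']['change']['mean']:.4f}")
top = res["scenario_table"].sort_values("r2_mean", ascending=False).head(3)
print(top[["scenario", "r2_mean"]].to_string(index=False))
```

Output (a couple of minutes on one CPU):

```
species fitted: 12
increasing: 7.3 [5, 9]
declining quarter change: -0.0619
increasing quarter change: 0.0953
                              scenario  r2_mean
                                  full 0.404368
temp_mean_change+crop_intensity_change 0.150011
 summer_precip_change+agri_area_change 0.126229
```

Reading this: of 12 simulated species, on average 7.3 have a positive
40-year trend in mean occupancy (the share of 1-km squares occupied); the
25% of species declining fastest lose 0.062 in occupied-square proportion
over 40 years while the fastest-increasing quarter gains 0.095; and the
scenario keeping all drivers at their measured trajectories explains the
most variance in the species' long-term trends.

The same run is available from the shell:

```
occutrend --seed 42 --outdir runs/quickstart all
```

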