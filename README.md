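# contactcalls

Vocal-dialect analysis for parrot contact calls: fundamental-frequency trace
conditioning, dynamic-time-warping acoustic distances, principal-coordinate
ordination, and a multilevel Bayesian decomposition of acoustic variance into
city, park, and individual levels — with a pseudoreplication sensitivity
simulation and a ground-truth-known synthetic-data generator.

## Who this is for

Bioacousticians studying geographic variation in vocalizations of open-ended
vocal learners (the motivating system is invasive European monk parakeets,
*Myiopsitta monachus*, recorded in parks across multiple cities). The core
question the pipeline answers: at which spatial scale do calls differ —
between parks within a city (group-level convergence) or only between cities
(cultural founder effects / drift) — and is any park-level signal
distinguishable from an artifact of assigning calls of untagged birds to
pseudo-individuals?

## The model

Each call's position on a standardized principal-coordinate axis (PC1 or
PC2, obtained from DTW distances between smoothed f0 contours) is modelled
as

    y_i     ~ normal(α_city[i] + α_park[i] + α_ind[i], σ_obs)
    α_city  ~ normal(μ_city, σ_city)
    α_park  ~ normal(0, σ_park)
    α_ind   ~ normal(0, σ_ind)
    μ_city  ~ normal(0, 1)
    σ_*     ~ exponential(2)

fitted by a No-U-Turn sampler (implemented in the package, non-centered,
validated against an independent ensemble sampler). σ_city and σ_park are
directly comparable: σ_city ≫ σ_park is the signature of city-level dialects
without park-level convergence. Individual effects — true IDs where
annotated, 5-minute-window pseudo-IDs otherwise — absorb repeated calls from
the same bird. See `docs/methods.md` for the full account.

## Worked example

Simulate calls from a known hierarchy (8 cities × 3 parks × 4 birds × 8
calls; σ_city = 0.40, σ_park = 0.21, σ_ind = 0.5, σ_obs = 0.5), fit the
model, and summarize the scale parameters:

```python
from contactcalls import (GeneratorConfig, simulate_model_level,
                          build_model_data, fit, summarize_sd)

cfg = GeneratorConfig(n_cities=8, parks_per_city=3, inds_per_park=4,
                      calls_per_ind=8, sigma_city=0.40, sigma_park=0.21,
                      sigma_ind=0.5, sigma_obs=0.5, p_labeled=1.0, seed=8)
metadata, truth = simulate_model_level(cfg)
data = build_model_data(metadata, metadata["y"].to_numpy())
post = fit(data, seed=1)                      # 4 chains x 1000+1000, NUTS
print(summarize_sd(post).round(2).to_string(index=False))
```

which prints

```
 parameter  mean  lower  upper  prob
sigma_city  0.46   0.21   0.77  0.89
sigma_park  0.26   0.05   0.48  0.89
 sigma_ind  0.59   0.51   0.69  0.89
 sigma_obs  0.52   0.50   0.54  0.89
```

Each row is a posterior mean with its 89% equal-tailed interval: the model
attributes SD ≈ 0.46 of the (standardized) acoustic axis to between-city
variation and ≈ 0.26 to between-park variation, both intervals comfortably
covering the generating values (0.40 and 0.21 — this seed's realized
city-effect SD is 0.455). `level_means` gives per-city and per-park
posterior locations, and `city_contrasts` the pairwise city differences with
exclusion-of-zero flags.

The same analysis runs end-to-end from f0 contours (conditioning → DTW →
PCoA → fit) via the CLI:

```sh
contactcalls simulate --seed 3 --outdir sim/
contactcalls process sim/traces.csv --out cond.csv
contactcalls distance cond.csv --out dist.csv
contactcalls ordinate dist.csv --out ord.csv
contactcalls fit sim/metadata.csv ord.csv --axis pc1 --outdir fit/
```

or in one shot from a YAML config with `contactcalls run --config run.yaml`,
which writes every intermediate artifact plus a manifest (seed, config hash,
sampler diagnostics). `contactcalls sensitivity` runs the incorrect-pooling
experiment.

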