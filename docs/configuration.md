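# Run configuration schema (v1)

`glucotrend run` (and each stage subcommand) accepts a single YAML document
via `--config`; flags (`--outdir`, `--seed`, `--reduced/--full`) override
the corresponding keys. All keys are optional except `outdir` when no flag
is given.

```yaml
# schema_version: 1
outdir: runs/demo          # output directory; every artifact lands here
seed: 11                   # global seed; stages derive their own streams
reduced: true              # reduced test-scale preset (fewer studies/draws)

stages:                    # enable/disable stages; order is fixed
  simulate: true
  crosswalk: true
  fit: true
  derive: true
  validate: true

world:                     # synthetic-world generative process
  n_super_regions: 2       # hierarchy sizes
  n_regions_per_super: 2
  n_countries_per_region: 3
  year_start: 1980
  year_end: 2014
  sexes: [female, male]
  base_level: -1.55        # probit scale, at the mid-year, standard age mix
  trend_per_decade: 0.12
  sd_super_intercept: 0.15 # hierarchical deviation SDs (slopes per decade)
  sd_region_intercept: 0.10
  sd_country_intercept: 0.10
  sd_super_slope: 0.05
  sd_region_slope: 0.04
  sd_country_slope: 0.04
  sd_nonlinear:            # marginal SD of the RW2 smooth per level
    world: 0.04
    super_region: 0.03
    region: 0.03
    country: 0.03
  age_amplitude: 0.85      # probit range of the age profile
  age_steepness: 0.25      # multiplier slope per probit unit of level
  beta_education: -0.02    # covariate effects per SD of the z-scored column
  beta_urbanisation: 0.04
  beta_food: 0.03
  beta_bmi: 0.08
  rural_urban_gap: 0.25    # probit urban minus rural, constant over age

plan:                      # survey plan (forwarded to make_survey_plan)
  studies_per_country: 8
  scope_probs: [0.5, 0.3, 0.2]        # national / subnational / community
  urbanicity_probs: [0.82, 0.10, 0.08]  # mixed / urban_only / rural_only
  n_range: [400, 2500]                # per-stratum examined
  definition_probs:                   # definition mix of simulated studies
    PRIMARY_FPG7: 0.8
    OGTT_11_1: 0.1
    HBA1C_6_5: 0.1
  offset_subnational: 0.1  # probit-scale scope biases of the simulation
  offset_community: 0.2
  noise_sd: {national: 0.0, subnational: 0.07, community: 0.12}

model:                     # forwarded to ModelConfig (hierarchy and year
  chains: 2                # range are taken from the simulated tables)
  burnin: 600
  draws: 2000              # total retained post-burn-in draws (5000 at full scale)
  thin: 1
  rw2_rank: 5
  rw2_levels: [world, super_region, region, country]
  age_knots: [35, 50, 65]
  rhat_threshold: 1.1
  ess_floor: 100

holdout:
  scheme: random_fraction  # random_fraction | whole_study | whole_country
  fraction: 0.2
```

Input/output tables are UTF-8 CSV with a header row; age intervals are two
integer columns `age_lo`,`age_hi` (half-open, 80+ encoded as `80,200`).
The fit stage writes posterior draws to `draws.zarr` (chunked array
container with an index manifest in its attributes) and the run writes
`manifest.json` recording the stage list, per-stage inputs/outputs, seed,
configuration hash and package version.
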