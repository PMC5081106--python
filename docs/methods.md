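# Methods

This note documents the statistical choices in `glucotrend`: the generative
model behind the synthetic world, the harmonisation regressions, the
hierarchical probit model and its sampler, the derived outputs, and the
places where the design was genuinely open and a choice had to be made.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Scales, age groups and transforms

All modelling happens on the probit scale, `z = Phi^-1(p)`. Observed stratum
prevalences of exactly 0 or 1 are continuity-corrected as `(x + 0.5)/(n + 1)`
(Anscombe-style) before transformation; interior values are used as reported.
Sampling standard errors are mapped to the probit scale by the delta method,
`se_z = se_p / phi(z)`.

Adults are discretised into the age groups 18–19, 20–24, …, 75–79, 80+
(14 groups, half-open intervals) for populations, truth surfaces and
standardisation; the open-ended 80+ group is represented by age 82.5.
Surveys may report any union of these groups; a multi-group stratum is
modelled as the population-weighted mixture of its member groups on the
probit scale (the same convention the simulator uses), which anchors the age
spline across its whole support rather than at a single midpoint.

The standard population is the WHO world standard restricted to adults:
the 15–19 band's weight is split proportionally into 18–19, the 80–84 and
85+ bands are merged, and the weights renormalised over ages 18+. It ships
as a versioned CSV fixture (`glucotrend/data/who_standard_population_adult.csv`).

## 2. Synthetic world

`build_world` draws a ground-truth world from the same structural family the
model assumes: on the probit scale, a global level (default −1.55 at the
1997 midpoint, i.e. ≈ 6% at the standard age mix) and linear trend
(+0.12/decade); nested Gaussian level and slope deviations for
super-regions, regions and countries (SDs 0.15/0.10/0.10 and
0.05/0.04/0.04 per decade); smooth non-linear year components at every
level; a logistic age profile of amplitude 0.85 probit whose steepness
scales as `1 + 0.25·(level − base)`; and linear effects of z-scored country
covariates (education −0.02, urbanisation +0.04, food score +0.03, mean BMI
+0.08 per SD). These defaults produce adult prevalences rising from roughly
4–5% to 8–10% over 1980–2014 with realistic cross-country spread, matching
the order of magnitude of published global estimates for this period.

Non-linear year components are second-order random-walk (RW2) smooths in a
reduced-rank spectral basis: eigenvectors of the RW2 structure matrix with
positive eigenvalues, scaled by `1/sqrt(eigenvalue)`, null space (constant
and linear) removed because those directions are carried by the explicit
intercept/slope terms, and the basis rescaled to unit average marginal
variance so the SD parameter is the typical size of the smooth itself, not
of its innovations. Default marginal SDs: 0.04 (world) and 0.03 (lower
levels), rank 4.

Covariates are smooth per-country trajectories (education and BMI rising,
urbanisation logistic, food score slowly varying, log income rising); a log
income column is emitted for the cross-walk regressions but does not drive
true prevalence. Populations grow at 0.5–2.5%/year with an ageing pyramid
(exponential-decay age shares whose decay rate falls over time).

Surveys are simulated per study with an independent random stream derived
from `(seed, crc32(study_id))`, so output does not depend on iteration
order. A stratum's observed count is Binomial(n, Phi(z)) where z is the true
stratum probit shifted by: the scope offset (+0.1 subnational, +0.2
community by default), a study-level non-sampling draw (SD 0.07 subnational,
0.12 community, 0 national), and rural/urban selectivity — sub-surfaces are
defined by a single probit rural-urban gap (default 0.25) applied as
`gap·(study urban fraction − country urbanisation)`. Alternative-definition
studies report the definition-mapped quantity; MEAN_FPG studies report mean
FPG in mmol/L. The magnitudes of the scope biases are free parameters of
the simulation, chosen to be large enough to matter and small enough to be
realistic; they are not estimates of real-world biases.

## 3. Cross-walk regressions

For each non-primary definition, probit(primary prevalence) is regressed on
the source scale (probit of source prevalence; for mean-FPG sources, the
mean concentration centred at 5.6 mmol/L — the simplest monotone map), plus
age (decades from 50), sex, study year (decades from 1997) and log income
(centred at 9.0) when an income lookup is supplied. Strata with fewer than
25 examined people are excluded before fitting. All 8 subsets of the
candidate interactions {source×age, source×sex, source×year} are fitted and
the BIC-minimising subset retained. With more than 400 training datapoints
the regression includes regional random intercepts (fitted by ML so BIC is
comparable across candidates; a Powell restart is used if L-BFGS fails);
below that threshold a regional effect is judged unidentifiable and omitted.

Conversion maps a datapoint to the model's point prediction, back-transformed
to a proportion. Its standard error combines, by the delta method on the
probit scale: coefficient uncertainty (x'Vx), residual variance, the regional
random-intercept variance for an unseen region, and the datapoint's own
sampling error propagated through the (interaction-adjusted) source slope.
The output SE is floored at the input sampling SE — conversion never makes a
datapoint more informative than it arrived.

## 4. Hierarchical probit model

The linear predictor and likelihood are given in the README. Fixed choices:

- **Year** is centred at the range midpoint and scaled to decades,
  decorrelating intercepts and slopes.
- **Non-linear trends** use the same reduced-rank RW2 basis as the
  generator (rank 5 by default), at all four hierarchy levels
  (world/super-region/region/country), each level with its own smooth SD.
- **Age pattern** is a cubic B-spline over age (clamped at 18 and 85,
  interior knots 35/50/65), columns centred with the standard-population
  weights so the intercept carries the overall level. Its multiplier
  `1 + kappa·(F − c0)` (reference level c0 = −1.5) implements the steeper
  age gradient where prevalence is higher; the (A, kappa) parametrisation
  is bilinear, so each factor has a Gaussian full conditional.
- **Scope terms**: fixed offsets for subnational and community strata, and
  per-study Gaussian random effects for non-national studies with
  scope-specific SDs. Scope-specific non-sampling variances
  (subnational, community) add to the sampling variance in the likelihood;
  national strata carry sampling variance only.
- **Rural/urban**: one shared coefficient on the signed difference between
  study urban fraction and country urbanisation (zero for representatively
  mixed samples). A single coefficient is used because the simulation's
  single rural-urban gap makes separate urban-only/rural-only coefficients
  unidentifiable.
- **Covariates** are z-scored over the covariate table before entering.
- **Priors**: fixed effects N(0, 10²); age-spline coefficients N(0, 2²);
  kappa N(0, 1); half-normal priors on every SD (scales 0.5/0.3/0.3 for
  level intercepts, 0.2/0.15/0.15 for slopes, 0.1–0.15 for smooths, 0.3 for
  study effects, 0.25 for non-sampling SDs). These are weakly informative
  on the probit scale and config-overridable.

### Sampler

A blocked Gibbs sampler: (1) all linear coefficients jointly from their
Gaussian conditional (sparse-in-structure design, dense Cholesky solve);
(2) age-spline block; (3) kappa (scalar Gaussian conditional); (4) study
random effects; (5) SDs by slice sampling under their half-normal priors;
(6) scope non-sampling SDs by slice sampling of the marginal likelihood.
Two mixing repairs make the redundant-but-convenient parametrisation mix
well: *location sweeps* resample the non-identified shifts between each
parent level and its nested children (global↔super-regions, super-region↔
regions, region↔countries, for intercepts, slopes, each smooth-basis
coefficient, and between each scope offset and its studies' random
effects); and an *interweaved non-centred redraw* gives every SD a conjugate
truncated-Gaussian update with its unit-scale coefficients held fixed,
removing the funnel coupling between an SD and its block. Both moves leave
the likelihood invariant and target the exact posterior.

Chains (≥ 2, over-dispersed starts) run burn-in plus enough iterations to
retain the configured number of post-burn-in draws (default 5000 in total;
reduced presets use less). Convergence is monitored with split-R-hat < 1.1
and an effective-sample-size floor of 100 on all scalar parameters (fixed
effects, kappa, all SDs) via arviz; failure raises a RuntimeWarning and is
flagged (`converged: False`) in the stored diagnostics — it never passes
silently. Retained draws are transformed to prevalence on the full
country-year-age grid (national, representatively mixed population: scope,
study and urbanicity terms excluded) and stored as float32, with an
on-disk chunked zarr container plus an index manifest.

Datapoints are put into a canonical order before fitting, so the posterior
is exactly invariant to input order at a fixed seed.

## 5. Derived outputs

Age standardisation is the exact weighted sum over age groups, per draw.
Aggregates over countries (region, super-region, world) age-standardise
each member and weight by adult population. Crude prevalence and counts use
the actual population structure. The decomposition of a count change fixes
base-year weighting at t0 for both main components and keeps the
interaction as its own component, which makes `G + P + I` equal the total
change exactly and reproduces published share triples from published
component magnitudes; shares are reported as component over component sum.

Trend-continuation projection fits, per posterior draw, an ordinary
least-squares line on the probit scale to the draw's age-standardised
trajectory over 2000–2014 and extrapolates to 2025 — a deliberately simple,
config-overridable stand-in for "post-2000 trends continue". The target
probability is the fraction of paired draws with projected 2025 ≤ 2010
baseline; ties count as met (the non-strict reading of "no increase"). The
posterior probability of an increase between two years uses the strict
inequality, so equal years give 0.

## 6. Hold-out validation

Three schemes: withhold a random fraction of datapoints, whole studies, or
whole countries. Scoring compares the posterior-mean estimated prevalence at
each withheld stratum (population-weighted over its age groups) with the
observed prevalence, in percentage points; medians of the error and absolute
error are reported together with the share of observations inside the
2.5–97.5 posterior interval. Note that this interval is a credible interval
for the underlying prevalence, not a predictive interval for a noisy,
possibly non-national observation, so its empirical coverage of raw
observations is expected to sit well below 95% — the error medians are the
headline validation quantities.

## 7. Test and acceptance problem sizes

Test-scale runs use a 12-country world (2 super-regions × 2 regions × 3
countries), 35 years, one sex, 6–8 studies per country, and 2 chains with a
few hundred burn-in and 1000–3000 retained draws; replicate-fit checks
(coverage across worlds, target probabilities under flat versus steep
trends) use 4-country worlds at a few hundred retained draws. These sizes
were chosen as the smallest at which the hierarchical structure (three
nesting levels, data-rich and data-free countries, all three scopes) is
actually exercised.

The flat-trend target check deserves a note: for a well-calibrated
posterior and an exactly flat truth, the probability of meeting the target
in a single fitted replicate is close to uniformly distributed — it is the
posterior CDF evaluated at the true (zero) trend — so the meaningful
statement is about the mean over replicate fits, which the tests and the
acceptance script compute over 24 flat and 8 steep replicates. The flat
worlds zero the covariate effects as well as the trend because the default
covariates drift upward and would otherwise make the true surface rise.

## 8. Known limitations

- The linear calendar trend, the covariate effects and the smooth year
  components are partially confounded with only ~12 countries; endpoint
  years (especially the last) can show systematic errors of a couple of
  percentage points even when the all-years median error is ~0.2pp. More
  countries, or priors informed by external knowledge, would sharpen this.
- The likelihood treats probit-transformed prevalences as Gaussian with
  known sampling variance; for very small strata (n below a few hundred)
  at low prevalence this approximation is crude.
- Cross-walk uncertainty enters the main model only through the inflated
  standard errors of converted datapoints, not as a joint measurement
  model.
- Mixing rural and urban sub-surfaces is done on the probit scale, which is
  only approximately the population mixture of prevalences.
- The synthetic world draws covariate trajectories independently per
  country and cannot emulate regionally clustered covariate shocks, shared
  measurement campaigns, or informative survey placement (surveys landing
  preferentially where prevalence is changing); passing tests therefore
  demonstrate correctness of the machinery under the stated generative
  assumptions, not robustness to every feature of real survey ecosystems.
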