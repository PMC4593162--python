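# Methods

## Estimand and data model

The estimand is the mean energy-adjusted intake θ (g/day, standardised to a
2000 kcal/day diet) of one food group in each stratum — country × period
(1990, 2010) × adult age band × sex. The default age grid has eight bands
(20–25, 25–35, …, 75–80, 80+); with two sexes that is the 16 age/sex cells
per country-period the model estimates.

Two evidence streams inform θ:

* **Surveys** report the mean intake of a grouped cell: an age range that may
  span several model bands, one sex or both, with a sampling SE. The model
  expectation of such an observation is the population-weighted average of
  exp(η) over the covered strata ("age integration"), where η is the
  log-linear predictor. Weights come from stratum populations; partial band
  overlap is pro-rated linearly in age (uniform population density within a
  band; the open 80+ band gets a nominal 10-year width). Three indicator
  biases multiply the expectation: household-budget instrument, subnational
  coverage, secondary metric. Nationally representative individual-level
  primary-metric surveys are the unbiased reference by construction.
* **Food balance sheets** give per-capita availability for every country and
  year. Availability is modelled as the all-adult population mean intake
  times a crosswalk factor exp(δ_fao) learned jointly from countries that
  have both streams. A floored measurement CV of 0.25 keeps these rows from
  outweighing surveys where both exist. A flag (`fao_mode="covariate"`)
  instead moves log availability into the covariate vector; the likelihood
  arm is the default because it is what identifies the crosswalk.

Both arms use a lognormal error model: log(observed) ~ Normal(log(expected),
(SE/mean)² + τ²), where τ is a shared non-sampling SD. Observations with
non-positive means cannot enter a log-scale likelihood and are dropped with
a warning.

### Periods and time

Surveys from 1980–1996 inform the 1990 anchor, 1998–2010 the 2010 anchor,
and 1997 lies in both spans, so a 1997 survey is duplicated into both
periods rather than silently assigned to one. Because the trend γ is
log-linear, each survey's expectation additionally carries
exp(γ·(year − anchor)/10); this evaluates the model at the survey's actual
field year exactly and stops early-1980s surveys from biasing the 1990
level downward (or inflating τ).

## Parameters, priors, defaults

| Parameter | Meaning (log-intake scale) | Prior / default |
|---|---|---|
| μ0, γ, φ, β, δ_* | intercept, decadal trend, female offset, covariate coefficients, source biases | Normal(0, 10²) |
| α (age knots) | sum-to-zero age curve, one knot per band | Normal(0, 10²) plus first-difference smoothness N(0, 0.05²) |
| u_region, u_country | hierarchical deviations | N(0, σ_r²), N(0, σ_c²) |
| σ_r, σ_c, τ | hierarchy and non-sampling SDs | Half-Normal(1), sampled as logs (Jacobian included) |

The smoothness prior is load-bearing: surveys report coarse age ranges
(pairs of bands in the synthetic corpus), so age contrasts finer than the
reporting resolution are not identified by the likelihood at all. Shrinking
adjacent-knot differences toward zero resolves the within-range split the
way any age-integrating mortality/exposure model does. Its SD (0.05 on the
log scale per band step) matches the magnitude of plausible adult age
gradients (a 0.3 log-unit rise over seven steps ≈ 0.04/step) and was chosen
so that posterior z-scores of the truth on synthetic replicate worlds have
approximately unit standard deviation (a much looser 0.1 leaves the
intervals visibly conservative).

Covariates (log lag-distributed income, education years, four FAO
composition factors) are z-scored over the country-periods entering a fit;
coefficients are reported on that standardized scale. The four factors are
principal components (correlation-matrix PCA, since the 14 composition
variables sit on heterogeneous percent scales) of the log-percent
composition matrix; each loading column's dominant entry is forced positive
so factor signs are reproducible. Lag-distributed income uses a 10-year
geometric lag (weights ∝ 0.9^k, renormalised over the available prefix) —
the published estimates do not state a kernel, so the simplest reproducible
one is used and is configurable.

## Posterior computation

A single random-walk Metropolis chain with two standard adaptation layers:

* covariance adaptation — after 500 iterations the proposal covariance is
  s_d·(empirical chain covariance + 10⁻⁶·I), s_d = 2.4²/d, refreshed every
  50 iterations;
* global scale adaptation — a Robbins–Monro update (step t^−0.7) of a scalar
  multiplier targeting 0.234 acceptance.

The chain starts at an approximate posterior mode found by BFGS with the
three SDs held at interior values (σ_r = 0.3, σ_c = 0.2, τ = 0.1). Profiling
the SDs is essential: the joint density of a centered hierarchical model
diverges as an SD and its random effects shrink to zero together, and an
unconstrained optimiser will find that degenerate spike on small data sets,
stranding the chain in the funnel neck. The proposal is seeded with a
Laplace covariance from an explicit central-difference Hessian at that mode
(curvature eigenvalues floored at 0.01 so flat directions get a bounded
proposal variance).

Defaults: 160 000 iterations, 32 000 burn-in, thin 128 → exactly 1000
retained draws, ≈ 14 s per food on one CPU for the default 20-country world
(47 parameters, ≈ 390 observations, 640 strata). Shorter schedules mix the
fixed effects fine but leave split-R̂ of the hierarchical effects above
1.05; the default brings every parameter below ≈ 1.015. Reduced replicate
worlds in the tests use 20 000 iterations / 500 draws, which suffices for
interval calibration though not for publication-grade R̂. Acceptance rates
outside [0.05, 0.7] raise a warning. One master seed derives all stage seeds
(SHA-256, < 2³¹); identical configs reproduce every output bit-for-bit.

Retained parameter draws map through the predictor to a stratum × 1000
intake matrix. Draw d is one coherent world across strata, so differences,
aggregates and sums computed per draw index propagate correlated
uncertainty correctly.

## Post-processing conventions

* Mean = arithmetic mean of draws; 95% UI = 2.5th/97.5th empirical centiles
  with linear interpolation between order statistics (numpy's "linear"
  rule). A change is called statistically certain when the UI of the
  draw-level difference excludes zero.
* Aggregation is a population-weighted mean per draw; it is associative
  (strata → global equals strata → country → global to 10⁻¹²).
* Vegetables and legumes are fitted separately and summed at the draw level.
* Attainment thresholds are inclusive (≥ for protective foods, ≤ for
  harmful); g/day ↔ g/week conversions are explicit ×7. Optimal-intake SDs
  are 10% of the mean on the serving scale (e.g. whole grains: 10% of 2.5
  servings × 50 g = 12.5 g/day), which reproduces the published spreads
  exactly, including the whole-grain row where serving arithmetic and the
  printed gram mean disagree (2.5 × 50 g = 125 g vs the printed 100 g/day —
  the printed gram values are kept for means and thresholds).
* The annual series interpolates the anchors log-linearly per draw, plus a
  covariate tilt: β·(x_t − chord(x)) on the standardized covariate scale,
  using the fitted income/education coefficients. The tilt vanishes at the
  anchors and under linearly-moving covariates. Smoothing acts on levels,
  not residuals — the published footnote does not say which; levels keep
  anchor reproduction exact.
* Fold variation is max/min of the supplied means, rounded to an integer or
  one decimal per the requested convention.

## The synthetic world

The generator emulates the statistical structure the model assumes, with
known truth: region- and country-level log-normal heterogeneity (SDs 0.3 /
0.2), smooth monotone age curves (rising for healthful foods, falling for
harmful ones, 0.3 log-units total), a +5% female multiplier for healthful
foods (−5% for harmful), a log-linear decadal trend (±0.05), and base
intakes at realistic global scales (fruits 81 g/day, vegetables 209,
nuts/seeds 9, whole grains 38, seafood 28, red meat 42, processed meat 14).
Surveys arrive with probability 0.1 per country-year (≈ 60 surveys for 20
countries over 1980–2010, ≈ 83% nationally representative, ≈ 33% household
budget — proportions mirroring the real evidence base); individual-level
surveys report paired-band age ranges by sex, household surveys one all-adult
both-sex row. Planted biases: household budget ×1.2, subnational ×0.9,
secondary metric ×1.1. Reported SEs are cv·mean/√n with within-person
CV 0.5; a 0.05 log-SD non-sampling term is added on top. FAO availability
covers every country-year: population-mean truth × a country multiplier
drawn uniformly from [1.1, 1.8] × 0.10 log-SD noise; the 14 composition
variables carry a planted 4-factor block structure. Individual records have
configurable intake–energy correlation (default 0.3) around 2000 kcal/day.

What the generator does not emulate — and hence what passing tests cannot
certify about real data: non-log-normal survey error, correlated errors
within survey waves, country-specific time-trend deviations, migration or
country split/merge, informative missingness of surveys (presence is
independent of intake level), and seasonal or sub-national intake
structure. Recovery and coverage results are statements about a correctly
specified world of desk scale (20 or 6 countries), not about the 187-country
evidence base.

## Known limitations

* One chain; between-chain diagnostics are approximated by split-R̂ halves.
* The FAO crosswalk is a single global factor per food; per-country
  multiplier spread lands in the FAO floor CV and τ rather than being
  estimated.
* The MAP profiling SDs are fixed constants; pathological data far from
  their scale would slow early adaptation (the chain still corrects).
* Survey age ranges coarser than the band grid leave fine age structure
  prior-driven by design; the smoothness prior makes that explicit rather
  than hiding it.
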