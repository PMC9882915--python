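# Methods

`ccscreen` estimates cervical-cancer screening coverage trends for
sub-Saharan Africa from stratified survey tabulations, and derives from
them the quantities public-health monitoring needs: coverage by country,
year, age and HIV serostatus; the rate at which already-screened women are
re-screened; the fraction of women screened at least twice by age 45; and
pre-cancer treatment coverage. Because the survey microdata that motivate
the pipeline are access-restricted, the package ships a synthetic-data
generator with known ground truth, and every stage is validated against
that truth.

## 1. Data model and pre-processing

The unit of analysis is a survey stratum: one survey x country x 5-year
age band x recall period (lifetime / past 3 years / past year) x HIV
serostatus cell, carrying an *effective* screened count and denominator.
Effective sample sizes absorb the survey design effect; when only a
design-adjusted proportion with a confidence interval is available,
`effective_sample_size` inverts the normal approximation,
`n_eff = p(1-p)/se^2` with `se = (upper - lower)/(2 z)`. Boundary
proportions receive the continuity adjustment `(k + 0.5)/(n + 1)`.
For the binomial likelihood, effective counts are rounded to the nearest
integer pair preserving the observed proportion (denominator floor 1).

Countries are normalized to ISO3 via a packaged alias table; regions
follow the 2015 Global Burden of Disease classification with Western and
Central Africa pooled (few surveys in either) and Mauritius assigned to
Eastern Africa. A survey may contribute either serostatus-split rows or a
serostatus-mixed row per (age, recall) cell, never both; the loader
enforces this together with all type invariants.

## 2. Coverage trend model

Lifetime and past-3-year screening are modeled jointly. Each stratum
contributes `k ~ Binomial(n, p)` with

    logit p = beta0 + u_region + u_country + u_survey + alpha_age
              + (beta_year + v_region + v_country) * (year - 2010)/10
              + beta_recall * 1[past3y]
              + (gamma + g_region + g_country) * 1[HIV+]

Four nested levels (survey < country < region < overall) carry random
intercepts; calendar-year slopes and the HIV log-odds-ratio carry country
and region deviations, so regions can trend differently and the
HIV-screening association can vary by place. The year covariate is
centered at 2010 and scaled per decade, which decorrelates intercepts and
slopes over the 2000-2020 window. `beta_recall` is constrained
non-positive (a past-3-year screen implies a lifetime screen) through the
smooth transform `beta_recall = -exp(zeta)`.

Strata without serostatus information are marginalized exactly: with HIV
prevalence `pi` from the auxiliary tables, the success probability is the
mixture `pi * p_pos + (1 - pi) * p_neg`. This is what lets surveys with
and without serostatus be pooled and still identify `gamma` — and what
the mixture-identity test checks to 1e-12.

Priors are weakly informative: Normal(0, 2.5^2) on fixed effects (the
recall offset's truncated analogue), half-Normal(0, 1) on all seven
hierarchical SDs. Both scales are configurable. Lifetime and past-3-year
reports from the same respondents are treated as independent binomials;
no joint structure is imposed. Optional flags reproduce two sensitivity
analyses: restricting to surveys from 2010 onward, and a fixed effect for
WHS-type surveys.

### Posterior computation

Sampling uses a Hamiltonian Monte Carlo kernel written for this model
(`ccscreen.mcmc`), with analytic gradients, chains vectorized in one
process, MAP initialization, dual-averaging step size, and convergence
summarized by rank-normalized split R-hat and bulk ESS (arviz). Three
design choices matter for the hierarchical geometry:

- **Centered effects with scale-aware metric.** Design-effect-adjusted
  counts make every random-effect block data-dominated, where centered
  parameterization conditions best (non-centered parameterization puts
  the posterior on a hyperbolic z/sigma ridge and freezes the sampler).
  The funnel that centered parameterization develops as a scale shrinks
  is neutralized by the kinetic metric
  `M = H_like + diag(prior precision)`, with `H_like` the likelihood
  curvature estimated once at the MAP and the prior precision `1/sigma^2`
  tracking the current scales. The scales move only between trajectories,
  so the metric is constant within each trajectory and the kernel remains
  exact.
- **Scales by exact conditional updates.** Given centered effects, each
  hierarchical variance has a generalized-inverse-Gaussian conditional;
  `log sigma` is updated by slice sampling that closed form, interweaved
  with an ancillary-frame move (effects rescaled with the SD against the
  likelihood). The trajectory never has to traverse the funnel.
- **Recentering translations.** The likelihood constrains only sums such
  as `beta0 + u_region + u_country + u_survey`; the split across levels
  is prior-driven. Exact Gaussian translation moves shift one level and
  compensate the one below along these likelihood-null directions,
  decorrelating the hierarchy. Several sweeps of these closed-form moves
  run per iteration; they are what brings the scale parameters' effective
  sample size to the level the R-hat threshold requires.

Defaults: 4 chains, 1500 warmup + 4000 kept iterations (about one minute
on the default synthetic world). Fits warn loudly and are flagged, never
silently returned, when any R-hat exceeds 1.05. Divergent transitions
(energy error > 1000) are counted and reported; on the default world the
count is zero. The low-dimensional models below reuse the same kernel
with finite-difference gradients.

## 3. Post-stratification and imputation

Model strata are pooled into reporting aggregates (ages 30-49, combined
serostatus, country / region / all-SSA) with weights proportional to
female population x prevalence share — `pop * prev` for the HIV-positive
stratum, `pop * (1 - prev)` for the negative — normalized within each
aggregate-year. Aggregation is a draw-wise convex combination, so
uncertainty propagates exactly and nested aggregation commutes with
composed weights. Age-specific prevalence is used throughout; weights
stay on the model's 5-year bands with no sub-band interpolation.

Countries without surveys are imputed by sampling fresh country effects
from the fitted hierarchy per posterior draw
(`u* ~ N(0, sigma_country_d^2)` etc.), which centers the imputation on
the regional average while widening intervals by the between-country
heterogeneity — imputed intervals are checked to be wider than observed
countries' in at least 95% of cases.

## 4. Re-screening and the life table

Surveys do not ask how many times a woman has been screened, so screening
frequency is reconstructed in three steps.

**Rate ratio.** The increase in lifetime coverage between successive
single-year ages reflects first screens only; the fraction reporting a
past-year screen reflects first screens plus re-screens. A hierarchical
binomial model relates the two: per survey, lifetime coverage follows
`L(a) = 1 - (1 - L0) e^{-r1 (a - a0)}` with a survey-level log-normal
first-screening hazard `r1`; past-year counts of women aged `a` are
binomial with success probability
`(1 - L(a-1))(1 - e^{-r1}) + L(a-1)(1 - e^{-RR r1})` (the window
`(a-1, a]` is entered never- or ever-screened). `RR` is shared within two
region groups — Western/Central/Eastern pooled, and Southern Africa.
Analyses are restricted to ages 18-29, where cohort and period effects
bias the cross-sectional comparison least. A crude moment estimator
(`RR_hat = log(1 - q_re)/log(1 - q_1)`) is computed per successive-age
pair for diagnostics only. Priors: log RR ~ N(0, 2^2), log r1 intercept
~ N(-3, 2^2), survey SD half-N(0, 1), logit L0 ~ N(-2, 2^2).

**Rates from coverage.** Past-3-year coverage `S3` from the trend model is
inverted into a first-screening hazard by solving
`S3 = S0 (1 - e^{-3 r1}) + (1 - S0)(1 - e^{-3 RR r1})` (monotone Brent
root find; `r2 = RR r1`). The operationalization: among women
never screened at the window start any screen is a first screen; among
the ever-screened, screening occurs at the re-screening rate. `S3` at the
supremum is clamped with a flag.

**Life table.** A cohort aged 30 in 2005 is pushed through annual cycles
to age 45 in 2020 across never / once / twice+ states: never -> once with
probability `1 - e^{-r1}`, once -> twice+ with `1 - e^{-r2}`, at most one
state advance per cycle. The cycle for age `a` uses coverage draws at
(band containing `a`, year `2005 + a - 30`). Initialization is
configurable: `model` starts at the trend model's lifetime coverage with
the ever-screened mass placed in the once state — the conservative choice
for the screened-twice endpoint, since women screened before 30 exist —
while `naive` starts everyone unscreened. Reported endpoints are
`S2(45)` and `S2(45)/(1 - S0(45))` with percentile credible intervals
across draws.

The life table is validated two ways. Against a microsimulation:
individual histories with exponential first-screen and re-screen gaps,
reduced to life-table states by a one-advance-per-cycle walk over integer
years (by memorylessness this discretized process is *exactly* the
life-table Markov chain, so occupancies must agree to Monte-Carlo error —
and do, at n = 100000). Against the trend model: on a coherent stationary
hazard world, pushing the cohort through past-3-year inversions
reproduces lifetime coverage at 45 to within about 0.015, well inside the
0.05 consistency band. On the default synthetic world the same check
lands near 0.05, because that world generates recall periods through a
constant logit offset rather than an explicit hazard process — a
phenomenological choice that mirrors how the trend model itself treats
recall, but one that is only approximately consistent with any single
(r1, RR) pair.

## 5. Treatment coverage meta-analysis

Country-level counts of women treated among those reporting an abnormal,
non-cancer screening result are pooled with a logistic random-effects
model `k_c ~ Binomial(n_c, expit(mu + u_c))`, `u_c ~ N(0, sigma^2)`,
priors `mu ~ N(0, 2.5^2)`, `sigma ~ half-N(0, 1)`. The pooled summary is
`expit(mu)` — the typical-country proportion, the standard random-effects
summary — with the population-average alternative
`E[expit(mu + u)]` (Gauss-Hermite) behind a flag. Per-country estimates
shrink between their raw proportion and the pooled mean. The bundled
demonstration inputs use the published per-country proportions with
*synthetic* denominators, since real per-country denominators are not
public; they are labeled as such wherever they appear.

## 6. The synthetic world

The generator instantiates the trend model as a simulator: nested
region/country intercepts, slopes and HIV deviations drawn from zero-mean
normals with configured SDs, a non-positive recall offset, and survey
tabulations drawn binomially at the implied probabilities (with a
survey-level intercept drawn per survey, and nominal sample sizes
deflated by a design effect). Serostatus-unreported surveys emit mixed
strata from the exact prevalence-weighted mixture, matching the model's
marginalization assumption so that recovery tests are well-posed.
Individual screening histories use exponential first-screen and re-screen
gaps from a sexual-debut age floor of 15, with an optional log-linear
period trend in the first-screening hazard so cohort/period-bias
scenarios can be expressed.

Default scale (chosen once for desk-scale MCMC): 3 regions x 2 countries
each x 2 surveys per country (an early DHS-style survey without
serostatus, a later PHIA-style survey with serostatus-split strata), 5
age bands, both recall periods, effective stratum sizes 500-2000 — 180
strata in all. True parameter values: `beta0 = logit(0.12)`,
`beta_year = 0.5`/decade, `beta_recall = -0.7`, `gamma = ln 2`, age
effects rising to 0.55, SDs 0.15-0.30, prevalences and populations
loosely patterned on the six countries. Rate ratios default to 30
(Western/Central/Eastern) and 20 (Southern) with a first-screening hazard
of 0.02/year.

What the generator does *not* emulate — and hence what passing tests do
not certify about real data: survey nonresponse and weighting error,
demographic change (fertility, migration, mortality), HIV incidence
dynamics, reporting/recall bias beyond the constant offset, and
country-level covariate effects. Recovery tests show the estimation
machinery is correct and calibrated under the stated model, not that the
model captures every feature of real screening surveys.

## 7. Numerical choices and limitations

- Root finding for the S3 inversion: Brent on a bracketing interval grown
  geometrically, converged in S3 to ~1e-14; round-trips recover rates to
  1e-8 across the admissible grid.
- Aggregation weights must normalize to 1e-12; life-table occupancies
  conserve mass to 1e-12 and are monotone by construction.
- Prevalence lookups round decimal survey years to the nearest tabulated
  year.
- Posterior CSVs persist draws at 10 significant digits; strata CSVs at
  full double precision (17 digits) for bit-faithful round trips.
- Posterior-predictive calibration is judged on the fraction of strata
  inside central 95% predictive intervals pooled across replicate fits;
  with 180 strata a single replicate can reach 100% by discreteness.
- The crude rate-ratio moment estimator is a diagnostic; records with
  negative lifetime increments or past-year counts below the increment
  are flagged out of it but retained for the Bayesian fit, which
  tolerates that noise.
- Known limitations: no survey-weighted pseudo-likelihood (effective
  counts are taken as exact binomials); no mortality or HIV-differential
  attrition in the cohort; at most three screening states; treatment
  analysis has no modality breakdown.
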