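# ccscreen

Cervical-cancer screening coverage estimation for sub-Saharan Africa from
stratified survey tabulations.

Cervical cancer elimination targets call for 70% of women to be screened
twice by age 45 and 90% of pre-cancers treated, yet in most of sub-Saharan
Africa the only data on screening are self-reports scattered across
household surveys (DHS, PHIA, STEPS, ...) with different recall periods,
age ranges, and — usually — no HIV serostatus, even though women living
with HIV are a priority group. `ccscreen` is a reusable implementation of
an estimation stack for exactly this situation, aimed at epidemiologists
and modelers who need coverage trends with honest uncertainty from sparse,
heterogeneous survey tabulations:

- **Trend model** — a four-level Bayesian multilevel binomial logistic
  regression (survey ⊂ country ⊂ region ⊂ overall) modeling lifetime and
  past-3-year screening jointly:

  `logit p = β₀ + u_r + u_c + u_v + α_age + (β_year + v_r + v_c)·(t−2010)/10
  + β_recall·1[past3y] + (γ + g_r + g_c)·1[HIV+]`

  Strata that do not report serostatus enter through the exact mixture
  `p = π·p_pos + (1−π)·p_neg` with π the UNAIDS-style HIV prevalence, so
  surveys with and without serostatus jointly identify the HIV
  odds ratio exp(γ + g_r + g_c).
- **Post-stratification** — population × prevalence weights pool stratum
  draws into country/region/SSA aggregates; countries without surveys are
  imputed by sampling fresh country effects from the fitted hierarchy.
- **Re-screening life table** — a rate ratio RR = r_re/r₁ between
  re-screening and first-screening hazards is identified from
  cross-sectional single-year-age increments in lifetime coverage versus
  past-year screening (ages 18–29); past-3-year coverage is inverted into
  rates via `S3 = S0(1−e^{−3r₁}) + (1−S0)(1−e^{−3·RR·r₁})`, and a cohort
  aged 30 in 2005 is pushed through a never/once/twice+ life table to age
  45 in 2020.
- **Treatment meta-analysis** — a logistic random-effects pooling of
  country-level pre-cancer treatment counts.

Survey microdata of this kind are access-restricted, so the package also
ships a first-class synthetic-data generator (`ccscreen.synthetic`) that
emulates every input with known ground truth; the test suite demonstrates
parameter recovery, posterior-predictive calibration, and agreement with
closed forms and microsimulation oracles.

## Worked example

```python
import numpy as np
import ccscreen as cc
from ccscreen.trend_model import (TrendMcmcConfig, fit_trend_model,
                                  hiv_odds_ratio, make_grid,
                                  predict_coverage)
from ccscreen.poststrat import aggregate_draws, build_weights

config = cc.default_world_config()          # 3 regions x 2 countries x 2 surveys
world = cc.make_world(config, seed=11)
obs = cc.simulate_surveys(world, cc.default_survey_designs(config), seed=12)
aux = cc.simulate_aux_tables(world)

post = fit_trend_model(obs, aux, TrendMcmcConfig(seed=13))
print(f"beta_year: {np.median(post.params['beta_year']):.3f} "
      f"(true {config.beta_year})")
print(f"HIV odds ratio: {hiv_odds_ratio(post)['median']:.2f} "
      f"(true {np.exp(config.gamma):.1f})")
print(f"max split R-hat: {post.max_rhat:.4f}")

bands = ["30-34", "35-39", "40-44", "45-49"]
cov = predict_coverage(post, make_grid(post.countries, [2020.0], bands))
w = build_weights(aux, "SSA 30-49", post.countries, [2020.0], bands)
summary, _ = aggregate_draws(cov, w, recall="lifetime")
print(summary.round(3).to_string(index=False))
```

Output (about a minute of sampling):

```
beta_year: 0.410 (true 0.5)
HIV odds ratio: 1.87 (true 2.0)
max split R-hat: 1.0011
aggregate   year  median  lo95  hi95
SSA 30-49 2020.0   0.303 0.229  0.39
```

The posterior median year slope of 0.410 logit per decade carries the true
0.5 inside its credible interval; the adjusted HIV odds ratio recovers the
simulated doubling of screening odds; and the post-stratified aggregate —
30.3% of women 30–49 ever screened in 2020 in this synthetic world — comes
with a draw-wise credible interval (the generator's true aggregate is
33.2%, inside it).

The same pipeline runs from the shell, stage by stage with manifest-tracked
CSV artifacts:

```bash
ccscreen all --config cfg.yaml --seed 7 --out runs/demo
ccscreen validate --config cfg.yaml --out runs/demo
```

Stages: `simulate`, `fit-trends`, `poststratify`, `lifetable`,
`treatment-meta`, `validate` (exit codes: 0 ok, 2 validation failure,
3 convergence failure).

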