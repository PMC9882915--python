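import numpy as np
import pytest

import ccscreen as cc
from ccscreen.trend_model import TrendMcmcConfig, TrendPosterior, fit_trend_model


@pytest.fixture(scope="session")
def default_world():
    cfg = cc.default_world_config()
    world = cc.make_world(cfg, seed=11)
    return cfg, world


@pytest.fixture(scope="session")
def small_fit():
    """A reduced trend-model fit shared by unit tests: one region, two
    countries, two surveys each, short chains."""
    cfg = cc.WorldConfig(
        regions={"Eastern Africa": ["KEN", "TZA"]},
        prevalence={"KEN": 0.07, "TZA": 0.06},
        population={"KEN": 1.6e6, "TZA": 1.8e6},
    )
    world = cc.make_world(cfg, seed=5)
    designs = cc.default_survey_designs(cfg)
    obs = cc.simulate_surveys(world, designs, seed=6)
    aux = cc.simulate_aux_tables(world)
    post = fit_trend_model(
        obs, aux, TrendMcmcConfig(seed=7, n_chains=2, n_warmup=500,
                                  n_draws=800))
    return cfg, world, obs, aux, post


@pytest.fixture
def hand_posterior():
    """Hand-built posterior draws with known structure (no MCMC)."""
    D = 4000
    rng = np.random.default_rng(0)
    params = {
        "beta0": rng.normal(-2.0, 0.1, D),
        "beta_year": rng.normal(0.5, 0.1, D),
        "alpha": rng.normal(0.0, 0.05, (D, 4)),
        "beta_recall": -np.abs(rng.normal(0.7, 0.05, D)),
        "gamma": rng.normal(np.log(2), 0.1, D),
        "u_survey": np.zeros((D, 1)),
        "u_country": rng.normal(0, 0.1, (D, 2)),
        "v_country": rng.normal(0, 0.05, (D, 2)),
        "g_country": rng.normal(0, 0.05, (D, 2)),
        "u_region": rng.normal(0, 0.1, (D, 1)),
        "v_region": rng.normal(0, 0.05, (D, 1)),
        "g_region": rng.normal(0, 0.05, (D, 1)),
        "sigma_survey": np.full(D, 0.1),
        "sigma_country": np.full(D, 0.5),
        "sigma_region": np.full(D, 0.1),
        "tau_country": np.full(D, 0.1),
        "tau_region": np.full(D, 0.1),
        "omega_country": np.full(D, 0.1),
        "omega_region": np.full(D, 0.1),
    }
    return TrendPosterior(
        surveys=["s1"], countries=["KEN", "TZA"],
        regions=["Eastern Africa"], country_region_idx=np.array([0, 0]),
        params=params, rhat={"all": 1.0}, ess_bulk={"all": 4000.0},
        converged=True)
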