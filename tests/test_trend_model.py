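import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ccscreen as cc
from ccscreen.synthetic import expit, logit
from ccscreen.trend_model import (
    TrendMcmcConfig, TrendPosterior, fit_trend_model, hiv_odds_ratio,
    make_grid, posterior_predictive_check, predict_coverage,
    stratum_probability,
)


class TestStratumProbability:
    def test_mixture_collapses_without_hiv_effect(self):
        params = {"beta0": logit(0.3)}
        cov = {"year": 2010.0, "age_group": "25-29", "recall": "lifetime",
               "hiv": "all"}
        p_all = stratum_probability(params, cov, prevalence=0.4)
        assert p_all == pytest.approx(0.3)

    def test_full_prevalence_equals_positive_stratum(self):
        params = {"beta0": logit(0.2), "gamma": 0.5}
        base = {"year": 2010.0, "age_group": "25-29", "recall": "lifetime"}
        p_all = stratum_probability(params, {**base, "hiv": "all"},
                                    prevalence=1.0)
        p_pos = stratum_probability(params, {**base, "hiv": "pos"})
        assert p_all == pytest.approx(p_pos, abs=1e-15)

    def test_worked_mixture_value(self):
        # p_neg = 0.1, OR = 2 -> p_pos = 2/11; pi = 0.2
        params = {"beta0": logit(0.1), "gamma": np.log(2)}
        cov = {"year": 2010.0, "age_group": "25-29", "recall": "lifetime",
               "hiv": "all"}
        p = stratum_probability(params, cov, prevalence=0.2)
        assert p == pytest.approx(0.2 * 2 / 11 + 0.8 * 0.1, abs=1e-12)

    def test_missing_prevalence_raises(self):
        with pytest.raises(ValueError, match="prevalence"):
            stratum_probability({"beta0": 0.0},
                                {"year": 2010.0, "age_group": "25-29",
                                 "recall": "lifetime", "hiv": "all"})

    @given(beta0=st.floats(-3, 3), gamma=st.floats(-2, 2),
           pi=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_mixture_identity(self, beta0, gamma, pi):
        params = {"beta0": beta0, "gamma": gamma}
        base = {"year": 2012.0, "age_group": "30-34", "recall": "past3y",
                "hiv": "all"}
        params["beta_recall"] = -0.4
        p_all = stratum_probability(params, base, prevalence=pi)
        p_pos = stratum_probability(params, {**base, "hiv": "pos"})
        p_neg = stratum_probability(params, {**base, "hiv": "neg"})
        assert p_all == pytest.approx(pi * p_pos + (1 - pi) * p_neg,
                                      abs=1e-12)


def _single_draw_posterior(**values):
    D = values.pop("D", 2)
    params = {
        "beta0": np.zeros(D), "beta_year": np.zeros(D),
        "alpha": np.zeros((D, 4)), "beta_recall": np.zeros(D),
        "gamma": np.zeros(D),
        "u_survey": np.zeros((D, 1)),
        "u_country": np.zeros((D, 1)), "v_country": np.zeros((D, 1)),
        "g_country": np.zeros((D, 1)),
        "u_region": np.zeros((D, 1)), "v_region": np.zeros((D, 1)),
        "g_region": np.zeros((D, 1)),
        "sigma_survey": np.full(D, 0.1), "sigma_country": np.full(D, 0.1),
        "sigma_region": np.full(D, 0.1), "tau_country": np.full(D, 0.1),
        "tau_region": np.full(D, 0.1), "omega_country": np.full(D, 0.1),
        "omega_region": np.full(D, 0.1),
    }
    for k, v in values.items():
        arr = np.asarray(v, float)
        params[k] = np.broadcast_to(arr, params[k].shape).copy()
    return TrendPosterior(
        surveys=["s1"], countries=["KEN"], regions=["Eastern Africa"],
        country_region_idx=np.array([0]), params=params, rhat={"a": 1.0},
        ess_bulk={"a": 1000.0}, converged=True)


class TestPredictCoverage:
    def test_null_parameters_give_half(self):
        post = _single_draw_posterior()
        cov = predict_coverage(post, make_grid(["KEN"], [2010.0]))
        assert np.allclose(cov.draws, 0.5)

    def test_hiv_odds_doubling(self):
        post = _single_draw_posterior(beta0=logit(0.1), gamma=np.log(2))
        grid = make_grid(["KEN"], [2010.0], ["25-29"])
        cov = predict_coverage(post, grid)
        neg = cov.draws[(grid["hiv"] == "neg").to_numpy()]
        pos = cov.draws[(grid["hiv"] == "pos").to_numpy()]
        assert np.allclose(neg, 0.1) and np.allclose(pos, 2 / 11)

    def test_recall_ordering_draw_wise(self):
        post = _single_draw_posterior(beta_recall=-0.3,
                                      beta0=np.random.default_rng(0).normal(
                                          0, 1, 2))
        grid = make_grid(["KEN"], [2005.0, 2015.0])
        cov = predict_coverage(post, grid)
        g = cov.grid
        for (c, y, a, h), sub in g.groupby(["country", "year", "age_group",
                                            "hiv"]):
            life = cov.draws[sub.index[sub["recall"] == "lifetime"][0]]
            p3 = cov.draws[sub.index[sub["recall"] == "past3y"][0]]
            assert (p3 < life).all()

    def test_unobserved_country_points_to_imputation(self):
        post = _single_draw_posterior()
        with pytest.raises(KeyError, match="impute"):
            predict_coverage(post, make_grid(["NGA"], [2010.0]))


class TestHivOddsRatio:
    def test_constant_draws_give_point_or(self):
        post = _single_draw_posterior(gamma=np.log(2))
        out = hiv_odds_ratio(post, country="KEN")
        assert out["median"] == pytest.approx(2.0)
        assert out["hi95"] - out["lo95"] == pytest.approx(0.0, abs=1e-12)

    def test_lognormal_quantiles(self):
        rng = np.random.default_rng(1)
        post = _single_draw_posterior(D=20000,
                                      gamma=rng.normal(np.log(2), 0.1, 20000))
        out = hiv_odds_ratio(post)
        assert out["median"] == pytest.approx(2.0, abs=0.02)
        assert out["lo95"] == pytest.approx(2 * np.exp(-1.96 * 0.1), abs=0.03)
        assert out["hi95"] == pytest.approx(2 * np.exp(1.96 * 0.1), abs=0.03)

    def test_degenerate_hierarchy_matches_global(self):
        rng = np.random.default_rng(2)
        post = _single_draw_posterior(D=100, gamma=rng.normal(0.7, 0.2, 100))
        country = hiv_odds_ratio(post, country="KEN")["draws"]
        overall = hiv_odds_ratio(post)["draws"]
        assert np.allclose(country, overall)


class TestFittedPosterior:
    def test_recall_offset_nonpositive_in_every_draw(self, small_fit):
        *_, post = small_fit
        assert (post.params["beta_recall"] <= 0).all()

    def test_diagnostics_reported(self, small_fit):
        *_, post = small_fit
        assert post.max_rhat < 1.2
        assert post.n_draws == 2 * 800
        assert set(post.countries) == {"KEN", "TZA"}

    def test_posterior_csv_round_trip(self, small_fit, tmp_path):
        *_, post = small_fit
        path = tmp_path / "post.csv"
        post.write_csv(path)
        back = TrendPosterior.read_csv(path)
        assert back.countries == post.countries
        assert np.allclose(back.params["beta_year"],
                           post.params["beta_year"], atol=1e-9)
        assert np.allclose(back.params["u_country"],
                           post.params["u_country"], atol=1e-9)

    def test_ppc_flags_corrupted_stratum(self, small_fit):
        _, _, obs, aux, post = small_fit
        target = next(o for o in obs if o.hiv == "neg" and o.n_eff > 500)
        corrupted = [o for o in obs if o is not target]
        bad = cc.StratumObservation(
            target.survey_id, target.country, target.survey_type,
            target.year, target.age_group, target.recall, target.hiv,
            k_eff=target.n_eff, n_eff=target.n_eff)
        report = posterior_predictive_check(post, corrupted + [bad], aux,
                                            seed=0)
        row = report.iloc[-1]
        assert not row["inside"]
        assert row["std_residual"] > 3

    def test_ppc_accepts_predictive_medians(self, small_fit):
        _, _, obs, aux, post = small_fit
        base = posterior_predictive_check(post, obs, aux, seed=1)
        centered = []
        for o, (_, row) in zip(obs, base.iterrows()):
            mid = 0.5 * (row["pred_lo95"] + row["pred_hi95"])
            centered.append(cc.StratumObservation(
                o.survey_id, o.country, o.survey_type, o.year, o.age_group,
                o.recall, o.hiv, k_eff=float(round(mid)), n_eff=float(row["n"])))
        report = posterior_predictive_check(post, centered, aux, seed=1)
        assert report["inside"].all()

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_trend_model([], cc.AuxTables())


@pytest.mark.parametrize("seed", [0])
def test_unidentified_hiv_slope_recovers_prior(seed):
    """With no serostatus information anywhere and zero prevalence, the HIV
    log-OR posterior should coincide with its Normal(0, 2.5^2) prior."""
    cfg = cc.WorldConfig(
        regions={"Eastern Africa": ["KEN", "TZA"]},
        prevalence={"KEN": 0.0, "TZA": 0.0},
        omega_country=0.0, omega_region=0.0,
    )
    world = cc.make_world(cfg, seed)
    designs = [cc.SurveyDesign(f"{c}-D-{y}", c, y, serostatus_reported=False)
               for c in cfg.countries for y in (2008.0, 2016.0)]
    obs = cc.simulate_surveys(world, designs, seed + 1)
    aux = cc.simulate_aux_tables(world)
    post = fit_trend_model(obs, aux, TrendMcmcConfig(
        seed=seed + 2, n_chains=4, n_warmup=500, n_draws=1000))
    draws = post.params["gamma"]
    ks = stats.kstest(draws, stats.norm(0, 2.5).cdf)
    assert ks.statistic < 0.1
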