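import numpy as np
import pytest
from scipy import stats

import ccscreen as cc
from ccscreen.io_core import AGE_BANDS
from ccscreen.synthetic import (
    SurveyDesign, WorldConfig, cross_section_strata, expit, logit,
)


def _flat_config(**over):
    base = dict(
        regions={"Eastern Africa": ["KEN", "TZA"],
                 "Southern Africa": ["ZAF", "NAM"]},
        sigma_survey=0.0, sigma_country=0.0, sigma_region=0.0,
        tau_country=0.0, tau_region=0.0, omega_country=0.0,
        omega_region=0.0,
    )
    base.update(over)
    return WorldConfig(**base)


class TestWorld:
    def test_reproducible(self):
        cfg = cc.default_world_config()
        w1, w2 = cc.make_world(cfg, 3), cc.make_world(cfg, 3)
        assert w1.u_country == w2.u_country
        assert w1.v_region == w2.v_region

    def test_degenerate_hierarchy_shares_surface(self):
        w = cc.make_world(_flat_config(), 1)
        p1 = cc.true_coverage(w, "KEN", 2015.0, "30-34")
        p2 = cc.true_coverage(w, "TZA", 2015.0, "30-34")
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_year_slope_is_half_logit_per_decade(self):
        w = cc.make_world(_flat_config(beta_year=0.5), 1)
        l10 = logit(cc.true_coverage(w, "KEN", 2010.0, "30-34"))
        l20 = logit(cc.true_coverage(w, "KEN", 2020.0, "30-34"))
        assert l20 - l10 == pytest.approx(0.5, abs=1e-12)

    def test_null_world_gives_half(self):
        cfg = _flat_config(beta0=0.0, beta_year=0.0, beta_recall=0.0,
                           gamma=0.0,
                           alpha={a: 0.0 for a in AGE_BANDS})
        w = cc.make_world(cfg, 1)
        assert cc.true_coverage(w, "KEN", 2013.0, "35-39") == pytest.approx(0.5)

    def test_hiv_effect_doubles_odds(self):
        cfg = _flat_config(beta0=float(logit(0.1)), gamma=float(np.log(2)),
                           alpha={a: 0.0 for a in AGE_BANDS})
        w = cc.make_world(cfg, 1)
        assert cc.true_coverage(w, "KEN", 2010.0, "25-29", hiv="neg") == \
            pytest.approx(0.1)
        assert cc.true_coverage(w, "KEN", 2010.0, "25-29", hiv="pos") == \
            pytest.approx(2 / 11)

    def test_recall_offset_orders_coverage_everywhere(self):
        cfg = cc.default_world_config()
        w = cc.make_world(cfg, 2)
        for c in w.countries:
            for year in (2000.0, 2010.0, 2020.0):
                for a in AGE_BANDS:
                    assert cc.true_coverage(w, c, year, a, recall="past3y") < \
                        cc.true_coverage(w, c, year, a, recall="lifetime")

    def test_off_grid_lookup_raises(self):
        w = cc.make_world(_flat_config(), 1)
        with pytest.raises(KeyError):
            cc.true_coverage(w, "NGA", 2010.0, "30-34")
        with pytest.raises(KeyError):
            cc.true_coverage(w, "KEN", 2010.0, "17-21")

    def test_positive_recall_offset_rejected(self):
        with pytest.raises(ValueError, match="beta_recall"):
            _flat_config(beta_recall=0.2)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = cc.default_world_config()
        path = tmp_path / "world.yaml"
        cfg.to_yaml(path)
        back = WorldConfig.from_yaml(path)
        assert back == cfg


class TestSimulateSurveys:
    def test_reproducible(self, default_world):
        cfg, world = default_world
        designs = cc.default_survey_designs(cfg)
        a = cc.simulate_surveys(world, designs, 9)
        b = cc.simulate_surveys(world, designs, 9)
        assert a == b

    def test_unknown_country_in_design(self, default_world):
        _, world = default_world
        with pytest.raises(KeyError, match="NGA"):
            cc.simulate_surveys(world, [SurveyDesign("x", "NGA", 2010.0)], 1)

    def test_large_n_concentrates_on_truth(self):
        cfg = _flat_config()
        world = cc.make_world(cfg, 1)
        designs = [SurveyDesign(f"{c}-S-{y}", c, y, "PHIA",
                                serostatus_reported=True,
                                n_nominal=(100000, 100000))
                   for c in cfg.countries for y in (2006.0, 2012.0)]
        obs = cc.simulate_surveys(world, designs, 2)
        inside = 0
        for o in obs:
            p = cc.true_coverage(world, o.country, o.year, o.age_group,
                                 o.hiv, o.recall)
            se = np.sqrt(p * (1 - p) / o.n_eff)
            inside += abs(o.p_hat - p) <= 3 * se
        assert inside / len(obs) >= 0.99

    def test_mixture_collapses_without_hiv_effect(self):
        cfg = _flat_config(gamma=0.0)
        world = cc.make_world(cfg, 1)
        for c in cfg.countries:
            p_all = cc.true_coverage(world, c, 2010.0, "30-34", hiv="all")
            p_neg = cc.true_coverage(world, c, 2010.0, "30-34", hiv="neg")
            assert p_all == pytest.approx(p_neg, abs=1e-15)

    def test_design_effect_deflates_denominator(self):
        cfg = _flat_config()
        world = cc.make_world(cfg, 1)
        d = SurveyDesign("KEN-S", "KEN", 2012.0, n_nominal=(1000, 1000),
                         design_effect=2.0)
        obs = cc.simulate_surveys(world, [d], 3)
        assert all(o.n_eff == 500 for o in obs)


class TestHistories:
    def test_zero_hazard_means_no_events(self):
        h = cc.simulate_histories(0.0, 5.0, n=100, horizon=20.0, seed=1)
        assert h.times.size == 0
        occ = h.occupancy(10)
        assert np.allclose(occ[:, 0], 1.0)

    def test_rr_one_makes_gaps_exchangeable(self):
        # among women with >= 2 events, (first gap, second gap) is an
        # exchangeable pair when RR = 1, so their marginals must agree
        h = cc.simulate_histories(0.3, 1.0, n=10000, horizon=30.0, seed=2)
        first, second = [], []
        for i in range(h.n_women):
            ev = h.events(i)
            if ev.size >= 2:
                first.append(ev[0])
                second.append(ev[1] - ev[0])
        stat = stats.ks_2samp(first, second)
        assert stat.pvalue > 0.01

    def test_ever_screened_matches_exponential_cdf(self):
        n = 100000
        h = cc.simulate_histories(0.05, 10.0, n=n, horizon=15.0, seed=3)
        frac = (h.n_events_by(15.0) > 0).mean()
        expect = 1.0 - np.exp(-0.75)
        mc_se = np.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) <= 3 * mc_se

    def test_event_times_strictly_increasing(self):
        h = cc.simulate_histories(0.2, 5.0, n=500, horizon=25.0, seed=4)
        for i in range(h.n_women):
            ev = h.events(i)
            assert (np.diff(ev) > 0).all()
            assert (h.event_ages(i) >= h.debut_age).all()

    def test_cross_section_counts_are_consistent(self):
        strata = cross_section_strata(0.05, 5.0, ages=[20, 25], n_per_age=500,
                                      seed=5, survey_id="S", country="KEN",
                                      year=2018.0)
        by = {(o.age_group, o.recall): o for o in strata}
        assert set(by) == {("20", "lifetime"), ("20", "past1y"),
                           ("25", "lifetime"), ("25", "past1y")}
        for a in ("20", "25"):
            assert by[(a, "past1y")].k_eff <= by[(a, "lifetime")].k_eff


class TestAuxAndTreatment:
    def test_aux_covers_grid(self, default_world):
        cfg, world = default_world
        aux = cc.simulate_aux_tables(world)
        for c in cfg.countries:
            for y in range(2000, 2021):
                for a in AGE_BANDS:
                    assert aux.pop_f(c, y, a) > 0
                    assert 0 <= aux.prev(c, y, a) <= 1

    def test_flat_zero_prevalence_collapses_mixture(self):
        cfg = _flat_config(prevalence={c: 0.0 for c in
                                       ("KEN", "TZA", "ZAF", "NAM")})
        world = cc.make_world(cfg, 1)
        assert cc.true_coverage(world, "KEN", 2010.0, "30-34", "all") == \
            pytest.approx(cc.true_coverage(world, "KEN", 2010.0, "30-34",
                                           "neg"))

    def test_certain_treatment_gives_full_counts(self):
        obs = cc.simulate_treatment({"MWI": 1.0, "ZMB": 1.0},
                                    {"MWI": 40, "ZMB": 25}, seed=1)
        assert all(o.k_treated == o.n_abnormal for o in obs)

    def test_treatment_counts_concentrate(self):
        obs = cc.simulate_treatment({"MWI": 0.8}, {"MWI": 10000}, seed=2)[0]
        se = np.sqrt(0.8 * 0.2 / 10000)
        assert abs(obs.k_treated / obs.n_abnormal - 0.8) <= 3 * se
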