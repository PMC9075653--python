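import numpy as np
import pytest

import pesim
from pesim.config import ScenarioConfig
from pesim.youth import (afterschool_decision, afterschool_probability,
                         build_calendar, daily_expenditure, pe_active_minutes,
                         pe_days, run_youth_simulation)


class TestCalendar:
    def test_five_years_is_1825_days(self):
        assert len(build_calendar(5)) == 1825

    def test_school_days_per_year(self):
        cal = build_calendar(1)
        assert cal["is_school_day"].sum() == 200

    def test_two_sessions_every_school_week(self):
        cal = build_calendar(1)
        mask = pe_days(cal, 2)
        per_week = cal[mask].groupby("week_of_year").size()
        assert (per_week == 2).all() and len(per_week) == 40

    def test_too_many_sessions_rejected(self):
        with pytest.raises(ValueError, match="5-day school week"):
            pe_days(build_calendar(1), 6)

    def test_zero_years_rejected(self):
        with pytest.raises(ValueError):
            build_calendar(0)


class TestPEMinutes:
    @pytest.mark.parametrize("male,primary,scen_kw,expected", [
        # observed practice, primary male: 40 min x 32% = 12.8
        (True, True, dict(primary_session_minutes=40, fraction_active_male=0.32,
                          fraction_active_female=0.26), 12.8),
        # guideline secondary female: 60 min x 50% = 30
        (False, False, dict(secondary_session_minutes=60, fraction_active_male=0.5,
                            fraction_active_female=0.5), 30.0),
    ])
    def test_session_fraction_arithmetic(self, male, primary, scen_kw, expected):
        sc = ScenarioConfig(name="x", pe_offered=True, **scen_kw)
        assert pe_active_minutes(male, primary, sc, True) == pytest.approx(expected)

    def test_zero_when_pe_not_offered(self):
        sc = ScenarioConfig(name="none", pe_offered=False)
        assert pe_active_minutes(True, True, sc, True) == 0.0

    def test_zero_when_no_session_that_day(self):
        sc = ScenarioConfig(name="x", pe_offered=True, primary_session_minutes=40,
                            fraction_active_male=0.5, fraction_active_female=0.5)
        assert pe_active_minutes(True, True, sc, False) == 0.0


class TestAfterschool:
    def test_forced_probabilities(self, cfg, rng):
        sc = cfg.scenarios["no_pe"]
        beh = cfg.behavior
        go, minutes = afterschool_decision(np.zeros(200), False, sc, rng, beh)
        assert not go.any() and (minutes == 0).all()
        go, minutes = afterschool_decision(np.ones(200), False, sc, rng, beh)
        assert go.all() and (minutes == 100.0).all()

    def test_participation_fraction_matches_probability(self, cfg, rng):
        sc = cfg.scenarios["no_pe"]
        go, _ = afterschool_decision(np.full(10_000, 0.3), False, sc, rng,
                                     cfg.behavior)
        assert go.mean() == pytest.approx(0.3, abs=0.015)

    def test_spillover_uplift_raises_probability(self, cfg):
        sc = cfg.scenarios["pe_guidelines_spillover"]
        rng_a = np.random.default_rng(0)
        rng_b = np.random.default_rng(0)
        up, _ = afterschool_decision(np.full(20_000, 0.2), True, sc, rng_a,
                                     cfg.behavior)
        no, _ = afterschool_decision(np.full(20_000, 0.2), False, sc, rng_b,
                                     cfg.behavior)
        assert up.mean() > no.mean()

    def test_probability_is_logistic_in_factors(self, cfg):
        p = afterschool_probability(0.5, 0.5, 0.5, cfg.behavior)
        b = cfg.behavior
        logit = (b.beta_intercept + 0.5 * (b.beta_propensity + b.beta_proximity
                                           + b.beta_ses))
        assert p == pytest.approx(1 / (1 + np.exp(-logit)))


class TestDailyExpenditure:
    def test_no_activity_no_increment(self, cfg):
        assert daily_expenditure(50.0, [], cfg.metabolism) == 0.0

    @pytest.mark.parametrize("minutes,mets,weight,expected", [
        (60.0, 6.0, 50.0, 250.0),          # (6-1) x 50 x 1 h
        (100.0, 6.0, 50.0, 416.6667),      # the 100-min after-school event
    ])
    def test_incremental_met_convention(self, cfg, minutes, mets, weight, expected):
        out = daily_expenditure(weight, [(minutes, mets)], cfg.metabolism)
        assert out == pytest.approx(expected, rel=1e-4)

    def test_gross_met_mode(self, cfg):
        cfg.metabolism.use_gross_mets = True
        assert daily_expenditure(50.0, [(60.0, 6.0)], cfg.metabolism) == 300.0

    def test_negative_minutes_rejected(self, cfg):
        with pytest.raises(ValueError):
            daily_expenditure(50.0, [(-5.0, 6.0)], cfg.metabolism)


class TestSimulation:
    def test_null_policy_bit_equality(self, small_pop):
        """PE offered with zero active fraction == no PE, bit-exactly."""
        cfg, pop = small_pop
        null = ScenarioConfig(name="null", pe_offered=True,
                              primary_sessions_per_week=1, primary_session_minutes=40,
                              secondary_sessions_per_week=2, secondary_session_minutes=40,
                              fraction_active_male=0.0, fraction_active_female=0.0)
        a = run_youth_simulation(pop, cfg.scenarios["no_pe"], cfg, seed=5, years=2)
        b = run_youth_simulation(pop, null, cfg, seed=5, years=2)
        assert np.array_equal(a.final["weight_kg"], b.final["weight_kg"])
        assert a.yearly.equals(b.yearly)

    def test_energy_ledger_closes(self, small_pop):
        cfg, pop = small_pop
        r = run_youth_simulation(pop, cfg.scenarios["pe_observed"], cfg, seed=5,
                                 years=2)
        # cumulative stored energy equals cumulative balance, per agent
        np.testing.assert_allclose(r.stored_energy_kcal, r.cum_energy_kcal,
                                   atol=2e-3 * 730)

    def test_seeded_rerun_identical(self, small_pop):
        cfg, pop = small_pop
        a = run_youth_simulation(pop, cfg.scenarios["pe_guidelines"], cfg, seed=8,
                                 years=1)
        b = run_youth_simulation(pop, cfg.scenarios["pe_guidelines"], cfg, seed=8,
                                 years=1)
        assert np.array_equal(a.final["weight_kg"], b.final["weight_kg"])

    def test_weight_never_nonpositive(self, small_pop):
        cfg, pop = small_pop
        r = run_youth_simulation(pop, cfg.scenarios["pe_guidelines"], cfg, seed=9,
                                 years=2)
        assert (r.final["weight_kg"] > 0).all()

    def test_prevalence_monotone_in_active_fraction(self, cfg):
        """Over >=10 paired replicates, mean prevalence is non-increasing in
        the active fraction of class time."""
        cfg.population.n_agents = 800
        cfg.years = 2
        means = []
        for frac in (0.0, 0.5):
            sc = ScenarioConfig(
                name=f"f{frac}", pe_offered=True,
                primary_sessions_per_week=3, primary_session_minutes=40,
                secondary_sessions_per_week=3, secondary_session_minutes=60,
                fraction_active_male=frac, fraction_active_female=frac)
            prevs = []
            for s in range(10):
                pop = pesim.generate_population(cfg, 50 + s)
                prevs.append(run_youth_simulation(pop, sc, cfg, seed=200 + s)
                             .final_prevalence)
            means.append(np.mean(prevs))
        assert means[1] < means[0]

    def test_more_sessions_lower_mean_prevalence(self, cfg):
        cfg.population.n_agents = 800
        cfg.years = 2
        means = []
        for sessions in (1, 5):
            sc = ScenarioConfig(
                name=f"s{sessions}", pe_offered=True,
                primary_sessions_per_week=sessions, primary_session_minutes=40,
                secondary_sessions_per_week=sessions, secondary_session_minutes=60,
                fraction_active_male=0.5, fraction_active_female=0.5)
            prevs = []
            for s in range(10):
                pop = pesim.generate_population(cfg, 80 + s)
                prevs.append(run_youth_simulation(pop, sc, cfg, seed=300 + s)
                             .final_prevalence)
            means.append(np.mean(prevs))
        assert means[1] < means[0]
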