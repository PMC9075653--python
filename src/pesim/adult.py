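"""Adult life-course: a 15-state annual-cycle Markov model with
obesity-related outcome incidence, mortality, and probabilistic
sensitivity analysis.

The 15 mutually exclusive states are the cross of BMI category
{normal, overweight, obese} x condition axis {healthy, diabetes,
post-CHD, post-stroke, cancer-survivor}, plus an absorbing death state.
This composition is a structural assumption (the state map is fully
table-driven, so a different enumeration is a data change). All
transition/incidence/mortality tables ship as editable CSV fixtures with
documented plausible defaults — no parity with any specific published
parameter set is claimed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import econ
from .config import AdultConfig, EconConfig
from .reference import _data_path, load_life_table

BMI_CATS = ["normal", "overweight", "obese"]
CONDITION_AXES = ["healthy", "diabetes", "post_chd", "post_stroke", "cancer_survivor"]
STATES = [(b, a) for b in BMI_CATS for a in CONDITION_AXES]          # 15 states
DEATH_STATE = "dead"

CANCERS = ["breast_cancer", "cervical_cancer", "uterine_cancer", "prostate_cancer",
           "colorectal_cancer", "esophageal_cancer", "kidney_cancer",
           "pancreatic_cancer", "stomach_cancer"]
FEMALE_ONLY = {"breast_cancer", "cervical_cancer", "uterine_cancer"}
MALE_ONLY = {"prostate_cancer"}
#: condition -> axis it maps the person onto (priority: chd > stroke > cancer > diabetes)
AXIS_OF = {"chd": "post_chd", "stroke": "post_stroke", "type2_diabetes": "diabetes",
           **{c: "cancer_survivor" for c in CANCERS}}
AXIS_PRIORITY = {"post_chd": 3, "post_stroke": 2, "cancer_survivor": 1,
                 "diabetes": 0, "healthy": -1}
_AXIS_PRIO = np.array([AXIS_PRIORITY[a] for a in CONDITION_AXES])


def adult_bmi_category(bmi) -> np.ndarray:
    """Adult cutoffs: overweight 25, obese 30 kg/m^2."""
    bmi = np.asarray(bmi, float)
    return np.select([bmi >= 30.0, bmi >= 25.0], [2, 1], default=0)


@dataclass
class TransitionModel:
    bands: list[str]
    band_lo: np.ndarray                       # lower age bound per band
    bmi_trans: np.ndarray                     # [sex(0=f,1=m), band, from, to]
    incidence: dict                           # cond -> [sex, band, bmi_cat]
    background_mort: np.ndarray               # [sex, band]
    case_fatality: dict                       # cond -> float
    excess_mort: dict                         # cond -> float
    costs: pd.DataFrame                       # indexed by condition

    def band_index(self, age) -> np.ndarray:
        return np.clip(np.searchsorted(self.band_lo, np.asarray(age, float),
                                       side="right") - 1, 0, len(self.bands) - 1)


def _band_bounds(bands: list[str]) -> np.ndarray:
    return np.array([float(b.split("-")[0].rstrip("+")) for b in bands])


def load_transition_model(econ_params: EconConfig | None = None,
                          table_dir: str | Path | None = None) -> TransitionModel:
    """Load the packaged (or user-supplied) adult tables.

    Condition costs are converted from US proxies to Mexican price levels,
    applying the first-year-ratio rule for cancers/ESRD subsequent years.
    """
    econ_params = econ_params or EconConfig()
    d = Path(table_dir) if table_dir else None

    def read(name):
        return pd.read_csv(d / name if d else _data_path(name))

    bt = read("synthetic_adult_bmi_transitions.csv")
    bands = list(dict.fromkeys(bt["age_band"]))
    nb = len(bands)
    bmi_trans = np.zeros((2, nb, 3, 3))
    for _, r in bt.iterrows():
        s = 1 if r["sex"] == "male" else 0
        bi = bands.index(r["age_band"])
        fi = BMI_CATS.index(r["from_bmi"])
        bmi_trans[s, bi, fi] = [r["to_normal"], r["to_overweight"], r["to_obese"]]

    inc = read("synthetic_adult_incidence.csv")
    incidence: dict[str, np.ndarray] = {}
    for cond, sub in inc.groupby("condition"):
        arr = np.zeros((2, nb, 3))
        for _, r in sub.iterrows():
            arr[1 if r["sex"] == "male" else 0,
                bands.index(r["age_band"]),
                BMI_CATS.index(r["bmi_category"])] = r["annual_probability"]
        incidence[cond] = arr

    bm = read("synthetic_adult_background_mortality.csv")
    background = np.zeros((2, nb))
    for _, r in bm.iterrows():
        background[1 if r["sex"] == "male" else 0,
                   bands.index(r["age_band"])] = r["annual_probability"]

    cm = read("synthetic_condition_mortality.csv")
    case_fatality = dict(zip(cm["condition"], cm["case_fatality_first_year"]))
    excess = dict(zip(cm["condition"], cm["annual_excess_mortality"]))

    costs = read("synthetic_condition_costs_dw.csv").set_index("condition")
    mx_first, mx_sub = [], []
    for cond, r in costs.iterrows():
        first = econ.convert_cost_us_to_mx(r["us_cost_first_year"], econ_params, "first")
        if r["first_year_ratio_rule"]:
            ratio = r["us_cost_first_year"] / r["us_cost_subsequent"]
            sub = econ.convert_cost_us_to_mx(
                r["us_cost_first_year"], econ_params, "subsequent", "cancer",
                us_first_to_subsequent_ratio=ratio)
        else:
            sub = econ.convert_cost_us_to_mx(r["us_cost_subsequent"], econ_params, "first")
        mx_first.append(first)
        mx_sub.append(sub)
    costs["mx_cost_first_year"] = mx_first
    costs["mx_cost_subsequent"] = mx_sub

    return TransitionModel(bands=bands, band_lo=_band_bounds(bands),
                           bmi_trans=bmi_trans, incidence=incidence,
                           background_mort=background, case_fatality=case_fatality,
                           excess_mort=excess, costs=costs)


# ------------------------------------------------------------------ validation
@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            raise ValueError("transition model validation failed:\n  "
                             + "\n  ".join(self.errors))


def validate_transition_model(model: TransitionModel,
                              atol: float = 1e-9) -> ValidationReport:
    """Row-stochasticity, probability-range, and coverage checks."""
    rep = ValidationReport()
    for s, sex in enumerate(("female", "male")):
        for bi, band in enumerate(model.bands):
            for fi, frm in enumerate(BMI_CATS):
                row = model.bmi_trans[s, bi, fi]
                if np.any(row < 0) or np.any(row > 1):
                    rep.errors.append(
                        f"bmi transition probability outside [0,1]: {sex}/{band}/{frm}")
                if abs(row.sum() - 1.0) > atol:
                    rep.errors.append(
                        f"bmi transition row does not sum to 1 "
                        f"({row.sum():.6f}): {sex}/{band}/{frm}")
    for cond, arr in model.incidence.items():
        if np.any(arr < 0) or np.any(arr > 1):
            rep.errors.append(f"incidence probability outside [0,1]: {cond}")
        if cond in FEMALE_ONLY and np.any(arr[1] > 0):
            rep.errors.append(f"female-only condition has male incidence: {cond}")
        if cond in MALE_ONLY and np.any(arr[0] > 0):
            rep.errors.append(f"male-only condition has female incidence: {cond}")
    if np.any(model.background_mort < 0) or np.any(model.background_mort > 1):
        rep.errors.append("background mortality outside [0,1]")
    for cond in model.incidence:
        if cond not in model.case_fatality:
            rep.errors.append(f"missing case fatality for {cond}")
        if cond not in model.costs.index:
            rep.errors.append(f"missing cost/disability row for {cond}")
    return rep


# -------------------------------------------------------------------- stepping
@dataclass
class CohortState:
    """Vectorized person-state for one trial."""

    age: np.ndarray
    male: np.ndarray
    bmi_cat: np.ndarray                    # 0/1/2
    axis: np.ndarray                       # index into CONDITION_AXES
    alive: np.ndarray
    has_condition: np.ndarray              # [n, n_conditions] bool
    onset_year: np.ndarray                 # [n, n_conditions] int (-1 = never)
    conditions: list[str]

    @classmethod
    def from_entry(cls, bmi_cat, male, conditions):
        n = len(bmi_cat)
        return cls(age=np.full(n, 18.0), male=np.asarray(male, bool),
                   bmi_cat=np.asarray(bmi_cat, int),
                   axis=np.zeros(n, int), alive=np.ones(n, bool),
                   has_condition=np.zeros((n, len(conditions)), bool),
                   onset_year=np.full((n, len(conditions)), -1, int),
                   conditions=list(conditions))


def step_year(state: CohortState, model: TransitionModel,
              rng: np.random.Generator, year: int,
              incidence_mult: float = 1.0, mortality_mult: float = 1.0):
    """Advance every living person one year.

    Returns (incident events bool [n, n_cond], died bool [n], cause index
    [n]; cause -1 = alive, n_cond = background).
    """
    n = len(state.age)
    alive = state.alive
    band = model.band_index(state.age)
    sex = state.male.astype(int)

    # BMI-category transition: one categorical draw per person
    rows = model.bmi_trans[sex, band, state.bmi_cat]          # [n, 3]
    u = rng.random(n)
    cum = np.cumsum(rows, axis=1)
    new_cat = (u[:, None] >= cum).sum(axis=1)
    state.bmi_cat = np.where(alive, np.minimum(new_cat, 2), state.bmi_cat)

    # outcome incidence: independent Bernoulli draws per eligible condition
    events = np.zeros((n, len(state.conditions)), bool)
    for ci, cond in enumerate(state.conditions):
        p = model.incidence[cond][sex, band, state.bmi_cat] * incidence_mult
        if cond in FEMALE_ONLY:
            p = np.where(state.male, 0.0, p)
        elif cond in MALE_ONLY:
            p = np.where(state.male, p, 0.0)
        hit = alive & ~state.has_condition[:, ci] & (rng.random(n) < np.clip(p, 0, 1))
        events[:, ci] = hit
        state.has_condition[hit, ci] = True
        state.onset_year[hit, ci] = year

    # dominant-axis update from the new events
    for ci, cond in enumerate(state.conditions):
        ax = CONDITION_AXES.index(AXIS_OF[cond])
        take = events[:, ci] & (_AXIS_PRIO[state.axis] < _AXIS_PRIO[ax])
        state.axis[take] = ax

    # mortality: background + first-year case fatality + prevalent excess
    contrib = np.zeros((n, len(state.conditions) + 1))
    contrib[:, -1] = model.background_mort[sex, band] * mortality_mult
    for ci, cond in enumerate(state.conditions):
        contrib[:, ci] = (events[:, ci] * model.case_fatality[cond]
                          + (state.has_condition[:, ci] & ~events[:, ci])
                          * model.excess_mort[cond]) * mortality_mult
    p_death = np.clip(contrib.sum(axis=1), 0.0, 1.0)
    dies = alive & (rng.random(n) < p_death)

    cause = np.full(n, -1, int)
    if dies.any():
        c = contrib[dies]
        c = c / c.sum(axis=1, keepdims=True)
        cum = np.cumsum(c, axis=1)
        cause[dies] = (rng.random(dies.sum())[:, None] >= cum).sum(axis=1)
    state.alive = alive & ~dies
    state.age = np.where(state.alive, state.age + 1.0, state.age)
    return events, dies, cause


# ------------------------------------------------------------------ life-course
@dataclass
class TrialResult:
    cases: pd.Series                  # incident cases by condition
    deaths_by_cause: pd.Series        # includes "background"
    total_deaths: int
    dalys: float                      # discounted YLD + YLL
    yld: float
    yll: float
    direct_medical: float             # discounted USD
    productivity: float               # discounted USD
    ages_at_death: np.ndarray


@dataclass
class LifecourseResult:
    trials: list[TrialResult]
    conditions: list[str]

    def mean_ledger(self) -> econ.LedgerRow:
        return econ.LedgerRow(
            dalys=float(np.mean([t.dalys for t in self.trials])),
            direct_medical=float(np.mean([t.direct_medical for t in self.trials])),
            productivity=float(np.mean([t.productivity for t in self.trials])))

    def mean_cases(self) -> pd.Series:
        return pd.concat([t.cases for t in self.trials], axis=1).mean(axis=1)

    def mean_deaths(self) -> pd.Series:
        return pd.concat([t.deaths_by_cause for t in self.trials], axis=1).mean(axis=1)


def _triangular(rng, lo_mode_hi):
    lo, mode, hi = lo_mode_hi
    if lo == mode == hi:
        return mode
    return rng.triangular(lo, mode, hi)


def run_lifecourse(entry_bmi_cat, male, model: TransitionModel,
                   adult_cfg: AdultConfig, econ_cfg: EconConfig,
                   trials: int, seed: int,
                   entry_year_offset: float | np.ndarray = 5.0,
                   life_table: pd.DataFrame | None = None,
                   psa: bool = True) -> LifecourseResult:
    """Monte Carlo trials of the full adult life course.

    Each trial redraws the PSA multipliers (triangular by parameter group),
    then steps the whole cohort annually to the absorbing death state,
    accruing discounted costs (dominance rule per person-year), YLD (the
    accrued disability weight per lived year) and YLL (a year-by-year
    discounted stream over the remaining life expectancy at death).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    life_table = life_table if life_table is not None else load_life_table()
    lt_age = life_table["age"].to_numpy(float)
    lt_e = life_table["remaining_life_expectancy"].to_numpy(float)
    conditions = sorted(model.incidence)
    rate = econ_cfg.discount_rate
    offsets = np.broadcast_to(np.asarray(entry_year_offset, float),
                              np.shape(entry_bmi_cat)).astype(float)

    costs_first = model.costs["mx_cost_first_year"]
    costs_sub = model.costs["mx_cost_subsequent"]
    dw = model.costs["disability_weight"]

    root = np.random.SeedSequence([int(seed), 77_015])
    out: list[TrialResult] = []
    for child in root.spawn(trials):
        rng = np.random.default_rng(child)
        inc_m = _triangular(rng, adult_cfg.psa_incidence) if psa else 1.0
        mort_m = _triangular(rng, adult_cfg.psa_mortality) if psa else 1.0
        cost_m = _triangular(rng, adult_cfg.psa_cost) if psa else 1.0
        dw_m = _triangular(rng, adult_cfg.psa_disability) if psa else 1.0

        st = CohortState.from_entry(entry_bmi_cat, male, conditions)
        n = len(st.age)
        cases = np.zeros(len(conditions))
        deaths_by_cause = np.zeros(len(conditions) + 1)
        direct = productivity = yld = yll = 0.0
        ages_at_death = []

        cf = np.array([costs_first[c] for c in conditions]) * cost_m
        cs = np.array([costs_sub[c] for c in conditions]) * cost_m
        dws = np.clip(np.array([dw[c] for c in conditions]) * dw_m, 0.0, 1.0)

        for year in range(adult_cfg.max_age - 18):
            if not st.alive.any():
                break
            alive_before = st.alive.copy()
            events, dies, cause = step_year(st, model, rng, year, inc_m, mort_m)
            cases += events.sum(axis=0)
            for ci in range(len(conditions) + 1):
                deaths_by_cause[ci] += int((cause == ci).sum())

            # person-year accrual with the dominance rule (max-cost condition)
            ann_cost = np.where(st.onset_year == year, cf, cs) * st.has_condition
            top_cost = ann_cost.max(axis=1)
            top_idx = ann_cost.argmax(axis=1)
            has_any = st.has_condition.any(axis=1)
            top_dw = np.where(has_any, dws[top_idx], 0.0)
            disc = 1.0 / (1.0 + rate) ** (offsets + year)
            direct += float((top_cost * alive_before * disc).sum())
            productivity += float((econ_cfg.annual_income_usd * top_dw
                                   * alive_before * disc).sum())
            yld += float((top_dw * alive_before * disc).sum())

            if dies.any():
                age_d = st.age[dies]
                ages_at_death.append(age_d)
                e_rem = np.interp(np.clip(age_d, lt_age[0], lt_age[-1]), lt_age, lt_e)
                t0 = offsets[dies] + year
                # discounted annuity of e_rem years starting at death
                full = np.floor(e_rem)
                ann = (1 - (1 + rate) ** -full) / rate
                frac = (e_rem - full) * (1 + rate) ** -(full)
                yll += float((( ann + frac) / (1 + rate) ** t0).sum())

        out.append(TrialResult(
            cases=pd.Series(cases, index=conditions),
            deaths_by_cause=pd.Series(deaths_by_cause, index=conditions + ["background"]),
            total_deaths=int(n - st.alive.sum()),
            dalys=yld + yll, yld=yld, yll=yll,
            direct_medical=direct, productivity=productivity,
            ages_at_death=np.concatenate(ages_at_death) if ages_at_death else np.array([])))
    return LifecourseResult(trials=out, conditions=conditions)


def cohort_outcome_totals(result: LifecourseResult, n_cohort: int,
                          male: np.ndarray | None = None) -> pd.DataFrame:
    """Mean condition and death counts across trials, with per-100k rates."""
    cases = result.mean_cases()
    deaths = result.mean_deaths()
    rows = []
    for cond in result.conditions:
        rows.append({"condition": cond, "cases": cases[cond],
                     "deaths": deaths.get(cond, 0.0),
                     "cases_per_100k": cases[cond] / n_cohort * 1e5,
                     "deaths_per_100k": deaths.get(cond, 0.0) / n_cohort * 1e5})
    rows.append({"condition": "background", "cases": 0.0,
                 "deaths": deaths["background"], "cases_per_100k": 0.0,
                 "deaths_per_100k": deaths["background"] / n_cohort * 1e5})
    return pd.DataFrame(rows)
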