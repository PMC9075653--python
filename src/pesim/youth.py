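"""Daily agent-based simulation of school PE and after-school activity.

The engine advances every agent in one-day steps for the whole horizon:

* on scheduled PE days, students are moderately-to-vigorously active
  (default 6 METs) for the sex-specific fraction of class time and lightly
  active (default 2 METs) for the remainder;
* every day each agent makes a Bernoulli after-school (or non-school-day)
  activity decision from a logistic on socio-cognitive/environmental
  factors; an event lasts 100 minutes at 6 METs;
* caloric intake is assigned annually from the agent's personal reference
  growth trajectory plus a calibrated global surplus, and does NOT respond
  to activity (no compensatory intake);
* the daily energy imbalance is converted to fat/fat-free mass changes by
  the metabolism module, and height/age advance along the growth reference.

Incremental activity expenditure uses the (METs - 1) convention so resting
expenditure is not double-counted against maintenance; a gross-MET mode is
available behind ``MetabolicConfig.use_gross_mets``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metabolism
from .config import BehaviorConfig, CalendarConfig, ScenarioConfig, SimConfig
from .reference import GrowthReference, OVERWEIGHT_Z

PRIMARY_MAX_AGE = 12.0   # primary school: ages 6-11; secondary: 12-18
SCHOOL_EXIT_AGE = 19.0   # students attend through their 18th year


# --------------------------------------------------------------------- calendar
def build_calendar(years: int, school_days_per_week: int = 5,
                   school_weeks_per_year: int = 40,
                   days_per_year: int = 365) -> pd.DataFrame:
    """Day-type calendar: one row per simulated day.

    School days are the first ``school_days_per_week`` weekdays of the first
    ``school_weeks_per_year`` weeks of each simulated year.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if not 1 <= school_days_per_week <= 7:
        raise ValueError("school_days_per_week must be in 1..7")
    day = np.arange(years * days_per_year)
    day_of_year = day % days_per_year
    weekday = day_of_year % 7
    week_of_year = day_of_year // 7
    is_school = (weekday < school_days_per_week) & (week_of_year < school_weeks_per_year)
    return pd.DataFrame({"day": day, "year": day // days_per_year,
                         "weekday": weekday, "week_of_year": week_of_year,
                         "is_school_day": is_school})


def pe_days(calendar: pd.DataFrame, sessions_per_week: int,
            school_days_per_week: int = 5) -> np.ndarray:
    """Boolean mask of PE days: sessions placed on the earliest weekdays."""
    if sessions_per_week < 0:
        raise ValueError("sessions_per_week must be >= 0")
    if sessions_per_week > school_days_per_week:
        raise ValueError(
            f"cannot schedule {sessions_per_week} PE sessions in a "
            f"{school_days_per_week}-day school week")
    return (calendar["is_school_day"].to_numpy()
            & (calendar["weekday"].to_numpy() < sessions_per_week))


# ------------------------------------------------------------------ operations
def pe_active_minutes(male, primary_level, scenario: ScenarioConfig,
                      is_pe_day_for_level) -> np.ndarray:
    """Active minutes in PE class: session length x sex-specific fraction.

    Zero when PE is not offered or there is no session that day.
    """
    male = np.asarray(male, bool)
    primary_level = np.asarray(primary_level, bool)
    on = np.asarray(is_pe_day_for_level, bool)
    if not scenario.pe_offered:
        return np.zeros(np.broadcast(male, primary_level, on).shape)
    sess = np.where(primary_level, scenario.primary_session_minutes,
                    scenario.secondary_session_minutes)
    frac = np.where(male, scenario.fraction_active_male, scenario.fraction_active_female)
    return np.where(on, sess * frac, 0.0)


def afterschool_probability(propensity, proximity, ses_norm,
                            behavior: BehaviorConfig) -> np.ndarray:
    """Daily after-school participation probability (logistic link)."""
    logit = (behavior.beta_intercept
             + behavior.beta_propensity * np.asarray(propensity, float)
             + behavior.beta_proximity * np.asarray(proximity, float)
             + behavior.beta_ses * np.asarray(ses_norm, float))
    return 1.0 / (1.0 + np.exp(-logit))


def afterschool_decision(p, uplift_active, scenario: ScenarioConfig,
                         rng: np.random.Generator, behavior: BehaviorConfig):
    """Bernoulli participation draw; returns (participates, minutes).

    ``uplift_active`` marks agents whose probability is multiplied by the
    spillover uplift (PE attendance that week under a spillover scenario).
    """
    p = np.asarray(p, float)
    if scenario.spillover_enabled:
        p = np.where(np.asarray(uplift_active, bool),
                     np.minimum(p * scenario.spillover_uplift, 1.0), p)
    participates = rng.random(p.shape) < p
    minutes = np.where(participates, behavior.afterschool_event_minutes, 0.0)
    return participates, minutes


def daily_expenditure(weight_kg, bouts, params) -> np.ndarray:
    """Incremental activity expenditure for a list of (minutes, METs) bouts.

    kcal = sum (METs - 1) * weight * hours  (incremental convention), or
    METs * weight * hours when gross accounting is configured.
    """
    w = np.asarray(weight_kg, float)
    total = np.zeros_like(w)
    offset = 0.0 if params.use_gross_mets else 1.0
    for minutes, mets in bouts:
        minutes = np.asarray(minutes, float)
        if np.any(minutes < 0):
            raise ValueError("negative activity minutes")
        total = total + (mets - offset) * w * (minutes / 60.0)
    return total


# ---------------------------------------------------------------------- result
@dataclass
class YouthResult:
    scenario: str
    years: int
    yearly: pd.DataFrame            # year, prevalence, prev_male, prev_female, obese
    final: dict = field(default_factory=dict)   # arrays: weight, height, fat, ffm, age, bmi_z
    z_at_18: np.ndarray | None = None
    cum_energy_kcal: np.ndarray | None = None
    stored_energy_kcal: np.ndarray | None = None
    clamp_events: int = 0

    @property
    def final_prevalence(self) -> float:
        return float(self.yearly["prevalence"].iloc[-1])

    def prevalence_by_sex(self) -> tuple[float, float]:
        r = self.yearly.iloc[-1]
        return float(r["prev_male"]), float(r["prev_female"])


# ---------------------------------------------------------------------- engine
def run_youth_simulation(population, scenario: ScenarioConfig, config: SimConfig,
                         seed: int, years: int | None = None,
                         surplus: float | None = None,
                         ref: GrowthReference | None = None) -> YouthResult:
    """Run the daily simulation for the whole cohort.

    ``surplus`` overrides the calibrated global intake surplus (kcal/day);
    0.0 is used if neither is set (with a warning-free fallback — the
    calibration operation persists its result into the config).
    """
    agents = population.agents if hasattr(population, "agents") else population
    ref = ref or GrowthReference.packaged()
    mp = config.metabolism
    beh = config.behavior
    years = int(years if years is not None else config.years)
    if surplus is None:
        surplus = config.intake_surplus_kcal if config.intake_surplus_kcal is not None else 0.0

    n = len(agents)
    male = agents["sex"].to_numpy() == "male"
    age = agents["age"].to_numpy(float).copy()
    height = agents["height_cm"].to_numpy(float).copy()
    fm = agents["fat_mass_kg"].to_numpy(float).copy()
    ffm = agents["fat_free_mass_kg"].to_numpy(float).copy()
    z0 = agents["bmi_z0"].to_numpy(float)
    p_base = agents["p_afterschool"].to_numpy(float)
    mult = agents["intake_multiplier"].to_numpy(float)

    cal = build_calendar(years, config.calendar.school_days_per_week,
                         config.calendar.school_weeks_per_year,
                         config.calendar.days_per_year)
    dpy = config.calendar.days_per_year
    is_school = cal["is_school_day"].to_numpy()
    week_index = (cal["day"].to_numpy() // 7)
    pe_primary = pe_days(cal, scenario.primary_sessions_per_week,
                         config.calendar.school_days_per_week) if scenario.pe_offered \
        else np.zeros(len(cal), bool)
    pe_secondary = pe_days(cal, scenario.secondary_sessions_per_week,
                           config.calendar.school_days_per_week) if scenario.pe_offered \
        else np.zeros(len(cal), bool)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2_065_118]))

    ev_min = beh.afterschool_event_minutes
    ev_int = beh.afterschool_intensity_mets
    offset = 0.0 if mp.use_gross_mets else 1.0

    fm0, ffm0 = fm.copy(), ffm.copy()
    cum_e = np.zeros(n)
    clamp_total = 0
    z18 = np.full(n, np.nan)
    last_pe_week = np.full(n, -10, dtype=np.int64)

    vel = np.zeros(n)
    w_ref0 = np.zeros(n)
    w_ref_slope = np.zeros(n)
    intake_extra = np.zeros(n)
    records = []

    def annual_refresh():
        """Set this year's reference-weight track and non-maintenance intake.

        Daily intake follows the maintenance requirement of the agent's
        personal z-preserving reference weight (interpolated within the
        year) plus growth-accretion energy, the expected after-school
        expenditure, and the calibrated surplus. It never responds to the
        activity actually realised (no compensatory intake).
        """
        nonlocal vel, w_ref0, w_ref_slope, intake_extra
        vel = ref.height_velocity(age + 0.5, male)
        h_m = height / 100.0
        w_ref0 = ref.bmi_for_z(z0, age, male) * h_m ** 2
        h1 = (height + vel) / 100.0
        w_ref1 = ref.bmi_for_z(z0, age + 1.0, male) * h1 ** 2
        w_ref_slope = (w_ref1 - w_ref0) / dpy
        growth_kcal = metabolism.energy_density(fm, mp) * w_ref_slope
        expected_as = p_base * (ev_int - offset) * w_ref0 * (ev_min / 60.0)
        intake_extra = (np.maximum(growth_kcal, 0.0) + expected_as
                        + surplus * mult)

    def snapshot(year_idx):
        w = fm + ffm
        bmi = w / (height / 100.0) ** 2
        z = ref.bmi_z(bmi, age, male)
        ow = z > OVERWEIGHT_Z
        records.append({
            "year": year_idx,
            "prevalence": float(ow.mean()),
            "prev_male": float(ow[male].mean()) if male.any() else np.nan,
            "prev_female": float(ow[~male].mean()) if (~male).any() else np.nan,
            "obesity": float((z > 2.0).mean()),
        })
        return z

    snapshot(0)
    for d in range(len(cal)):
        if d % dpy == 0:
            annual_refresh()
        w_ref_t = w_ref0 + w_ref_slope * (d % dpy)
        intake = np.clip(mp.pal * metabolism.bmr(w_ref_t, age, male) + intake_extra,
                         mp.intake_floor_kcal, mp.intake_cap_kcal)
        w = fm + ffm
        in_school = age < SCHOOL_EXIT_AGE
        primary = age < PRIMARY_MAX_AGE

        active_min = np.zeros(n)
        light_min = np.zeros(n)
        if scenario.pe_offered and is_school[d]:
            has_pe = np.where(primary, pe_primary[d], pe_secondary[d]) & in_school
            sess = np.where(primary, scenario.primary_session_minutes,
                            scenario.secondary_session_minutes)
            frac = np.where(male, scenario.fraction_active_male,
                            scenario.fraction_active_female)
            active_min = np.where(has_pe, sess * frac, 0.0)
            # a class engaging zero active time is fully sedentary: no
            # light-activity increment either (null-policy equivalence)
            light_min = np.where(has_pe & (frac > 0), sess * (1.0 - frac), 0.0)
            last_pe_week = np.where(has_pe & (active_min > 0), week_index[d], last_pe_week)

        uplift = (last_pe_week == week_index[d]) if scenario.spillover_enabled \
            else np.zeros(n, bool)
        participates, as_min = afterschool_decision(p_base, uplift, scenario, rng, beh)

        activity = ((scenario.activity_intensity_mets - offset) * w * (active_min / 60.0)
                    + (mp.light_intensity_mets - offset) * w * (light_min / 60.0)
                    + (ev_int - offset) * w * (as_min / 60.0))
        maint = mp.pal * metabolism.bmr(w, age, male)
        e = intake - maint - activity

        p_frac = metabolism.partition_fraction(fm, mp)
        new_fm, new_ffm, clamped = metabolism.update_body_composition(fm, ffm, e, mp)
        if clamped.any():
            # energy discarded by the fat-mass floor, kept out of the ledger
            raw_fm = fm + (1 - p_frac) * e / mp.rho_fat
            e = e - mp.rho_fat * (raw_fm - new_fm) / np.maximum(1 - p_frac, 1e-9)
            clamp_total += int(clamped.sum())
        fm, ffm = new_fm, new_ffm
        cum_e += e

        age += 1.0 / dpy
        height += vel / dpy

        if (d + 1) % dpy == 0:
            if not np.all(np.isfinite(fm + ffm)):
                bad = int(np.flatnonzero(~np.isfinite(fm + ffm))[0])
                raise FloatingPointError(
                    f"non-finite body mass for agent index {bad} at day {d}")
            z = snapshot((d + 1) // dpy)
            crossed = (age >= 18.0) & np.isnan(z18)
            z18[crossed] = z[crossed]

    w = fm + ffm
    bmi = w / (height / 100.0) ** 2
    final = {"weight_kg": w, "height_cm": height, "fat_mass_kg": fm,
             "fat_free_mass_kg": ffm, "age": age,
             "bmi": bmi, "bmi_z": ref.bmi_z(bmi, age, male), "male": male}
    stored = mp.rho_fat * (fm - fm0) + mp.rho_lean * (ffm - ffm0)
    return YouthResult(scenario=scenario.name, years=years,
                       yearly=pd.DataFrame(records), final=final, z_at_18=z18,
                       cum_energy_kcal=cum_e, stored_energy_kcal=stored,
                       clamp_events=clamp_total)
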