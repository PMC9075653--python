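"""Synthetic youth cohort: agents, schools, and activity locations.

The generator emulates the statistical structure the analysis needs —
age/sex marginals, school assignment by level and proximity, sex-specific
anthropometry on a BMI-for-age z scale, socioeconomic strata and activity
propensities — without any real census or map data. Districts are four
labeled rectangular zones with uniform home placement.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

from .config import FULL_COHORT_SIZE, PopulationConfig, ScenarioConfig, SimConfig
from .reference import GrowthReference
from .youth import afterschool_probability, run_youth_simulation

PRIMARY_AGE_MAX = 11  # primary: 6-11; secondary: 12-18


@dataclass
class Population:
    agents: pd.DataFrame
    schools: pd.DataFrame
    locations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.agents)

    def write(self, outdir: str | Path) -> None:
        """Flat CSV tables plus a JSON sidecar of generation parameters."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.agents.to_csv(outdir / "agents.csv", index=False)
        self.schools.to_csv(outdir / "schools.csv", index=False)
        self.locations.to_csv(outdir / "activity_locations.csv", index=False)
        (outdir / "population_meta.json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def read(cls, outdir: str | Path) -> "Population":
        outdir = Path(outdir)
        return cls(agents=pd.read_csv(outdir / "agents.csv"),
                   schools=pd.read_csv(outdir / "schools.csv"),
                   locations=pd.read_csv(outdir / "activity_locations.csv"),
                   meta=json.loads((outdir / "population_meta.json").read_text()))


def _validate(cfg: PopulationConfig) -> None:
    if cfg.n_agents <= 0:
        raise ValueError("cohort size must be positive")
    if not 0.0 <= cfg.sex_ratio_male <= 1.0:
        raise ValueError("sex_ratio_male must be in [0,1]")
    if not 0.0 < cfg.baseline_prevalence < 1.0:
        raise ValueError("baseline_prevalence must be in (0,1)")
    if cfg.bmi_z_sd < 0 or cfg.height_z_sd < 0:
        raise ValueError("distribution scale parameters must be non-negative")
    if cfg.age_min < 6 or cfg.age_max > 18 or cfg.age_min > cfg.age_max:
        raise ValueError("ages must satisfy 6 <= age_min <= age_max <= 18")


def assign_baseline_anthropometry(agents: pd.DataFrame, cfg: PopulationConfig,
                                  ref: GrowthReference,
                                  rng: np.random.Generator) -> pd.DataFrame:
    """Draw height, BMI-z, weight, and the fat / fat-free split.

    BMI-for-age z ~ Normal(mu0, sigma_z) with mu0 set so the configured
    baseline combined overweight+obesity prevalence (z > +1) holds exactly
    in expectation. The fat split uses a sex-specific body-fat-percent
    regression on BMI and age (configurable coefficients, an assumption).
    """
    n = len(agents)
    male = agents["sex"].to_numpy() == "male"
    age = agents["age"].to_numpy(float)

    sigma = cfg.bmi_z_sd
    mu0 = 1.0 - sigma * norm.isf(cfg.baseline_prevalence)
    z0 = rng.normal(mu0, sigma, n)

    height = ref.median_height(age, male) + rng.normal(0.0, 1.0, n) \
        * ref.height_sd(age, male) * cfg.height_z_sd
    bmi = ref.bmi_for_z(z0, age, male)
    weight = bmi * (height / 100.0) ** 2

    c0, c_bmi, c_age, c_male = cfg.bodyfat_coeffs
    bf_pct = np.clip(c0 + c_bmi * bmi + c_age * age + c_male * male, 5.0, 60.0)
    fat = bf_pct / 100.0 * weight

    out = agents.copy()
    out["bmi_z0"] = z0
    out["height_cm"] = height
    out["weight_kg"] = weight
    out["fat_mass_kg"] = fat
    out["fat_free_mass_kg"] = weight - fat
    return out


def generate_population(config: SimConfig, seed: int,
                        ref: GrowthReference | None = None) -> Population:
    """Generate the full synthetic cohort, schools, and activity locations.

    Deterministic given ``seed``. Every agent is assigned exactly one school
    of the level matching its age (nearest same-level school in its home
    district).
    """
    cfg = config.population
    _validate(cfg)
    ref = ref or GrowthReference.packaged()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 901]))
    n = cfg.n_agents

    # ------------------------------------------------------------ demographics
    ages = rng.integers(cfg.age_min, cfg.age_max + 1, n)
    male = rng.random(n) < cfg.sex_ratio_male
    weights = np.array([d.weight for d in cfg.districts], float)
    weights = weights / weights.sum()
    district_idx = rng.choice(len(cfg.districts), n, p=weights)
    home_x = np.empty(n)
    home_y = np.empty(n)
    for i, d in enumerate(cfg.districts):
        m = district_idx == i
        home_x[m] = rng.uniform(d.x_min, d.x_max, m.sum())
        home_y[m] = rng.uniform(d.y_min, d.y_max, m.sum())

    # --------------------------------------------------------------- schools
    scale = n / FULL_COHORT_SIZE
    n_schools = max(2 * len(cfg.districts), int(round(cfg.schools_full_scale * scale)))
    per_district = max(2, n_schools // len(cfg.districts))
    school_rows = []
    sid = 0
    for i, d in enumerate(cfg.districts):
        for j in range(per_district):
            level = "primary" if j % 2 == 0 else "secondary"
            school_rows.append({
                "school_id": f"S{sid:04d}", "level": level, "district": d.name,
                "x_km": rng.uniform(d.x_min, d.x_max),
                "y_km": rng.uniform(d.y_min, d.y_max)})
            sid += 1
    schools = pd.DataFrame(school_rows)

    school_id = np.empty(n, dtype=object)
    for i, d in enumerate(cfg.districts):
        for level, age_mask in (("primary", ages <= PRIMARY_AGE_MAX),
                                ("secondary", ages > PRIMARY_AGE_MAX)):
            m = (district_idx == i) & age_mask
            if not m.any():
                continue
            sub = schools[(schools["district"] == d.name) & (schools["level"] == level)]
            tree = cKDTree(sub[["x_km", "y_km"]].to_numpy())
            _, nearest = tree.query(np.column_stack([home_x[m], home_y[m]]))
            school_id[m] = sub["school_id"].to_numpy()[nearest]

    # ---------------------------------------------------- activity locations
    n_act = max(2 * len(cfg.districts),
                int(round(cfg.activity_locations_full_scale * scale)))
    kinds = rng.choice(["park", "gym", "school_grounds"], n_act, p=[0.5, 0.2, 0.3])
    loc_d = rng.choice(len(cfg.districts), n_act, p=weights)
    loc_x = np.empty(n_act)
    loc_y = np.empty(n_act)
    for i, d in enumerate(cfg.districts):
        m = loc_d == i
        loc_x[m] = rng.uniform(d.x_min, d.x_max, m.sum())
        loc_y[m] = rng.uniform(d.y_min, d.y_max, m.sum())
    locations = pd.DataFrame({
        "loc_id": [f"L{i:04d}" for i in range(n_act)], "kind": kinds,
        "x_km": loc_x, "y_km": loc_y})

    tree = cKDTree(np.column_stack([loc_x, loc_y]))
    dist, _ = tree.query(np.column_stack([home_x, home_y]))
    proximity = np.exp(-dist / config.behavior.proximity_scale_km)

    # ---------------------------------------------------- behavior covariates
    ses = rng.integers(1, cfg.ses_levels + 1, n)
    propensity = rng.beta(cfg.propensity_beta_a, cfg.propensity_beta_b, n)
    sigma_m = config.metabolism.intake_multiplier_sigma
    mult = rng.lognormal(-0.5 * sigma_m ** 2, sigma_m, n)

    agents = pd.DataFrame({
        "agent_id": [f"A{i:06d}" for i in range(n)],
        "age": ages, "sex": np.where(male, "male", "female"),
        "ses": ses, "district": [cfg.districts[i].name for i in district_idx],
        "home_x_km": home_x, "home_y_km": home_y, "school_id": school_id,
        "pa_propensity": propensity, "proximity": proximity,
        "intake_multiplier": mult,
    })
    agents = assign_baseline_anthropometry(agents, cfg, ref, rng)
    ses_norm = (ses - 1) / max(cfg.ses_levels - 1, 1)
    agents["p_afterschool"] = afterschool_probability(
        propensity, proximity, ses_norm, config.behavior)
    # nominal intake at zero surplus; the engine refreshes this annually
    from . import metabolism as _met
    agents["daily_intake"] = np.clip(
        _met.maintenance_expenditure(agents["weight_kg"].to_numpy(), ages, male,
                                     config.metabolism),
        config.metabolism.intake_floor_kcal, config.metabolism.intake_cap_kcal)

    meta = {"seed": int(seed), "n_agents": int(n),
            "baseline_prevalence_target": cfg.baseline_prevalence,
            "bmi_z_sd": cfg.bmi_z_sd, "n_schools": len(schools),
            "n_activity_locations": n_act}
    return Population(agents=agents, schools=schools, locations=locations, meta=meta)


# ------------------------------------------------------------------ calibration
@dataclass
class CalibrationResult:
    surplus_kcal: float
    achieved_prevalence: float
    target_prevalence: float
    evaluations: int
    converged: bool


def calibrate_intake(population: Population, config: SimConfig,
                     scenario: ScenarioConfig, target_prevalence: float,
                     tolerance: float, seed: int,
                     bracket: tuple[float, float] = (-150.0, 250.0),
                     max_iter: int = 24) -> CalibrationResult:
    """Bisection search over the global intake surplus (kcal/day) so the
    simulated five-year prevalence under ``scenario`` (normally no-PE) hits
    the target. The search is seeded and deterministic; the calibrated
    surplus is persisted into ``config.intake_surplus_kcal`` and the
    agents' ``daily_intake`` column is updated.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must be in (0,1)")
    evals = 0

    def f(surplus: float) -> float:
        nonlocal evals
        evals += 1
        res = run_youth_simulation(population, scenario, config, seed=seed,
                                   surplus=surplus)
        return res.final_prevalence

    p0 = f(0.0)
    if abs(p0 - target_prevalence) <= tolerance:
        _persist(population, config, 0.0)
        return CalibrationResult(0.0, p0, target_prevalence, evals, True)

    lo, hi = bracket
    plo, phi = f(lo), f(hi)
    if not plo <= target_prevalence <= phi:
        raise ValueError(
            f"target prevalence {target_prevalence:.4f} unreachable within the "
            f"intake-surplus bracket [{lo}, {hi}] kcal/day "
            f"(achievable range {plo:.4f}..{phi:.4f})")
    pm = p0
    mid = 0.0
    if p0 < target_prevalence:
        lo, plo = 0.0, p0
    else:
        hi, phi = 0.0, p0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        pm = f(mid)
        if abs(pm - target_prevalence) <= tolerance or (hi - lo) < 0.5:
            break
        if pm < target_prevalence:
            lo = mid
        else:
            hi = mid
    converged = abs(pm - target_prevalence) <= tolerance
    _persist(population, config, mid)
    return CalibrationResult(mid, pm, target_prevalence, evals, converged)


def _persist(population: Population, config: SimConfig, surplus: float) -> None:
    config.intake_surplus_kcal = float(surplus)
    a = population.agents
    a["daily_intake"] = np.clip(
        a["daily_intake"].to_numpy()
        + surplus * a["intake_multiplier"].to_numpy(),
        config.metabolism.intake_floor_kcal, config.metabolism.intake_cap_kcal)
    population.meta["intake_surplus_kcal"] = float(surplus)
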