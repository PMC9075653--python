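"""Configuration for the PE-policy simulation.

Every stand-in default that fills a gap left by unavailable source data
(census marginals, anthropometric survey distributions, socio-cognitive
coefficients) is a named key here, so swapping in better data is a config
change, not a code change.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: full-scale cohort: every 6-18-year-old student in the four modelled
#: districts; desk-scale runs default to 20,000 with results reported as
#: prevalences/rates so they are comparable.
FULL_COHORT_SIZE = 218_163
#: schools implied by the printed program-cost arithmetic
#: (42,032,248 USD / 38,811 USD per school).
FULL_SCHOOL_COUNT = 1_083


@dataclass
class DistrictConfig:
    """A labeled rectangular zone with uniform home placement (km)."""

    name: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    weight: float = 0.25


def _default_districts() -> list[DistrictConfig]:
    # four abutting 6x6 km zones; purely synthetic stand-ins for the
    # real central-city districts
    names = ["district_a", "district_b", "district_c", "district_d"]
    out = []
    for i, n in enumerate(names):
        x0 = (i % 2) * 6.0
        y0 = (i // 2) * 6.0
        out.append(DistrictConfig(n, x0, x0 + 6.0, y0, y0 + 6.0))
    return out


@dataclass
class PopulationConfig:
    n_agents: int = 20_000
    age_min: int = 6
    age_max: int = 18
    sex_ratio_male: float = 0.5
    districts: list[DistrictConfig] = field(default_factory=_default_districts)
    schools_full_scale: int = FULL_SCHOOL_COUNT
    activity_locations_full_scale: int = 1_200
    #: year-0 combined overweight+obesity target; the no-PE five-year run is
    #: then calibrated (via the intake surplus) onto the rising-trend endpoint.
    baseline_prevalence: float = 0.29
    #: SD of the baseline BMI-for-age z distribution relative to the packaged
    #: reference; >1 encodes the overdispersion of a high-prevalence urban
    #: population.
    bmi_z_sd: float = 1.25
    height_z_sd: float = 1.0
    ses_levels: int = 5
    #: Beta(a, b) for the socio-cognitive activity propensity score
    propensity_beta_a: float = 2.0
    propensity_beta_b: float = 2.0
    #: body-fat%% = c0 + c1*BMI + c2*age + c3*male, clamped to [5, 60]
    bodyfat_coeffs: tuple[float, float, float, float] = (1.4, 1.51, -0.70, -3.6)


@dataclass
class BehaviorConfig:
    """After-school participation model: daily Bernoulli with
    p = logistic(b0 + b_prop*propensity + b_prox*proximity + b_ses*ses_norm).

    Defaults sized so mean daily p is about 0.075, i.e. roughly 40% of agents
    do at least one after-school event in a week under no PE.
    """

    beta_intercept: float = -3.45
    beta_propensity: float = 1.2
    beta_proximity: float = 0.6
    beta_ses: float = 0.3
    afterschool_event_minutes: float = 100.0
    afterschool_intensity_mets: float = 6.0
    #: e-folding distance (km) for the home-to-facility proximity factor
    proximity_scale_km: float = 1.0


@dataclass
class MetabolicConfig:
    rho_fat: float = 9_500.0        # kcal per kg fat tissue
    rho_lean: float = 1_800.0       # kcal per kg lean tissue
    partition_constant: float = 10.4  # Forbes-type constant (kg)
    pal: float = 1.4                # physical-activity level on BMR, excl. modelled PA
    #: in-class intensity for the non-active share of a PE class (standing,
    #: instruction) relative to 1-MET rest
    light_intensity_mets: float = 2.0
    intake_cap_kcal: float = 2_800.0
    intake_floor_kcal: float = 600.0
    #: lognormal sigma of the per-agent surplus multiplier
    intake_multiplier_sigma: float = 0.35
    #: gross-MET accounting (no -1 subtraction) behind a flag; default is the
    #: incremental convention so resting expenditure is not double-counted
    use_gross_mets: bool = False
    fat_floor_kg: float = 0.5


@dataclass
class CalendarConfig:
    school_days_per_week: int = 5
    school_weeks_per_year: int = 40   # 200 school days/yr
    days_per_year: int = 365


@dataclass
class EconConfig:
    discount_rate: float = 0.03
    exchange_rate_pesos_per_usd: float = 20.5
    oecd_price_ratio: float = 0.45     # MX/US healthcare price-level ratio
    wtp_per_daly: float = 8_597.0      # GDP per capita, USD/DALY
    annual_income_usd: float = 9_000.0  # productivity proxy (income incl. benefits)


@dataclass
class AdultConfig:
    trials: int = 1_000
    max_age: int = 100
    #: triangular PSA multiplier ranges (low, mode, high) by parameter group
    psa_incidence: tuple[float, float, float] = (0.8, 1.0, 1.2)
    psa_mortality: tuple[float, float, float] = (0.85, 1.0, 1.15)
    psa_cost: tuple[float, float, float] = (0.75, 1.0, 1.25)
    psa_disability: tuple[float, float, float] = (0.8, 1.0, 1.2)


@dataclass
class ScenarioConfig:
    name: str
    pe_offered: bool = False
    primary_sessions_per_week: int = 0
    primary_session_minutes: float = 0.0
    secondary_sessions_per_week: int = 0
    secondary_session_minutes: float = 0.0
    fraction_active_male: float = 0.0
    fraction_active_female: float = 0.0
    activity_intensity_mets: float = 6.0
    spillover_enabled: bool = False
    spillover_uplift: float = 1.5
    program_cost_npv: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.fraction_active_male, self.fraction_active_female):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction_active must be in [0,1], got {f}")
        if self.activity_intensity_mets < 1.0:
            raise ValueError("activity_intensity_mets must be >= 1")
        if self.program_cost_npv < 0:
            raise ValueError("program_cost_npv must be >= 0")


def default_scenarios() -> dict[str, ScenarioConfig]:
    """The four packaged policy scenarios.

    - no_pe: no school offers PE.
    - pe_observed: currently observed practice — one 40-min class/week in
      primary, two 40-min classes/week in secondary, with boys active 32%
      and girls 26% of class time.
    - pe_guidelines: international guidelines — 120 min/wk (primary) and
      180 min/wk (secondary) of PE, students active 50% of class.
    - pe_guidelines_spillover: guidelines plus a social-norm spillover that
      raises after-school participation in weeks with PE attendance.
    """
    return {
        "no_pe": ScenarioConfig(name="no_pe", pe_offered=False),
        "pe_observed": ScenarioConfig(
            name="pe_observed", pe_offered=True,
            primary_sessions_per_week=1, primary_session_minutes=40.0,
            secondary_sessions_per_week=2, secondary_session_minutes=40.0,
            fraction_active_male=0.32, fraction_active_female=0.26,
            program_cost_npv=50_333_172.0,
        ),
        "pe_guidelines": ScenarioConfig(
            name="pe_guidelines", pe_offered=True,
            primary_sessions_per_week=3, primary_session_minutes=40.0,
            secondary_sessions_per_week=3, secondary_session_minutes=60.0,
            fraction_active_male=0.50, fraction_active_female=0.50,
            program_cost_npv=50_333_172.0,
        ),
        "pe_guidelines_spillover": ScenarioConfig(
            name="pe_guidelines_spillover", pe_offered=True,
            primary_sessions_per_week=3, primary_session_minutes=40.0,
            secondary_sessions_per_week=3, secondary_session_minutes=60.0,
            fraction_active_male=0.50, fraction_active_female=0.50,
            spillover_enabled=True, spillover_uplift=1.5,
            program_cost_npv=50_333_172.0,
        ),
    }


@dataclass
class SimConfig:
    """Root configuration object."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    metabolism: MetabolicConfig = field(default_factory=MetabolicConfig)
    calendar: CalendarConfig = field(default_factory=CalendarConfig)
    econ: EconConfig = field(default_factory=EconConfig)
    adult: AdultConfig = field(default_factory=AdultConfig)
    scenarios: dict[str, ScenarioConfig] = field(default_factory=default_scenarios)
    years: int = 5
    #: five-year no-PE prevalence the intake calibration targets
    calibration_target_prevalence: float = 0.3065
    calibration_tolerance: float = 0.0025
    #: calibrated global intake surplus (kcal/day); persisted after calibration
    intake_surplus_kcal: float | None = None

    # ---------------------------------------------------------- serialization
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        pop = d.pop("population", {})
        if "districts" in pop:
            pop["districts"] = [DistrictConfig(**x) for x in pop["districts"]]
        if "bodyfat_coeffs" in pop:
            pop["bodyfat_coeffs"] = tuple(pop["bodyfat_coeffs"])
        scen = {k: ScenarioConfig(**v) for k, v in d.pop("scenarios", {}).items()}
        kw: dict[str, Any] = {}
        for name, sub in [("behavior", BehaviorConfig), ("metabolism", MetabolicConfig),
                          ("calendar", CalendarConfig), ("econ", EconConfig),
                          ("adult", AdultConfig)]:
            if name in d:
                v = d.pop(name)
                for key, val in list(v.items()):
                    if isinstance(val, list):
                        v[key] = tuple(val)
                kw[name] = sub(**v)
        cfg = cls(population=PopulationConfig(**pop), scenarios=scen or default_scenarios(),
                  **kw, **d)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
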