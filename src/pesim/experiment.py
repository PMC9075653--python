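"""End-to-end experiment orchestration:
generate -> calibrate -> simulate youth -> adult life-course -> CEA.

A master seed fans out to per-stage child seeds through a documented
splitting rule (``numpy.random.SeedSequence([master, stage_tag])``), so
every stage is independently reproducible. Paired scenario runs share the
youth-stage seed, which aligns the after-school random draws between the
baseline and intervention arms (a common-random-numbers design).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adult, econ
from .config import SimConfig
from .population import Population, calibrate_intake, generate_population
from .reference import GrowthReference, load_life_table
from .youth import YouthResult, run_youth_simulation

STAGE_TAGS = {"generate": 11, "calibrate": 22, "youth": 33, "adult": 44}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    return int(np.random.SeedSequence([int(master_seed), STAGE_TAGS[stage]])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentSpec:
    baseline: str = "no_pe"
    intervention: str = "pe_guidelines"
    n_agents: int = 20_000
    years: int = 5
    cost_grid: tuple[float, ...] = (42_032_248.0, 46_182_710.0, 50_333_172.0)
    trials: int = 200
    master_seed: int = 1
    run_adult: bool = True

    def __post_init__(self) -> None:
        if self.baseline == self.intervention:
            raise ValueError("baseline and intervention scenarios must differ")
        if self.n_agents < 1:
            raise ValueError("cohort size must be >= 1")


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    population: Population
    calibration: object
    youth: dict[str, YouthResult]
    prevalence_reduction_pp: float
    prevalence_reduction_by_sex: tuple[float, float]
    ledgers: dict[str, econ.LedgerRow] | None
    cea_by_cost: dict[float, econ.CEAResult] | None
    outcome_totals: dict[str, pd.DataFrame] | None
    provenance: dict = field(default_factory=dict)


def _entry_categories(res: YouthResult, ref: GrowthReference) -> np.ndarray:
    """Adult BMI category at the age-18 hand-off.

    Agents who crossed 18 in-simulation use their recorded BMI-z at the
    crossing; younger agents carry their end-of-horizon z forward along the
    reference to age 18 (z-preserving projection), then adult cutoffs
    25/30 kg/m^2 apply.
    """
    z = np.where(np.isnan(res.z_at_18), res.final["bmi_z"], res.z_at_18)
    bmi18 = ref.bmi_for_z(z, np.full_like(z, 18.0), res.final["male"])
    return adult.adult_bmi_category(bmi18)


def run_experiment(spec: ExperimentSpec, config: SimConfig | None = None,
                   ref: GrowthReference | None = None) -> ExperimentResult:
    """Run the full pipeline for a (baseline, intervention) scenario pair."""
    config = config or SimConfig()
    config.population.n_agents = spec.n_agents
    config.years = spec.years
    ref = ref or GrowthReference.packaged()

    base_sc = config.scenarios[spec.baseline]
    int_sc = config.scenarios[spec.intervention]

    pop = generate_population(config, stage_seed(spec.master_seed, "generate"), ref)
    calib = calibrate_intake(pop, config, base_sc,
                             config.calibration_target_prevalence,
                             config.calibration_tolerance,
                             stage_seed(spec.master_seed, "calibrate"))

    yseed = stage_seed(spec.master_seed, "youth")
    youth_runs = {
        spec.baseline: run_youth_simulation(pop, base_sc, config, yseed, ref=ref),
        spec.intervention: run_youth_simulation(pop, int_sc, config, yseed, ref=ref),
    }
    rb, ri = youth_runs[spec.baseline], youth_runs[spec.intervention]
    red = (rb.final_prevalence - ri.final_prevalence) * 100.0
    red_m = (rb.prevalence_by_sex()[0] - ri.prevalence_by_sex()[0]) * 100.0
    red_f = (rb.prevalence_by_sex()[1] - ri.prevalence_by_sex()[1]) * 100.0

    ledgers = cea_by_cost = totals = None
    if spec.run_adult:
        model = adult.load_transition_model(config.econ)
        adult.validate_transition_model(model).raise_if_failed()
        aseed = stage_seed(spec.master_seed, "adult")
        life = load_life_table()
        ledgers, totals = {}, {}
        for name, yres in youth_runs.items():
            cats = _entry_categories(yres, ref)
            male = yres.final["male"]
            offs = np.clip(18.0 - (yres.final["age"] - spec.years), 0.0, None)
            lc = adult.run_lifecourse(cats, male, model, config.adult, config.econ,
                                      trials=spec.trials, seed=aseed,
                                      entry_year_offset=offs, life_table=life)
            ledgers[name] = lc.mean_ledger()
            totals[name] = adult.cohort_outcome_totals(lc, len(pop))
        cea_by_cost = {}
        for cost in spec.cost_grid:
            b = ledgers[spec.baseline]
            i = econ.LedgerRow(dalys=ledgers[spec.intervention].dalys,
                               direct_medical=ledgers[spec.intervention].direct_medical,
                               productivity=ledgers[spec.intervention].productivity,
                               program_cost=float(cost))
            cea_by_cost[float(cost)] = econ.cea_from_ledgers(b, i, config.econ)

    prov = {
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "master_seed": spec.master_seed,
        "stage_seeds": {s: stage_seed(spec.master_seed, s) for s in STAGE_TAGS},
        "n_agents": spec.n_agents, "years": spec.years,
        "calibrated_surplus_kcal": config.intake_surplus_kcal,
    }
    return ExperimentResult(spec=spec, population=pop, calibration=calib,
                            youth=youth_runs, prevalence_reduction_pp=red,
                            prevalence_reduction_by_sex=(red_m, red_f),
                            ledgers=ledgers, cea_by_cost=cea_by_cost,
                            outcome_totals=totals, provenance=prov)


# --------------------------------------------------------------------- reports
TABLE_COLUMNS = ["scenario", "health_outcomes", "deaths", "dalys",
                 "cost_of_pe_classes", "direct_medical_costs",
                 "productivity_losses", "total_societal_costs"]


def report_tables(result: ExperimentResult | None,
                  cost_point: float | None = None) -> dict[str, pd.DataFrame]:
    """Summary-table and cost-sweep outputs.

    The scenario table mirrors the published column set (outcomes, deaths,
    DALYs, program cost, direct medical, productivity, societal total; the
    societal column is the row identity direct + productivity + program).
    An empty/None bundle yields header-only frames.
    """
    if result is None or result.ledgers is None:
        return {"scenario_table": pd.DataFrame(columns=TABLE_COLUMNS),
                "cost_sweep": pd.DataFrame(columns=[
                    "program_cost", "net_societal_savings", "net_direct_savings",
                    "icer_third_party", "icer_societal"])}
    cost = cost_point if cost_point is not None else max(result.spec.cost_grid)
    rows = []
    for name, led in result.ledgers.items():
        tot = result.outcome_totals[name]
        program = 0.0 if name == result.spec.baseline else float(cost)
        rows.append({
            "scenario": name,
            "health_outcomes": float(tot["cases"].sum()),
            "deaths": float(tot["deaths"].sum()),
            "dalys": led.dalys,
            "cost_of_pe_classes": program,
            "direct_medical_costs": led.direct_medical,
            "productivity_losses": led.productivity,
            "total_societal_costs": led.direct_medical + led.productivity + program,
        })
    sweep = []
    for c, cea in sorted(result.cea_by_cost.items()):
        sweep.append({
            "program_cost": c,
            "net_societal_savings": cea.net_societal_savings,
            "net_direct_savings": cea.net_direct_savings,
            "icer_third_party": cea.icer_third_party.value,
            "icer_societal": cea.icer_societal.value,
        })
    return {"scenario_table": pd.DataFrame(rows, columns=TABLE_COLUMNS),
            "cost_sweep": pd.DataFrame(sweep)}


def save_bundle(result: ExperimentResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = report_tables(result)
    tables["scenario_table"].to_csv(outdir / "scenario_table.csv", index=False)
    tables["cost_sweep"].to_csv(outdir / "cost_sweep.csv", index=False)
    for name, yres in result.youth.items():
        yres.yearly.to_csv(outdir / f"prevalence_{name}.csv", index=False)
    (outdir / "provenance.json").write_text(json.dumps(result.provenance, indent=2))
    summary = {
        "prevalence_reduction_pp": result.prevalence_reduction_pp,
        "prevalence_reduction_male_pp": result.prevalence_reduction_by_sex[0],
        "prevalence_reduction_female_pp": result.prevalence_reduction_by_sex[1],
        "calibrated_surplus_kcal": result.provenance["calibrated_surplus_kcal"],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
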