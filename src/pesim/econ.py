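"""Cost-effectiveness layer: discounting, currency conversion, DALYs,
dominance-resolved accrual, ICERs, and budget thresholds.

Perspectives follow standard convention: the third-party payer counts
direct medical costs only; the societal perspective adds productivity
losses (annual income attenuated by the disability weight, accrued to
every living person-year with a condition) and the program cost.

ICER = (Cost_PE - Cost_noPE) / (DALYs_noPE - DALYs_PE); an intervention is
cost-effective when ICER <= the willingness-to-pay threshold (GDP per
capita, default $8,597/DALY) and dominant (cost saving) when it both saves
costs and averts DALYs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EconConfig


# ----------------------------------------------------------------- discounting
def discount_npv(amount, years_from_reference, rate: float):
    """Net present value: amount / (1+rate)^years."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return np.asarray(amount, float) / (1.0 + rate) ** np.asarray(years_from_reference, float)


def discount_factor(years_from_reference, rate: float):
    return 1.0 / (1.0 + rate) ** np.asarray(years_from_reference, float)


# ------------------------------------------------------------------ conversion
def convert_cost_us_to_mx(us_cost: float, params: EconConfig,
                          year_index: str = "first",
                          condition_class: str = "other",
                          us_first_to_subsequent_ratio: float | None = None) -> float:
    """US treatment cost -> Mexico cost via the OECD comparative price-level
    ratio. For cancer/ESRD subsequent years, the Mexican subsequent-year
    cost is the Mexican first-year cost divided by the US first:subsequent
    ratio (the first-year ratio rule).
    """
    if params.oecd_price_ratio <= 0:
        raise ValueError("price ratio must be positive")
    if year_index not in ("first", "subsequent"):
        raise ValueError("year_index must be 'first' or 'subsequent'")
    mx = us_cost * params.oecd_price_ratio
    if year_index == "subsequent" and condition_class in ("cancer", "esrd"):
        if us_first_to_subsequent_ratio is None or us_first_to_subsequent_ratio <= 0:
            raise ValueError("cancer/ESRD subsequent-year conversion needs a "
                             "positive US first:subsequent cost ratio")
        # here `us_cost` is the US *first-year* cost; scale the Mexican
        # first-year cost down by the US ratio
        mx = mx / us_first_to_subsequent_ratio
    return mx


# ----------------------------------------------------------------------- DALYs
def compute_yld(incident_cases: float, disability_weight: float,
                avg_duration_years: float) -> float:
    """Years lived with disability = cases x weight x duration."""
    if incident_cases < 0 or avg_duration_years < 0:
        raise ValueError("cases and duration must be >= 0")
    if not 0.0 <= disability_weight <= 1.0:
        raise ValueError("disability weight must be in [0,1]")
    return incident_cases * disability_weight * avg_duration_years


def compute_yll(deaths: float, life_expectancy_at_death: float) -> float:
    """Years of life lost = deaths x remaining life expectancy at death."""
    if deaths < 0 or life_expectancy_at_death < 0:
        raise ValueError("inputs must be >= 0")
    return deaths * life_expectancy_at_death


def remaining_life_expectancy(age_at_death: float, life_table: pd.DataFrame) -> float:
    ages = life_table["age"].to_numpy(float)
    if age_at_death < ages.min() or age_at_death > ages.max():
        raise ValueError(f"age {age_at_death} outside the life table range "
                         f"[{ages.min():.0f}, {ages.max():.0f}]")
    return float(np.interp(age_at_death, ages, life_table["remaining_life_expectancy"].to_numpy(float)))


# -------------------------------------------------------------------- accrual
@dataclass(frozen=True)
class ActiveCondition:
    condition: str
    annual_cost: float
    disability_weight: float


def accrue_person_year(events: list[ActiveCondition],
                       annual_income: float) -> tuple[float, float, float]:
    """One person-year's (direct cost, disability weight, productivity loss).

    Dominance rule: when several conditions are active in a year, only the
    one with the highest cost (its cost AND its weight) is accrued — never
    the sum. Productivity loss = annual income x accrued disability weight.
    """
    if not events:
        return 0.0, 0.0, 0.0
    top = max(events, key=lambda ev: (ev.annual_cost, ev.disability_weight))
    return top.annual_cost, top.disability_weight, annual_income * top.disability_weight


# --------------------------------------------------------------------- ledgers
@dataclass
class CostLedger:
    """Per-perspective discounted (NPV) cost accumulators, USD."""

    direct_medical: float = 0.0
    productivity: float = 0.0
    program_cost: float = 0.0

    @property
    def third_party_total(self) -> float:
        return self.direct_medical + self.program_cost

    @property
    def societal_total(self) -> float:
        return self.direct_medical + self.productivity + self.program_cost


@dataclass
class ICERResult:
    value: float | None           # USD per DALY averted (None when undefined)
    delta_cost: float
    delta_daly: float
    dominant: bool                # cost saving with positive health effect
    cost_effective: bool
    undefined: bool = False


def compute_icer(cost_pe: float, cost_no_pe: float, daly_pe: float,
                 daly_no_pe: float, wtp: float | None = None) -> ICERResult:
    """Incremental cost per DALY averted between two scenarios."""
    delta_cost = cost_pe - cost_no_pe
    delta_daly = daly_no_pe - daly_pe
    if delta_daly == 0.0:
        return ICERResult(None, delta_cost, 0.0, False, False, undefined=True)
    icer = delta_cost / delta_daly
    dominant = delta_cost < 0 and delta_daly > 0
    ce = dominant or (wtp is not None and delta_daly > 0 and icer <= wtp)
    return ICERResult(icer, delta_cost, delta_daly, dominant, ce)


def budget_thresholds(savings: float, delta_daly: float, wtp: float) -> tuple[float, float]:
    """Maximum program cost that stays (cost saving, cost-effective).

    Cost saving up to the gross savings; cost-effective up to
    savings + WTP x DALYs averted.
    """
    if delta_daly <= 0:
        raise ValueError("thresholds undefined when no DALYs are averted")
    return savings, savings + wtp * delta_daly


# ------------------------------------------------------------- printed ledgers
@dataclass
class LedgerRow:
    """One scenario's aggregate discounted ledger (Table-style inputs)."""

    dalys: float
    direct_medical: float
    productivity: float
    program_cost: float = 0.0

    @property
    def societal_total(self) -> float:
        return self.direct_medical + self.productivity + self.program_cost


@dataclass
class CEAResult:
    delta_daly: float
    icer_third_party: ICERResult
    icer_societal: ICERResult
    direct_savings: float
    productivity_savings: float
    net_direct_savings: float        # after program cost
    net_societal_savings: float
    max_cost_cost_saving: dict = field(default_factory=dict)
    max_cost_cost_effective: dict = field(default_factory=dict)


def cea_from_ledgers(baseline: LedgerRow, intervention: LedgerRow,
                     params: EconConfig) -> CEAResult:
    """Full CEA from two aggregate ledgers (the pure-arithmetic path).

    Works identically whether the rows come from the simulation or from a
    published results table.
    """
    wtp = params.wtp_per_daly
    delta_daly = baseline.dalys - intervention.dalys
    direct_savings = baseline.direct_medical - intervention.direct_medical
    productivity_savings = baseline.productivity - intervention.productivity
    program = intervention.program_cost - baseline.program_cost

    tpp = compute_icer(intervention.direct_medical + intervention.program_cost,
                       baseline.direct_medical + baseline.program_cost,
                       intervention.dalys, baseline.dalys, wtp)
    soc = compute_icer(intervention.societal_total, baseline.societal_total,
                       intervention.dalys, baseline.dalys, wtp)

    saving_tp = ce_tp = saving_soc = ce_soc = math.nan
    if delta_daly > 0:
        saving_tp, ce_tp = budget_thresholds(direct_savings, delta_daly, wtp)
        saving_soc, ce_soc = budget_thresholds(direct_savings + productivity_savings,
                                               delta_daly, wtp)
    return CEAResult(
        delta_daly=delta_daly, icer_third_party=tpp, icer_societal=soc,
        direct_savings=direct_savings, productivity_savings=productivity_savings,
        net_direct_savings=direct_savings - program,
        net_societal_savings=direct_savings + productivity_savings - program,
        max_cost_cost_saving={"third_party": saving_tp, "societal": saving_soc},
        max_cost_cost_effective={"third_party": ce_tp, "societal": ce_soc},
    )
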