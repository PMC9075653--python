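"""Energy balance and body composition.

A two-compartment (fat / fat-free) model: each day's energy imbalance E
(kcal) is partitioned between compartments with a Forbes-type fraction

    p = C / (C + fat_mass),   dFFM = p * E / rho_lean,   dFM = (1-p) * E / rho_fat,

so lean tissue dominates deposition when fat stores are small and fat
dominates when they are large. Maintenance expenditure is a Schofield-type
age/sex band regression on weight, scaled by a physical-activity level (PAL)
that excludes the explicitly modelled activity. Defaults (rho_fat 9500,
rho_lean 1800 kcal/kg, C = 10.4 kg) are standard literature values and are
implementation defaults, not a claim about any particular prior model.
"""
from __future__ import annotations

import numpy as np

from .config import MetabolicConfig
from .reference import GrowthReference

# Schofield BMR coefficients (kcal/day): bands keyed by (male, age_lo, age_hi)
SCHOFIELD = [
    (True, 3.0, 10.0, 22.706, 504.3),
    (True, 10.0, 18.0, 17.686, 658.2),
    (True, 18.0, 200.0, 15.057, 692.2),
    (False, 3.0, 10.0, 20.315, 485.9),
    (False, 10.0, 18.0, 13.384, 692.6),
    (False, 18.0, 200.0, 14.818, 486.6),
]


def bmr(weight_kg, age_years, male):
    """Schofield basal metabolic rate (kcal/day), vectorized."""
    weight_kg = np.asarray(weight_kg, float)
    age_years = np.asarray(age_years, float)
    male = np.asarray(male, bool)
    w, a, m = np.broadcast_arrays(weight_kg, age_years, male)
    if np.any(w <= 0):
        raise ValueError("weight must be positive")
    out = np.zeros(w.shape, float)
    for is_male, lo, hi, slope, icept in SCHOFIELD:
        sel = (m == is_male) & (a >= lo) & (a < hi)
        out[sel] = slope * w[sel] + icept
    return out


def maintenance_expenditure(weight_kg, age_years, male, params: MetabolicConfig):
    """Daily maintenance (non-exercise) expenditure: PAL x BMR, kcal/day."""
    return params.pal * bmr(weight_kg, age_years, male)


def partition_fraction(fat_mass_kg, params: MetabolicConfig):
    """Forbes partition fraction p = C/(C + FM): share of E going to lean."""
    fm = np.asarray(fat_mass_kg, float)
    return params.partition_constant / (params.partition_constant + np.maximum(fm, 0.0))


def energy_density(fat_mass_kg, params: MetabolicConfig):
    """Effective kcal per kg of total tissue at the current composition."""
    p = partition_fraction(fat_mass_kg, params)
    return 1.0 / (p / params.rho_lean + (1.0 - p) / params.rho_fat)


def update_body_composition(fat_mass_kg, fat_free_mass_kg, energy_balance_kcal,
                            params: MetabolicConfig):
    """Apply one day's energy balance; returns (fat, ffm, clamped_mask).

    A deficit that would drive fat mass below the configured floor is
    clamped there (diagnostic mask returned); lean mass is never reduced
    below 1 kg.
    """
    fm = np.asarray(fat_mass_kg, float)
    ffm = np.asarray(fat_free_mass_kg, float)
    e = np.asarray(energy_balance_kcal, float)
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite energy balance")
    p = partition_fraction(fm, params)
    new_fm = fm + (1.0 - p) * e / params.rho_fat
    new_ffm = ffm + p * e / params.rho_lean
    clamped = new_fm < params.fat_floor_kg
    new_fm = np.maximum(new_fm, params.fat_floor_kg)
    new_ffm = np.maximum(new_ffm, 1.0)
    return new_fm, new_ffm, clamped


def grow(age_years, height_cm, elapsed_years, male, ref: GrowthReference):
    """Advance age and height along the reference velocity table.

    Height gain uses the velocity at the midpoint of the elapsed interval
    and is held at zero beyond the table's upper age bound.
    """
    if np.any(np.asarray(elapsed_years) <= 0):
        raise ValueError("elapsed_years must be positive")
    age = np.asarray(age_years, float)
    v = ref.height_velocity(age + np.asarray(elapsed_years) / 2.0, male)
    return age + elapsed_years, np.asarray(height_cm, float) + v * elapsed_years
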