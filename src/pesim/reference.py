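"""Growth reference: BMI-for-age z-scores (LMS form) and height-for-age.

The packaged tables are smooth synthetic approximations of an international
school-age growth reference (see the ``synthetic_`` filename prefix); any
LMS-format table with the same columns can be substituted via the loader.

Classification convention: overweight z > +1, obesity z > +2, combined
overweight+obesity = fraction with z > +1.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

OVERWEIGHT_Z = 1.0
OBESITY_Z = 2.0


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pesim").joinpath("data", name)))


class GrowthReference:
    """Interpolating wrapper over an LMS BMI table and a height table."""

    def __init__(self, lms: pd.DataFrame, heights: pd.DataFrame):
        self._tab: dict[bool, dict[str, np.ndarray]] = {}
        for male, sex in ((True, "male"), (False, "female")):
            sub = lms[lms["sex"] == sex].sort_values("age_years")
            h = heights[heights["sex"] == sex].sort_values("age_years")
            self._tab[male] = {
                "age": sub["age_years"].to_numpy(float),
                "L": sub["L"].to_numpy(float),
                "M": sub["M"].to_numpy(float),
                "S": sub["S"].to_numpy(float),
                "h_age": h["age_years"].to_numpy(float),
                "h_med": h["median_cm"].to_numpy(float),
                "h_sd": h["sd_cm"].to_numpy(float),
            }
        self.age_min = float(self._tab[True]["age"][0])
        self.age_max = float(self._tab[True]["age"][-1])

    @classmethod
    def packaged(cls) -> "GrowthReference":
        return cls(pd.read_csv(_data_path("synthetic_bmi_lms.csv")),
                   pd.read_csv(_data_path("synthetic_height_reference.csv")))

    # -------------------------------------------------------------- internals
    def _lms(self, age, male):
        age = np.clip(np.asarray(age, float), self.age_min, self.age_max)
        male = np.broadcast_to(np.asarray(male, bool), age.shape)
        L = np.empty_like(age)
        M = np.empty_like(age)
        S = np.empty_like(age)
        for flag in (True, False):
            m = male == flag
            if m.any():
                t = self._tab[flag]
                L[m] = np.interp(age[m], t["age"], t["L"])
                M[m] = np.interp(age[m], t["age"], t["M"])
                S[m] = np.interp(age[m], t["age"], t["S"])
        return L, M, S

    # ------------------------------------------------------------------- BMI
    def bmi_z(self, bmi, age, male):
        """BMI-for-age z-score, z = ((BMI/M)^L - 1) / (L*S)."""
        bmi = np.asarray(bmi, float)
        L, M, S = self._lms(age, male)
        return (np.power(bmi / M, L) - 1.0) / (L * S)

    def bmi_for_z(self, z, age, male):
        """Inverse transform: the BMI at a given z-score."""
        z = np.asarray(z, float)
        L, M, S = self._lms(age, male)
        base = np.maximum(1.0 + L * S * z, 1e-6)
        return M * np.power(base, 1.0 / L)

    def classify(self, bmi, age, male):
        """Return (overweight_or_obese, obese) boolean arrays."""
        z = self.bmi_z(bmi, age, male)
        return z > OVERWEIGHT_Z, z > OBESITY_Z

    # ---------------------------------------------------------------- height
    def median_height(self, age, male):
        age = np.clip(np.asarray(age, float), self.age_min, self.age_max)
        male = np.broadcast_to(np.asarray(male, bool), age.shape)
        out = np.empty_like(age)
        for flag in (True, False):
            m = male == flag
            if m.any():
                t = self._tab[flag]
                out[m] = np.interp(age[m], t["h_age"], t["h_med"])
        return out

    def height_sd(self, age, male):
        age = np.clip(np.asarray(age, float), self.age_min, self.age_max)
        male = np.broadcast_to(np.asarray(male, bool), age.shape)
        out = np.empty_like(age)
        for flag in (True, False):
            m = male == flag
            if m.any():
                t = self._tab[flag]
                out[m] = np.interp(age[m], t["h_age"], t["h_sd"])
        return out

    def height_velocity(self, age, male):
        """Reference growth velocity (cm/yr); zero beyond the table range."""
        age = np.asarray(age, float)
        v = (self.median_height(age + 0.5, male) - self.median_height(np.maximum(age - 0.5, self.age_min), male)) \
            / (np.clip(age + 0.5, self.age_min, self.age_max) - np.clip(age - 0.5, self.age_min, self.age_max) + 1e-12)
        return np.where(age >= self.age_max, 0.0, v)


def load_life_table(path: str | Path | None = None) -> pd.DataFrame:
    """Remaining-life-expectancy table (synthetic fixture by default)."""
    p = Path(path) if path is not None else _data_path("synthetic_life_table.csv")
    df = pd.read_csv(p)
    if not {"age", "remaining_life_expectancy"} <= set(df.columns):
        raise ValueError("life table needs columns age, remaining_life_expectancy")
    return df
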