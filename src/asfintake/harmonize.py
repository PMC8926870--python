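"""Survey harmonisation: energy adjustment, serving conversion, validation.

Dietary surveys report mean intakes on incompatible footings (different
total-energy levels, different units).  Harmonisation rescales every
reported mean to an age-specific reference energy and converts grams to
standardised servings for reporting.  ``validate_surveys`` runs basic
extraction-error and plausibility checks before modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .strata import age_band_midpoint

#: The seven animal-source foods handled by this package.
FOODS: tuple[str, ...] = (
    "unprocessed_red_meat", "processed_meat", "seafood", "eggs",
    "milk", "cheese", "yoghurt",
)

#: Standardised grams per serving.
SERVING_GRAMS: dict[str, float] = {
    "unprocessed_red_meat": 100.0,
    "processed_meat": 50.0,
    "seafood": 100.0,
    "eggs": 55.0,
    "cheese": 42.0,
    "yoghurt": 245.0,
    "milk": 245.0,
}

# Age-specific reference energies (kcal/day): the band containing the
# stratum's midpoint age decides the reference.
_ENERGY_SCHEDULE: tuple[tuple[float, float], ...] = (
    (1.0, 700.0),      # <1 year
    (2.0, 1000.0),     # 1 to <2
    (6.0, 1300.0),     # 2-5
    (11.0, 1700.0),    # 6-10
    (75.0, 2000.0),    # 11-74
    (math.inf, 1700.0),  # >=75
)

#: Plausibility caps (g/day) per food: ten times the largest regional mean
#: intake reported in global surveillance; values above these are flagged.
PLAUSIBILITY_CAP_G_DAY: dict[str, float] = {
    "unprocessed_red_meat": 1140.0,
    "processed_meat": 540.0,
    "seafood": 440.0,
    "eggs": 350.0,
    "milk": 1850.0,
    "cheese": 340.0,
    "yoghurt": 840.0,
}

REQUIRED_SURVEY_COLUMNS = (
    "survey_id", "country", "year", "food", "age_group", "sex", "education",
    "urbanicity", "mean_g_day", "sd_g_day", "n", "method", "representativeness",
)


@dataclass(frozen=True)
class EnergyRef:
    """Mapping from age band to reference energy (kcal/day)."""

    schedule: tuple[tuple[float, float], ...] = _ENERGY_SCHEDULE

    def __call__(self, age_group: str) -> float:
        mid = age_band_midpoint(age_group)
        for upper, kcal in self.schedule:
            if mid < upper:
                return kcal
        raise ValueError(f"no energy reference for age band {age_group!r}")


DEFAULT_ENERGY_REF = EnergyRef()


def reference_energy(age_group: str) -> float:
    """Reference energy (kcal/day) for an age band."""
    return DEFAULT_ENERGY_REF(age_group)


def energy_adjust(mean_g_day: float, energy_kcal_day: float | None,
                  age_group: str, ref: EnergyRef = DEFAULT_ENERGY_REF) -> float:
    """Rescale a reported mean to the age band's reference energy.

    ``adjusted = mean * ref(age) / energy``.  A missing reported energy
    (``None`` or NaN) leaves the mean unchanged; callers that need to track
    this use :func:`energy_adjust_table`, which records a flag column.
    """
    if energy_kcal_day is None or (isinstance(energy_kcal_day, float)
                                   and math.isnan(energy_kcal_day)):
        return float(mean_g_day)
    if energy_kcal_day <= 0:
        raise ValueError(f"energy_kcal_day must be positive, got {energy_kcal_day}")
    return float(mean_g_day) * ref(age_group) / float(energy_kcal_day)


def energy_adjust_table(surveys: pd.DataFrame,
                        ref: EnergyRef = DEFAULT_ENERGY_REF) -> pd.DataFrame:
    """Energy-adjust ``mean_g_day`` and ``sd_g_day`` for every row.

    Returns a copy with adjusted values and a boolean ``energy_adjusted``
    column (False where the reported energy was missing).
    """
    out = surveys.copy()
    energy = out.get("energy_kcal_day", pd.Series(np.nan, index=out.index))
    energy = pd.to_numeric(energy, errors="coerce")
    if (energy <= 0).any():
        bad = out.index[energy <= 0][0]
        raise ValueError(f"non-positive energy_kcal_day at row {bad}")
    refs = out["age_group"].map(ref)
    factor = (refs / energy).where(energy.notna(), 1.0)
    out["mean_g_day"] = out["mean_g_day"] * factor
    out["sd_g_day"] = out["sd_g_day"] * factor
    out["energy_adjusted"] = energy.notna()
    return out


def grams_to_servings(g_per_day: float, food: str, period: str = "day") -> float:
    """Convert grams/day into standardised servings per day or week."""
    if food not in SERVING_GRAMS:
        raise ValueError(f"unknown food {food!r}; expected one of {FOODS}")
    per_day = float(g_per_day) / SERVING_GRAMS[food]
    if period == "day":
        return per_day
    if period == "week":
        return 7.0 * per_day
    raise ValueError(f"period must be 'day' or 'week', got {period!r}")


def servings_to_grams(servings: float, food: str, period: str = "day") -> float:
    """Inverse of :func:`grams_to_servings`."""
    if food not in SERVING_GRAMS:
        raise ValueError(f"unknown food {food!r}; expected one of {FOODS}")
    grams = float(servings) * SERVING_GRAMS[food]
    return grams / 7.0 if period == "week" else grams


@dataclass(frozen=True)
class Issue:
    """One validation finding, tied to a row and a named rule."""

    row: int | None
    rule: str
    severity: str  # "error" | "warning"
    message: str

    def to_dict(self) -> dict:
        return {"row": self.row, "rule": self.rule,
                "severity": self.severity, "message": self.message}


def validate_surveys(surveys: pd.DataFrame) -> list[Issue]:
    """Basic extraction-error and plausibility screening.

    Errors: negative mean or SD, n < 1, non-positive energy.  Warnings:
    SD exactly zero with n > 1, and means above the food-specific
    plausibility cap.  Pure function: repeated calls on the same table
    return identical lists.
    """
    missing = [c for c in REQUIRED_SURVEY_COLUMNS if c not in surveys.columns]
    if missing:
        raise KeyError(f"surveys table missing required column(s): {missing}")

    issues: list[Issue] = []
    mean = pd.to_numeric(surveys["mean_g_day"], errors="coerce")
    sd = pd.to_numeric(surveys["sd_g_day"], errors="coerce")
    n = pd.to_numeric(surveys["n"], errors="coerce")
    energy = pd.to_numeric(
        surveys.get("energy_kcal_day", pd.Series(np.nan, index=surveys.index)),
        errors="coerce")

    for idx in surveys.index:
        if mean[idx] < 0:
            issues.append(Issue(idx, "mean_non_negative", "error",
                                f"mean_g_day={mean[idx]} is negative"))
        if sd[idx] < 0:
            issues.append(Issue(idx, "sd_non_negative", "error",
                                f"sd_g_day={sd[idx]} is negative"))
        if not np.isnan(n[idx]) and n[idx] < 1:
            issues.append(Issue(idx, "n_at_least_one", "error",
                                f"n={n[idx]} is below 1"))
        if not np.isnan(energy[idx]) and energy[idx] <= 0:
            issues.append(Issue(idx, "energy_positive", "error",
                                f"energy_kcal_day={energy[idx]} is not positive"))
        if sd[idx] == 0 and n[idx] > 1:
            issues.append(Issue(idx, "sd_zero_with_replication", "warning",
                                f"sd_g_day=0 with n={n[idx]}"))
        food = surveys.at[idx, "food"]
        cap = PLAUSIBILITY_CAP_G_DAY.get(food)
        if cap is not None and mean[idx] > cap:
            issues.append(Issue(idx, "implausible_mean", "warning",
                                f"mean_g_day={mean[idx]} exceeds the "
                                f"{food} plausibility cap of {cap} g/day"))
    return issues
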