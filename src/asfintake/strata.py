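"""Joint demographic stratification of a national population.

Every estimate in this package is resolved to a *stratum*: one cell of the
Cartesian product age band x sex x education level x urbanicity.  The full
surveillance grid uses 22 age bands, 2 sexes, 3 education levels and 2
urbanicity levels — 264 strata per country-year.  A compact 6-age-band grid
is provided for desk-scale simulation studies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

#: The 22 age bands of the full surveillance grid, in ascending order.
AGE_BANDS_FULL: tuple[str, ...] = (
    "<1", "1-2", "3-4", "5-9", "10-14", "15-19",
    "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80-84", "85-89", "90-94", "95+",
)

#: Compact age bands used by the scaled-down simulation world.
AGE_BANDS_COMPACT: tuple[str, ...] = (
    "1-2", "10-14", "25-29", "40-44", "60-64", "75-79",
)

SEXES: tuple[str, ...] = ("female", "male")
EDUCATION_LEVELS: tuple[str, ...] = ("low", "medium", "high")
URBANICITY_LEVELS: tuple[str, ...] = ("rural", "urban")

#: Marker values used when a survey does not stratify a dimension.
COLLAPSED = {"age_group": "all", "sex": "both", "education": "all",
             "urbanicity": "both"}

STRATUM_COLUMNS = ("age_group", "sex", "education", "urbanicity")


@dataclass(frozen=True, order=True)
class StratumKey:
    """One joint demographic cell."""

    age_group: str
    sex: str
    education: str
    urbanicity: str


def age_band_midpoint(band: str) -> float:
    """Midpoint age (years) of a band; used for energy references and
    child/adult classification.  ``<1`` -> 0.5, ``95+`` -> 97.5,
    ``all`` (collapsed) -> 40."""
    if band == "all":
        return 40.0
    if band.startswith("<"):
        return float(band[1:]) / 2.0
    if band.endswith("+"):
        return float(band[:-1]) + 2.5
    lo, hi = band.split("-")
    return (float(lo) + float(hi) + 1.0) / 2.0  # band "20-24" covers [20, 25)


def is_child(band: str) -> bool:
    """Children are younger than 20 years; bands never straddle 20."""
    return age_band_midpoint(band) < 20.0


def strata_grid(
    age_bands: Sequence[str] = AGE_BANDS_FULL,
    sexes: Sequence[str] = SEXES,
    education_levels: Sequence[str] = EDUCATION_LEVELS,
    urbanicity_levels: Sequence[str] = URBANICITY_LEVELS,
) -> list[StratumKey]:
    """Full Cartesian product of the category lists, age slowest.

    Raises
    ------
    ValueError
        If any category list is empty or contains duplicates.
    """
    for name, cats in (("age_bands", age_bands), ("sexes", sexes),
                       ("education_levels", education_levels),
                       ("urbanicity_levels", urbanicity_levels)):
        if len(cats) == 0:
            raise ValueError(f"{name} must be non-empty")
        if len(set(cats)) != len(cats):
            raise ValueError(f"duplicate categories in {name}: {list(cats)}")
    return [
        StratumKey(a, s, e, u)
        for a, s, e, u in itertools.product(
            age_bands, sexes, education_levels, urbanicity_levels)
    ]


class StrataGrid:
    """An ordered stratification grid with fast key lookup."""

    def __init__(self, age_bands: Sequence[str] = AGE_BANDS_FULL,
                 sexes: Sequence[str] = SEXES,
                 education_levels: Sequence[str] = EDUCATION_LEVELS,
                 urbanicity_levels: Sequence[str] = URBANICITY_LEVELS):
        self.age_bands = tuple(age_bands)
        self.sexes = tuple(sexes)
        self.education_levels = tuple(education_levels)
        self.urbanicity_levels = tuple(urbanicity_levels)
        self.strata = strata_grid(self.age_bands, self.sexes,
                                  self.education_levels,
                                  self.urbanicity_levels)
        self._index = {k: i for i, k in enumerate(self.strata)}

    @classmethod
    def full(cls) -> "StrataGrid":
        """The 264-stratum surveillance grid."""
        return cls()

    @classmethod
    def compact(cls) -> "StrataGrid":
        """A 72-stratum grid (6 age bands) for desk-scale runs."""
        return cls(age_bands=AGE_BANDS_COMPACT)

    def __len__(self) -> int:
        return len(self.strata)

    def __iter__(self) -> Iterable[StratumKey]:
        return iter(self.strata)

    def index_of(self, key: StratumKey) -> int:
        return self._index[key]

    def to_frame(self) -> pd.DataFrame:
        """One row per stratum, columns ``age_group, sex, education,
        urbanicity``, in grid order."""
        return pd.DataFrame(
            [(k.age_group, k.sex, k.education, k.urbanicity)
             for k in self.strata],
            columns=list(STRATUM_COLUMNS),
        )
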