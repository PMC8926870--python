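"""Synthetic dietary-surveillance worlds with known ground truth.

Real multi-country survey inventories are assembled from hundreds of
heterogeneous, mostly non-public surveys.  This module generates the same
*structure* — surveys nested in countries nested in regions, jointly
stratified demographics, assessment-method bias, non-representative and
incompletely stratified surveys, secular trends over 1990-2018 — from a
latent intake surface that is retained, so that every downstream stage
(harmonisation, hierarchical modelling, aggregation, cross-validation) can
be scored against truth.

Latent intakes are built multiplicatively on the log scale: intakes are
non-negative and right-skewed, and the fitting module models them on the
same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .harmonize import FOODS, reference_energy
from .strata import COLLAPSED, StrataGrid, StratumKey, age_band_midpoint

YEAR_CENTER = 2004  # midpoint of 1990-2018; slopes are per year about this


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


#: Default global mean intakes (g/day) per food, matching the order of
#: magnitude seen in global dietary surveillance.
DEFAULT_GLOBAL_MEANS: dict[str, float] = {
    "unprocessed_red_meat": 51.0,
    "processed_meat": 17.0,
    "seafood": 28.0,
    "eggs": 21.0,
    "milk": 88.0,
    "cheese": 8.0,
    "yoghurt": 20.0,
}

#: Synthetic assessment-method bias multipliers (24HR is the reference).
#: Fixed truths for recovery tests, not empirical estimates.
DEFAULT_METHOD_BIAS: dict[str, float] = {
    "24HR": 1.0, "FFQ": 1.15, "ShortQ": 0.9, "HBS": 1.1,
}

METHODS = ("24HR", "FFQ", "ShortQ", "HBS")
REPRESENTATIVENESS = ("national", "subnational", "community")


@dataclass
class WorldConfig:
    """Effect sizes, noise levels and demographics of a synthetic world."""

    n_regions: int = 3
    countries_per_region: int = 4
    years: tuple[int, int] = (1990, 2018)
    foods: tuple[str, ...] = FOODS
    grid: StrataGrid = field(default_factory=StrataGrid.compact)

    # effect sizes (multiplicative; SDs on the log scale)
    global_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GLOBAL_MEANS))
    region_sd: float = 0.25
    country_sd: float = 0.30
    age_amplitude: float = 0.5
    sex_effect: float = 1.1          # male vs female
    education_effects: tuple[float, float, float] = (1.0, 1.1, 1.25)
    urban_effect: float = 1.2        # urban vs rural
    slope_mean: float = 0.01         # mean log-scale trend per year
    slope_sd: float = 0.012
    slope_rho: float = 0.6           # corr(country intercept, country slope)

    # noise
    survey_cv: float = 0.25          # within-stratum coefficient of variation
    nonrep_extra_sd: float = 0.10    # extra log-scale noise for surveys
                                     # that are non-representative or
                                     # incompletely stratified
    energy_noise_sd: float = 0.05    # log-scale spread of reported energy
    method_bias: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METHOD_BIAS))
    availability_noise_sd: float = 0.05
    availability_scale_mean: float = 1.3   # availability exceeds intake
    availability_scale_sd: float = 0.10

    # population marginals
    male_share: float = 0.5
    education_shares: tuple[float, float, float] = (0.35, 0.40, 0.25)
    urban_share: float | tuple[float, float] = 0.55  # scalar or (1990, 2018) ramp
    age_decay: float = 0.02          # exp(-decay * midpoint age) age pyramid
    pop_log_mean: float = 16.0       # log persons; exp(16) ~ 8.9 million
    pop_log_sd: float = 1.0
    pop_growth: float = 0.01

    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if self.countries_per_region < 1:
            raise ConfigError("countries_per_region must be >= 1")
        if self.years[1] < self.years[0]:
            raise ConfigError("years range is empty")
        if not self.foods:
            raise ConfigError("foods must be non-empty")
        for sd_name in ("region_sd", "country_sd", "slope_sd", "survey_cv",
                        "nonrep_extra_sd", "energy_noise_sd",
                        "availability_noise_sd", "availability_scale_sd"):
            if getattr(self, sd_name) < 0:
                raise ConfigError(f"{sd_name} must be >= 0")
        for eff_name in ("sex_effect", "urban_effect"):
            if getattr(self, eff_name) <= 0:
                raise ConfigError(f"{eff_name} must be > 0")
        if any(e <= 0 for e in self.education_effects):
            raise ConfigError("education_effects must all be > 0")
        if any(self.global_means.get(f, 0) <= 0 for f in self.foods):
            raise ConfigError("global_means must be > 0 for every food")
        if any(b <= 0 for b in self.method_bias.values()):
            raise ConfigError("method_bias multipliers must be > 0")
        if abs(self.slope_rho) > 1:
            raise ConfigError("slope_rho must satisfy |rho| <= 1")
        if not 0 <= self.male_share <= 1:
            raise ConfigError("male_share must lie in [0, 1]")
        if any(not 0 <= s <= 1 for s in self.education_shares) or \
                abs(sum(self.education_shares) - 1) > 1e-9:
            raise ConfigError("education_shares must lie in [0, 1] and sum to 1")
        us = self.urban_share
        shares = us if isinstance(us, tuple) else (us,)
        if any(not 0 <= s <= 1 for s in shares):
            raise ConfigError("urban_share must lie in [0, 1]")

    @classmethod
    def full_scale(cls, **overrides) -> "WorldConfig":
        """Full-scale world: 7 regions and the 264-stratum grid."""
        kw = dict(n_regions=7, countries_per_region=5,
                  grid=StrataGrid.full())
        kw.update(overrides)
        return cls(**kw)

    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)


# ---------------------------------------------------------------------------
# population marginals

def _urban_share_at(config: WorldConfig, year: int) -> float:
    us = config.urban_share
    if isinstance(us, tuple):
        y0, y1 = config.years
        f = 0.0 if y1 == y0 else (year - y0) / (y1 - y0)
        return us[0] + f * (us[1] - us[0])
    return float(us)


def marginal_shares(config: WorldConfig, year: int) -> dict[str, dict[str, float]]:
    """Per-dimension category shares used for population weights and for
    collapsing incompletely stratified survey rows."""
    mids = np.array([age_band_midpoint(b) for b in config.grid.age_bands])
    age_w = np.exp(-config.age_decay * mids)
    age_w = age_w / age_w.sum()
    urban = _urban_share_at(config, year)
    lo, med, hi = config.education_shares
    return {
        "age_group": dict(zip(config.grid.age_bands, age_w)),
        "sex": {"female": 1.0 - config.male_share, "male": config.male_share},
        "education": {"low": lo, "medium": med, "high": hi},
        "urbanicity": {"rural": 1.0 - urban, "urban": urban},
    }


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class TrueWorld:
    """Latent intake surface plus the components that built it.

    ``log mean = log global + region RE + country RE + age + sex + education
    + urbanicity + slope * (year - 2004)``, all per food except the
    demographic curves, which are shared across foods.
    """

    config: WorldConfig
    regions: tuple[str, ...]
    countries: tuple[str, ...]
    country_region: dict[str, str]
    region_effects: dict[tuple[str, str], float]      # (food, region)
    country_effects: dict[tuple[str, str], float]     # (food, country)
    country_slopes: dict[tuple[str, str], float]      # (food, country), /year
    age_effects: dict[str, float]
    sex_effects: dict[str, float]
    education_log_effects: dict[str, float]
    urban_log_effects: dict[str, float]

    def log_mean(self, country: str, year: int, key: StratumKey,
                 food: str) -> float:
        if country not in self.country_region:
            raise KeyError(f"unknown country {country!r}")
        region = self.country_region[country]
        return (np.log(self.config.global_means[food])
                + self.region_effects[(food, region)]
                + self.country_effects[(food, country)]
                + self.age_effects[key.age_group]
                + self.sex_effects[key.sex]
                + self.education_log_effects[key.education]
                + self.urban_log_effects[key.urbanicity]
                + self.country_slopes[(food, country)] * (year - YEAR_CENTER))

    def stratum_means(self, country: str, year: int, food: str,
                      grid: StrataGrid | None = None) -> np.ndarray:
        """True mean intake (g/day) for every stratum of the grid, in order."""
        grid = grid or self.config.grid
        return np.array([np.exp(self.log_mean(country, year, k, food))
                         for k in grid])

    def truth_frame(self, countries: Sequence[str] | None = None,
                    years: Sequence[int] | None = None,
                    foods: Sequence[str] | None = None) -> pd.DataFrame:
        """Long table of true means for the requested subset."""
        countries = countries or self.countries
        years = years if years is not None else list(self.config.year_range())
        foods = foods or self.config.foods
        grid = self.config.grid
        rows = []
        for food in foods:
            for c in countries:
                for y in years:
                    means = self.stratum_means(c, y, food)
                    for k, m in zip(grid, means):
                        rows.append((c, self.country_region[c], y, food,
                                     k.age_group, k.sex, k.education,
                                     k.urbanicity, m))
        return pd.DataFrame(rows, columns=[
            "country", "region", "year", "food", "age_group", "sex",
            "education", "urbanicity", "true_mean_g_day"])

    def country_mean(self, country: str, year: int, food: str) -> float:
        """Population-weighted true national mean (uses the configured
        demographic marginals as weights)."""
        shares = marginal_shares(self.config, year)
        grid = self.config.grid
        w = np.array([shares["age_group"][k.age_group]
                      * shares["sex"][k.sex]
                      * shares["education"][k.education]
                      * shares["urbanicity"][k.urbanicity] for k in grid])
        return float(w @ self.stratum_means(country, year, food))


def generate_true_intakes(config: WorldConfig) -> TrueWorld:
    """Draw one latent world.  Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = tuple(f"R{i+1}" for i in range(config.n_regions))
    countries, country_region = [], {}
    for r in regions:
        for j in range(config.countries_per_region):
            c = f"{r}C{j+1}"
            countries.append(c)
            country_region[c] = r

    region_effects, country_effects, country_slopes = {}, {}, {}
    for food in config.foods:
        for r in regions:
            region_effects[(food, r)] = rng.normal(0.0, config.region_sd)
        # country intercept RE and slope drawn jointly with correlation rho
        # (built from standard normals so zero-variance configs stay valid)
        rho = config.slope_rho
        e1 = rng.standard_normal(len(countries))
        e2 = rng.standard_normal(len(countries))
        u = config.country_sd * e1
        phi = config.slope_mean + config.slope_sd * (
            rho * e1 + np.sqrt(1.0 - rho ** 2) * e2)
        for c, ui, pi in zip(countries, u, phi):
            country_effects[(food, c)] = float(ui)
            country_slopes[(food, c)] = float(pi)

    mids = np.array([age_band_midpoint(b) for b in config.grid.age_bands])
    raw = np.minimum(mids, 25.0) / 25.0   # rise through childhood, plateau
    raw = config.age_amplitude * (raw - raw.mean())
    age_effects = dict(zip(config.grid.age_bands, raw))

    e_lo, e_med, e_hi = config.education_effects
    return TrueWorld(
        config=config,
        regions=regions,
        countries=tuple(countries),
        country_region=country_region,
        region_effects=region_effects,
        country_effects=country_effects,
        country_slopes=country_slopes,
        age_effects=age_effects,
        sex_effects={"female": 0.0, "male": float(np.log(config.sex_effect))},
        education_log_effects={"low": float(np.log(e_lo)),
                               "medium": float(np.log(e_med)),
                               "high": float(np.log(e_hi))},
        urban_log_effects={"rural": 0.0,
                           "urban": float(np.log(config.urban_effect))},
    )


# ---------------------------------------------------------------------------
# survey simulation

@dataclass
class SurveySpec:
    """Design of one survey: where, when, how, and how completely."""

    country: str
    year: int
    method: str = "24HR"
    representativeness: str = "national"
    strat_age: bool = True
    strat_sex: bool = True
    strat_edu: bool = True
    strat_urban: bool = True
    n_per_stratum: int = 50

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}")
        if self.representativeness not in REPRESENTATIVENESS:
            raise ConfigError(
                f"representativeness must be one of {REPRESENTATIVENESS}")
        if self.n_per_stratum < 1:
            raise ConfigError("n_per_stratum must be >= 1")


@dataclass
class SurveyDesign:
    surveys: list[SurveySpec]

    @classmethod
    def default(cls, world: TrueWorld, surveys_per_country: int = 2,
                seed: int = 0) -> "SurveyDesign":
        """A realistic default inventory: every country gets one national
        fully stratified 24HR survey plus (surveys_per_country - 1) surveys
        of mixed method, representativeness and stratification completeness,
        spread over the modelled years."""
        rng = np.random.default_rng(seed)
        y0, y1 = world.config.years
        specs = []
        for c in world.countries:
            for i in range(surveys_per_country):
                year = int(rng.integers(y0, y1 + 1))
                if i == 0:
                    specs.append(SurveySpec(c, year))
                else:
                    specs.append(SurveySpec(
                        c, year,
                        method=str(rng.choice(
                            ["24HR", "FFQ", "ShortQ"], p=[0.5, 0.3, 0.2])),
                        representativeness=str(rng.choice(
                            ["national", "subnational"], p=[0.6, 0.4])),
                        strat_edu=bool(rng.random() > 0.2),
                        strat_urban=bool(rng.random() > 0.2),
                    ))
        return cls(specs)


def _collapse_groups(grid: StrataGrid, spec: SurveySpec):
    """Map each grid stratum to the (possibly collapsed) reported cell."""
    def reported(k: StratumKey) -> StratumKey:
        return StratumKey(
            k.age_group if spec.strat_age else COLLAPSED["age_group"],
            k.sex if spec.strat_sex else COLLAPSED["sex"],
            k.education if spec.strat_edu else COLLAPSED["education"],
            k.urbanicity if spec.strat_urban else COLLAPSED["urbanicity"],
        )
    groups: dict[StratumKey, list[StratumKey]] = {}
    for k in grid:
        groups.setdefault(reported(k), []).append(k)
    return groups


def simulate_surveys(world: TrueWorld, design: SurveyDesign,
                     seed: int = 0) -> pd.DataFrame:
    """Observe the latent world through the survey designs.

    Observed stratum mean = (population-weighted true mean over the covered
    grid cells) x method bias x energy ratio x lognormal sampling noise with
    log-scale SD ``sqrt(cv^2 / n + extra^2)``, where the extra term applies
    to surveys that are non-representative or incompletely stratified.  The
    reported SD is ``cv x observed mean`` so that the implied standard error
    matches the generating noise.
    """
    config = world.config
    for spec in design.surveys:
        if spec.country not in world.country_region:
            raise KeyError(f"survey design references unknown country "
                           f"{spec.country!r}")
    rng = np.random.default_rng(seed)
    bias = config.method_bias
    rows = []
    for s_idx, spec in enumerate(design.surveys):
        survey_id = f"S{s_idx:04d}"
        groups = _collapse_groups(config.grid, spec)
        shares = marginal_shares(config, spec.year)
        fully_strat = (spec.strat_age and spec.strat_sex and spec.strat_edu
                       and spec.strat_urban)
        extra = 0.0
        if spec.representativeness != "national" or not fully_strat:
            extra = config.nonrep_extra_sd
        metric = "household" if spec.method == "HBS" else "individual"
        for food in config.foods:
            true = {k: np.exp(world.log_mean(spec.country, spec.year, k, food))
                    for k in config.grid}
            for cell, members in groups.items():
                w = np.array([shares["age_group"][k.age_group]
                              * shares["sex"][k.sex]
                              * shares["education"][k.education]
                              * shares["urbanicity"][k.urbanicity]
                              for k in members])
                w = w / w.sum()
                cell_true = float(w @ np.array([true[k] for k in members]))
                n_cell = spec.n_per_stratum * len(members)
                se_log = np.sqrt(config.survey_cv ** 2 / n_cell + extra ** 2)
                noise = np.exp(rng.normal(0.0, se_log)) if se_log > 0 else 1.0
                ref = reference_energy(cell.age_group)
                if config.energy_noise_sd > 0:
                    energy = ref * np.exp(rng.normal(0.0, config.energy_noise_sd))
                else:
                    energy = ref
                observed = cell_true * bias[spec.method] * noise * (energy / ref)
                rows.append((
                    survey_id, spec.country,
                    world.country_region[spec.country], spec.year, food,
                    cell.age_group, cell.sex, cell.education, cell.urbanicity,
                    observed, config.survey_cv * observed, n_cell, energy,
                    spec.method, spec.representativeness, metric,
                    spec.strat_age, spec.strat_sex, spec.strat_edu,
                    spec.strat_urban,
                ))
    return pd.DataFrame(rows, columns=[
        "survey_id", "country", "region", "year", "food", "age_group", "sex",
        "education", "urbanicity", "mean_g_day", "sd_g_day", "n",
        "energy_kcal_day", "method", "representativeness", "metric",
        "strat_age", "strat_sex", "strat_edu", "strat_urban"])


# ---------------------------------------------------------------------------
# availability and population

def simulate_availability(world: TrueWorld, noise_sd: float | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """National food-availability series (g/day-equivalent per capita).

    Availability tracks the population-weighted true national mean, scaled
    by a country-specific supply factor (losses, waste, non-food uses make
    availability a biased proxy for intake) with lognormal year-to-year
    noise.
    """
    config = world.config
    if noise_sd is None:
        noise_sd = config.availability_noise_sd
    if noise_sd < 0:
        raise ConfigError("availability noise_sd must be >= 0")
    years = list(config.year_range())
    if len(years) < 2:
        raise ConfigError("availability needs >= 2 years")
    rng = np.random.default_rng(seed)
    rows = []
    for food in config.foods:
        for c in world.countries:
            scale = config.availability_scale_mean * np.exp(
                rng.normal(0.0, config.availability_scale_sd))
            for y in years:
                base = world.country_mean(c, y, food)
                noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
                rows.append((c, y, food, base * scale * noise))
    return pd.DataFrame(rows, columns=["country", "year", "food",
                                       "availability_g_day"])


def simulate_population(config: WorldConfig, seed: int | None = None
                        ) -> pd.DataFrame:
    """Country-year-stratum population counts.

    Stratum proportions are products of the configured marginals (so they
    sum to one per country-year by construction); country totals are
    lognormal with geometric growth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    regions = [f"R{i+1}" for i in range(config.n_regions)]
    countries = [f"{r}C{j+1}" for r in regions
                 for j in range(config.countries_per_region)]
    totals = {c: np.exp(rng.normal(config.pop_log_mean, config.pop_log_sd))
              for c in countries}
    grid = config.grid
    rows = []
    for y in config.year_range():
        shares = marginal_shares(config, y)
        props = np.array([shares["age_group"][k.age_group]
                          * shares["sex"][k.sex]
                          * shares["education"][k.education]
                          * shares["urbanicity"][k.urbanicity]
                          for k in grid])
        growth = (1.0 + config.pop_growth) ** (y - config.years[0])
        for c in countries:
            total = totals[c] * growth
            for k, p in zip(grid, props):
                rows.append((c, y, k.age_group, k.sex, k.education,
                             k.urbanicity, total * p))
    return pd.DataFrame(rows, columns=["country", "year", "age_group", "sex",
                                       "education", "urbanicity", "population"])


# ---------------------------------------------------------------------------
# CSV round trips (seed recorded as a header comment)

def write_table(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
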