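"""Population-weighted aggregation of posterior stratum draws.

All aggregation happens at the draw level: for each retained posterior
draw, stratum predictions are averaged with population weights; medians
and 95% uncertainty intervals are taken only afterwards.  This propagates
the full joint uncertainty and makes nested aggregates exactly consistent
(the global draw-level mean equals the population-weighted mean of the
regional draw-level means — which is *not* true of medians).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import SERVING_GRAMS, grams_to_servings
from .intake_model import StratumDraws
from .strata import STRATUM_COLUMNS
from .uncertainty import DiffResult, Estimate, difference_from_draws, \
    summarize_draws

__all__ = [
    "weighted_mean", "weighted_draw_means", "subgroup_difference",
    "time_change", "count_exceeding", "spearman_matrix", "ThresholdResult",
]


def _as_list(draws) -> list[StratumDraws]:
    return [draws] if isinstance(draws, StratumDraws) else list(draws)


def _weights_for(block: StratumDraws, population: pd.DataFrame) -> np.ndarray:
    """Population count per stratum row of ``block`` (matched on country,
    year where present, and the four stratum keys)."""
    pop = population
    if "country" in pop.columns:
        pop = pop[pop["country"] == block.country]
    if "year" in pop.columns and (pop["year"] == block.year).any():
        pop = pop[pop["year"] == block.year]
    lookup = pop.set_index(list(STRATUM_COLUMNS))["population"]
    idx = pd.MultiIndex.from_frame(block.strata[list(STRATUM_COLUMNS)])
    try:
        return lookup.reindex(idx).to_numpy(dtype=float)
    except Exception as exc:  # pragma: no cover
        raise ValueError("population table does not cover the draw strata") from exc


def _subset_mask(strata: pd.DataFrame, subset: Mapping | None) -> np.ndarray:
    mask = np.ones(len(strata), dtype=bool)
    if subset:
        for col, val in subset.items():
            allowed = val if isinstance(val, (list, tuple, set)) else {val}
            mask &= strata[col].isin(allowed).to_numpy()
    return mask


def weighted_draw_means(draws, population: pd.DataFrame,
                        subset: Mapping | None = None) -> np.ndarray:
    """Per-draw population-weighted mean over all strata in scope.

    ``draws`` is one :class:`StratumDraws` or a sequence of them (e.g. all
    countries of a region for a regional mean); weights are renormalised
    within the scope.  Raises on empty scope or zero total weight.
    """
    blocks = _as_list(draws)
    if not blocks:
        raise ValueError("no stratum draws supplied")
    n_draws = blocks[0].n_draws
    acc = np.zeros(n_draws)
    total_w = 0.0
    for block in blocks:
        if block.n_draws != n_draws:
            raise ValueError("draw counts differ across blocks")
        w = _weights_for(block, population)
        if np.isnan(w).any():
            missing = block.strata[np.isnan(w)].iloc[0].to_dict()
            raise ValueError(f"population weight missing for stratum {missing} "
                             f"of {block.country}/{block.year}")
        mask = _subset_mask(block.strata, subset)
        w = np.where(mask, w, 0.0)
        # sequential accumulation over strata: the summation order is
        # deterministic and reproducible by a scalar per-draw loop
        for i in range(len(w)):
            if w[i] != 0.0:
                acc += w[i] * block.values[i]
        total_w += float(np.sum(w))
    if total_w <= 0:
        raise ValueError("zero total population weight in the requested scope")
    return acc / total_w


def weighted_mean(draws, population: pd.DataFrame,
                  subset: Mapping | None = None,
                  min_draws: int = 100) -> Estimate:
    """Population-weighted aggregate estimate (median, 95% UI)."""
    return summarize_draws(
        weighted_draw_means(draws, population, subset), min_draws)


def subgroup_difference(draws, population: pd.DataFrame,
                        group_a: Mapping, group_b: Mapping,
                        food: str | None = None,
                        unit: str = "g/day",
                        min_draws: int = 100) -> DiffResult:
    """Draw-level difference between two disjoint stratum subsets (A - B),
    with B (the comparator: low education, rural, 1990, ...) as the
    relative denominator.

    For the education contrast pass ``{"education": "high"}`` versus
    ``{"education": "low"}`` — medium education never enters.  ``unit``
    may be ``servings/week`` or ``servings/day``, in which case ``food``
    selects the serving size (defaults to the draws' food).
    """
    blocks = _as_list(draws)
    mean_a = weighted_draw_means(blocks, population, group_a)
    mean_b = weighted_draw_means(blocks, population, group_b)
    if unit != "g/day":
        period = "week" if unit == "servings/week" else "day"
        food = food or blocks[0].food
        mean_a = np.array([grams_to_servings(v, food, period) for v in mean_a])
        mean_b = np.array([grams_to_servings(v, food, period) for v in mean_b])
    return difference_from_draws(mean_a, mean_b, unit=unit,
                                 min_draws=min_draws)


def time_change(draws_y0, draws_y1, population_2018: pd.DataFrame,
                food: str | None = None, unit: str = "g/day",
                min_draws: int = 100) -> DiffResult:
    """Change from year0 to year1, standardised to the 2018 population.

    Both years' draws are weighted with the *same* 2018 stratum
    proportions, so demographic change over time cannot masquerade as a
    consumption change.  The relative change uses the 2018-standardised
    year0 mean as denominator.
    """
    b0, b1 = _as_list(draws_y0), _as_list(draws_y1)
    if len(b0) != len(b1):
        raise ValueError("year0 and year1 draws cover different countries")
    for x, y in zip(b0, b1):
        if not x.strata[list(STRATUM_COLUMNS)].equals(
                y.strata[list(STRATUM_COLUMNS)]) or x.country != y.country:
            raise ValueError("stratum grids differ between the two years")
    pop = population_2018
    if "year" in pop.columns and (pop["year"] == 2018).any():
        pop = pop[pop["year"] == 2018]
    mean_y0 = weighted_draw_means(b0, pop)
    mean_y1 = weighted_draw_means(b1, pop)
    if unit != "g/day":
        period = "week" if unit == "servings/week" else "day"
        food = food or b0[0].food
        mean_y0 = np.array([grams_to_servings(v, food, period) for v in mean_y0])
        mean_y1 = np.array([grams_to_servings(v, food, period) for v in mean_y1])
    return difference_from_draws(mean_y1, mean_y0, unit=unit,
                                 min_draws=min_draws)


@dataclass(frozen=True)
class ThresholdResult:
    """Countries whose median national intake crosses a threshold."""

    count: int
    pct_countries: float
    population: float
    pct_population: float
    countries: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"count": self.count, "pct_countries": self.pct_countries,
                "population": self.population,
                "pct_population": self.pct_population,
                "countries": list(self.countries)}


def count_exceeding(national_estimates: pd.DataFrame,
                    foods: Sequence[str],
                    threshold: float,
                    populations: pd.DataFrame,
                    direction: str = ">=",
                    per: str = "day") -> ThresholdResult:
    """How many countries (and how much population) cross an intake bound.

    ``national_estimates`` needs columns ``country, food, median`` in g/day;
    multi-food thresholds (e.g. total red plus processed meat) sum the
    listed foods per country.  ``threshold`` is g/day or g/week according
    to ``per``.  Counting uses the posterior median point estimate.
    """
    if direction not in (">=", "<="):
        raise ValueError("direction must be '>=' or '<='")
    est = national_estimates[national_estimates["food"].isin(foods)]
    counts = est.groupby("country")["food"].nunique()
    incomplete = counts[counts < len(set(foods))]
    if len(incomplete):
        raise ValueError(
            f"countries missing required foods: {list(incomplete.index)}")
    totals = est.groupby("country")["median"].sum()
    limit = threshold / 7.0 if per == "week" else float(threshold)
    hit = totals >= limit if direction == ">=" else totals <= limit
    winners = tuple(sorted(totals.index[hit]))
    pop = populations.groupby("country")["population"].sum()
    pop = pop.reindex(totals.index)
    if pop.isna().any():
        raise ValueError("populations table does not cover all countries")
    world = float(pop.sum())
    share = float(pop[list(winners)].sum()) if winners else 0.0
    return ThresholdResult(
        count=int(hit.sum()),
        pct_countries=100.0 * float(hit.sum()) / len(totals),
        population=share,
        pct_population=100.0 * share / world if world > 0 else 0.0,
        countries=winners)


def spearman_matrix(national_means: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlations between national mean intakes of foods.

    Accepts a wide table (countries x foods) or a long table with columns
    ``country, food, median``.  Ties get average ranks; a constant food
    column yields NaN against every other food.
    """
    if {"country", "food"}.issubset(national_means.columns):
        value_col = "median" if "median" in national_means.columns else \
            national_means.columns.difference(["country", "food"])[0]
        wide = national_means.pivot(index="country", columns="food",
                                    values=value_col)
    else:
        wide = national_means
    if len(wide) < 3:
        raise ValueError("need at least 3 countries for rank correlations")
    foods = list(wide.columns)
    mat = pd.DataFrame(np.eye(len(foods)), index=foods, columns=foods)
    for i, fi in enumerate(foods):
        for j in range(i + 1, len(foods)):
            fj = foods[j]
            xi, xj = wide[fi].to_numpy(float), wide[fj].to_numpy(float)
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                r = np.nan
            else:
                r = stats.spearmanr(xi, xj).statistic
            mat.loc[fi, fj] = mat.loc[fj, fi] = r
    return mat
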