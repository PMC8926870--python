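import numpy as np
import pandas as pd
import pytest

from asfintake.aggregate import (ThresholdResult, count_exceeding,
                                 spearman_matrix, subgroup_difference,
                                 time_change, weighted_draw_means,
                                 weighted_mean)
from asfintake.harmonize import SERVING_GRAMS
from asfintake.intake_model import StratumDraws
from asfintake.strata import STRATUM_COLUMNS, StrataGrid


def _draws(values, country="A", year=2018, food="unprocessed_red_meat",
           strata=None):
    """StratumDraws from an (S, D) array, default strata from a tiny grid."""
    values = np.asarray(values, dtype=float)
    if strata is None:
        grid = StrataGrid(age_bands=["20-24"], sexes=["female", "male"],
                          education_levels=["low", "medium", "high"],
                          urbanicity_levels=["rural", "urban"])
        strata = grid.to_frame().iloc[: values.shape[0]].reset_index(drop=True)
    return StratumDraws(country=country, year=year, food=food,
                        strata=strata, values=values)


def _pop(strata, weights, country="A", year=2018):
    df = strata.copy()
    df.insert(0, "year", year)
    df.insert(0, "country", country)
    df["population"] = weights
    return df


class TestWeightedMean:
    def test_equal_weights_average_constant_strata(self):
        d = _draws(np.vstack([np.full(200, 10.0), np.full(200, 30.0)]))
        pop = _pop(d.strata, [0.5, 0.5])
        e = weighted_mean(d, pop)
        assert (e.median, e.lower95, e.upper95) == (20.0, 20.0, 20.0)

    def test_degenerate_weight_selects_single_stratum(self, rng):
        vals = rng.normal(10, 1, (2, 500))
        d = _draws(vals)
        e = weighted_mean(d, _pop(d.strata, [1.0, 0.0]))
        lo, med, hi = np.percentile(vals[0], [2.5, 50, 97.5])
        assert (e.median, e.lower95, e.upper95) == (med, lo, hi)

    def test_matches_brute_force_oracle_exactly(self, rng):
        """Draw-level aggregation then summarisation equals an explicit
        per-draw loop on a 5-strata x 4000-draw instance."""
        vals = rng.lognormal(3.0, 0.5, (5, 4000))
        w = rng.uniform(0.5, 2.0, 5)
        d = _draws(vals)
        got = weighted_draw_means(d, _pop(d.strata, w))
        total = float(np.sum(w))
        expected = np.empty(4000)
        for j in range(4000):       # explicit per-draw, per-stratum loop
            s = 0.0
            for i in range(5):
                s += w[i] * vals[i, j]
            expected[j] = s / total
        np.testing.assert_array_equal(got, expected)
        e = weighted_mean(d, _pop(d.strata, w))
        lo, med, hi = np.percentile(expected, [2.5, 50.0, 97.5])
        assert (e.median, e.lower95, e.upper95) == (med, lo, hi)

    def test_zero_total_weight_rejected(self):
        d = _draws(np.ones((2, 200)))
        with pytest.raises(ValueError, match="zero total"):
            weighted_mean(d, _pop(d.strata, [0.0, 0.0]))

    def test_global_equals_weighted_regions_at_draw_level_not_medians(
            self, rng):
        """Draw-level nesting is exact; averaging regional *medians* is not
        (skewed draws break it)."""
        vals_a = rng.lognormal(2.0, 1.2, (2, 2000))
        vals_b = rng.lognormal(3.0, 0.3, (2, 2000))
        da = _draws(vals_a, country="A")
        db = _draws(vals_b, country="B")
        pop = pd.concat([_pop(da.strata, [3.0, 1.0], country="A"),
                         _pop(db.strata, [1.0, 2.0], country="B")])
        global_draws = weighted_draw_means([da, db], pop)
        wa, wb = 4.0, 3.0
        per_region = (wa * weighted_draw_means(da, pop)
                      + wb * weighted_draw_means(db, pop)) / (wa + wb)
        np.testing.assert_allclose(global_draws, per_region, rtol=1e-12)
        med_global = np.median(global_draws)
        med_of_medians = (wa * np.median(weighted_draw_means(da, pop))
                          + wb * np.median(weighted_draw_means(db, pop))) \
            / (wa + wb)
        assert med_global != pytest.approx(med_of_medians, rel=1e-6)


class TestSubgroupDifference:
    def test_identical_groups_give_zero_nonsignificant(self, rng):
        d = _draws(rng.normal(10, 1, (12, 300)))
        pop = _pop(d.strata, np.ones(12))
        res = subgroup_difference(d, pop, {"education": "high"},
                                  {"education": "high"})
        assert res.absolute.median == 0.0
        assert not res.significant

    def test_constant_two_to_one_servings(self):
        vals = np.where(np.arange(12)[:, None] % 2 == 0, 2.0, 1.0)
        vals = np.repeat(vals, 200, axis=1)
        d = _draws(vals * SERVING_GRAMS["unprocessed_red_meat"] / 7.0)
        pop = _pop(d.strata, np.ones(12))
        res = subgroup_difference(
            d, pop, {"urbanicity": "rural"}, {"urbanicity": "urban"},
            unit="servings/week")
        assert res.absolute.median == pytest.approx(1.0)
        assert res.relative_pct.median == pytest.approx(100.0)

    def test_small_separation_with_tiny_noise_is_significant(self, rng):
        base = rng.normal(5.0, 0.01, (12, 500))
        d = _draws(base + np.where(np.arange(12) % 2 == 0, 0.5, 0.0)[:, None])
        pop = _pop(d.strata, np.ones(12))
        res = subgroup_difference(d, pop, {"urbanicity": "rural"},
                                  {"urbanicity": "urban"})
        assert res.significant
        assert res.absolute.median == pytest.approx(0.5, abs=0.05)

    def test_empty_group_rejected(self, rng):
        d = _draws(rng.normal(10, 1, (12, 300)))
        pop = _pop(d.strata, np.ones(12))
        with pytest.raises(ValueError):
            subgroup_difference(d, pop, {"education": "postdoc"},
                                {"education": "low"})


class TestTimeChange:
    def test_identical_years_give_zero(self, rng):
        vals = rng.normal(20, 2, (4, 300))
        d0 = _draws(vals[:, :], year=1990)
        d1 = _draws(vals[:, :], year=2018)
        pop = _pop(d0.strata, np.ones(4))
        res = time_change(d0, d1, pop)
        assert res.absolute.median == 0.0
        assert not res.significant

    def test_uniform_red_meat_shift_in_servings_per_week(self):
        d0 = _draws(np.full((4, 200), 50.0), year=1990)
        d1 = _draws(np.full((4, 200), 57.0), year=2018)
        pop = _pop(d0.strata, np.ones(4))
        res = time_change(d0, d1, pop, unit="servings/week")
        assert res.absolute.median == pytest.approx(0.49)  # 7 g * 7 / 100

    def test_only_2018_weights_are_used(self):
        """Counter-weight construction: per-stratum changes {+10, 0} with
        2018 shares {0.3, 0.7}; the 1990 shares {0.7, 0.3} must not enter."""
        d0 = _draws(np.vstack([np.full(200, 10.0), np.full(200, 10.0)]),
                    year=1990)
        d1 = _draws(np.vstack([np.full(200, 20.0), np.full(200, 10.0)]),
                    year=2018)
        pop_2018 = _pop(d0.strata, [0.3, 0.7], year=2018)
        pop_1990 = _pop(d0.strata, [0.7, 0.3], year=1990)
        res = time_change(d0, d1, pd.concat([pop_1990, pop_2018]))
        assert res.absolute.median == pytest.approx(3.0)

    def test_grid_mismatch_rejected(self):
        d0 = _draws(np.ones((2, 200)), year=1990)
        grid = StrataGrid(age_bands=["40-44"], sexes=["female", "male"],
                          education_levels=["low"],
                          urbanicity_levels=["rural"])
        d1 = _draws(np.ones((2, 200)), year=2018, strata=grid.to_frame())
        with pytest.raises(ValueError, match="grids differ"):
            time_change(d0, d1, _pop(d0.strata, [1, 1]))


class TestThresholds:
    @staticmethod
    def _estimates(intakes, food="unprocessed_red_meat"):
        return pd.DataFrame({"country": [f"C{i}" for i in range(len(intakes))],
                             "food": food, "median": intakes})

    @staticmethod
    def _pops(values):
        return pd.DataFrame({"country": [f"C{i}" for i in range(len(values))],
                             "population": values})

    def test_enumerated_example(self):
        res = count_exceeding(self._estimates([120.0, 90.0, 100.0]),
                              ["unprocessed_red_meat"], 100.0,
                              self._pops([10.0, 20.0, 30.0]))
        assert res.count == 2
        assert res.pct_countries == pytest.approx(66.7, abs=0.05)
        assert res.pct_population == pytest.approx(66.7, abs=0.05)

    def test_nobody_exceeds(self):
        res = count_exceeding(self._estimates([10.0, 20.0]),
                              ["unprocessed_red_meat"], 100.0,
                              self._pops([1.0, 1.0]))
        assert res.count == 0 and res.pct_population == 0.0

    def test_combined_red_and_processed_meat_weekly_bound(self):
        est = pd.concat([
            self._estimates([50.0], "unprocessed_red_meat"),
            self._estimates([20.0], "processed_meat")])
        res = count_exceeding(est, ["unprocessed_red_meat",
                                    "processed_meat"], 98.0,
                              self._pops([1.0]), direction="<=", per="week")
        # 70 g/day = 490 g/week, far above the 98 g/week bound
        assert res.count == 0

    def test_missing_food_rejected(self):
        est = self._estimates([50.0], "unprocessed_red_meat")
        with pytest.raises(ValueError, match="missing required foods"):
            count_exceeding(est, ["unprocessed_red_meat", "processed_meat"],
                            98.0, self._pops([1.0]))


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self):
        wide = pd.DataFrame({"a": [1.0, 2.0, 5.0, 9.0],
                             "b": [10.0, 40.0, 250.0, 810.0]})
        mat = spearman_matrix(wide)
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        wide = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [9.0, 5.0, 1.0]})
        assert spearman_matrix(wide).loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        wide = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [1, 3, 2, 5, 4]})
        assert spearman_matrix(wide).loc["a", "b"] == pytest.approx(0.8)

    def test_constant_column_reported_missing(self):
        wide = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        mat = spearman_matrix(wide)
        assert np.isnan(mat.loc["a", "b"])
        assert mat.loc["a", "a"] == 1.0

    def test_symmetry_and_bounds(self, rng):
        wide = pd.DataFrame(rng.normal(size=(8, 4)),
                            columns=list("abcd"))
        mat = spearman_matrix(wide)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
        assert (mat.abs().to_numpy() <= 1.0 + 1e-12).all()

    def test_too_few_countries_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman_matrix(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))
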