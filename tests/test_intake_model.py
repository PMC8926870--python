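import warnings

import numpy as np
import pandas as pd
import pytest

from asfintake.aggregate import weighted_mean
from asfintake.intake_model import (ExtrapolationError, IntakeModel,
                                    ModelConfig, _Design, _diagnostics,
                                    convergence_check, predict_strata,
                                    summarize_stratum)
from asfintake.harmonize import energy_adjust_table
from asfintake.strata import StrataGrid
from asfintake.synthetic import (SurveyDesign, SurveySpec, WorldConfig,
                                 generate_true_intakes, simulate_surveys)

FOOD = "unprocessed_red_meat"


def _noiseless_config(**kw):
    base = dict(foods=(FOOD,), survey_cv=0.0, nonrep_extra_sd=0.0,
                energy_noise_sd=0.0, seed=21)
    base.update(kw)
    return WorldConfig(**base)


def _quick_model(n_draws=300, warmup=150, seed=0, **kw):
    return ModelConfig(n_draws=n_draws, n_chains=2, warmup=warmup, seed=seed,
                       **kw)


class TestDegenerateRecovery:
    def test_single_noiseless_survey_recovers_observed_means(self):
        config = _noiseless_config(n_regions=1, countries_per_region=1)
        world = generate_true_intakes(config)
        design = SurveyDesign([SurveySpec(world.countries[0], 2005)])
        surveys = simulate_surveys(world, design, seed=0)
        model = IntakeModel(config=_quick_model()).fit(surveys)
        draws = model.predict_strata(world.countries[0], 2005)
        medians = np.median(draws.values, axis=1)
        observed = surveys.set_index(
            ["age_group", "sex", "education", "urbanicity"])["mean_g_day"]
        keys = list(zip(draws.strata.age_group, draws.strata.sex,
                        draws.strata.education, draws.strata.urbanicity))
        np.testing.assert_allclose(medians, observed.loc[keys].to_numpy(),
                                   rtol=0.05)

    def test_constant_world_predicts_equal_strata(self):
        config = _noiseless_config(
            n_regions=1, countries_per_region=1, region_sd=0.0,
            country_sd=0.0, age_amplitude=0.0, sex_effect=1.0,
            education_effects=(1.0, 1.0, 1.0), urban_effect=1.0,
            slope_mean=0.0, slope_sd=0.0, global_means={FOOD: 50.0})
        world = generate_true_intakes(config)
        surveys = simulate_surveys(
            world, SurveyDesign([SurveySpec(world.countries[0], 2005)]),
            seed=0)
        model = IntakeModel(config=_quick_model()).fit(surveys)
        draws = model.predict_strata(world.countries[0], 2005)
        medians = np.median(draws.values, axis=1)
        assert medians.std() / medians.mean() < 0.02


class TestBiasRecovery:
    def test_ffq_coefficient_recovers_known_bias(self):
        world = generate_true_intakes(WorldConfig(foods=(FOOD,), seed=13))
        specs = []
        for i, c in enumerate(world.countries):
            specs.append(SurveySpec(c, 2000 + i % 10))
            specs.append(SurveySpec(c, 1995 + i % 12, method="FFQ"))
        surveys = energy_adjust_table(
            simulate_surveys(world, SurveyDesign(specs), seed=13))
        model = IntakeModel(config=_quick_model(seed=5)).fit(surveys)
        gamma = model.posterior_.block_draws("method")[:, 0]  # FFQ column
        med, sd = np.median(gamma), gamma.std()
        assert abs(med - np.log(1.15)) < 2 * sd


class TestShrinkage:
    def test_zero_survey_country_shrinks_to_own_region(self):
        """A country without surveys is predicted nearer its own region's
        data-rich mean than any other region's, in >= 95% of replicates."""
        successes = 0
        n_reps = 20
        for rep in range(n_reps):
            config = WorldConfig(foods=(FOOD,), n_regions=3,
                                 countries_per_region=4, region_sd=0.6,
                                 country_sd=0.1, seed=500 + rep)
            world = generate_true_intakes(config)
            held_out = world.countries[0]
            design = SurveyDesign([SurveySpec(c, y) for c in world.countries
                                   if c != held_out for y in (1998, 2010)])
            surveys = energy_adjust_table(
                simulate_surveys(world, design, seed=600 + rep))
            model = IntakeModel(config=_quick_model(
                n_draws=200, warmup=120, seed=rep)).fit(surveys)
            pred = model.predict_strata(
                held_out, 2004, region=world.country_region[held_out])
            pred_mean = np.log(np.median(pred.values.mean(axis=0)))
            region_means = {}
            for region in world.regions:
                vals = [np.log(np.median(
                    model.predict_strata(c, 2004).values.mean(axis=0)))
                    for c in world.countries
                    if world.country_region[c] == region and c != held_out]
                region_means[region] = np.mean(vals)
            own = world.country_region[held_out]
            dist_own = abs(pred_mean - region_means[own])
            if all(dist_own <= abs(pred_mean - m)
                   for r, m in region_means.items() if r != own):
                successes += 1
        assert successes >= 0.95 * n_reps


class TestOverdispersion:
    def test_tau_larger_when_nonrepresentative_surveys_are_corrupted(self):
        """Posterior overdispersion fitted on data with noisy
        non-representative surveys exceeds the clean-data fit."""
        wins = 0
        n_reps = 8
        for rep in range(n_reps):
            base = dict(foods=(FOOD,), seed=700 + rep, energy_noise_sd=0.0)
            clean_cfg = WorldConfig(nonrep_extra_sd=0.0, **base)
            dirty_cfg = WorldConfig(nonrep_extra_sd=0.25, **base)
            specs = None
            taus = {}
            for label, cfg in (("clean", clean_cfg), ("dirty", dirty_cfg)):
                world = generate_true_intakes(cfg)
                if specs is None:
                    specs = [SurveySpec(c, 2000) for c in world.countries]
                    specs += [SurveySpec(c, 2008,
                                         representativeness="subnational")
                              for c in world.countries]
                surveys = simulate_surveys(world, SurveyDesign(specs),
                                           seed=800 + rep)
                model = IntakeModel(config=_quick_model(
                    n_draws=200, warmup=120, seed=rep)).fit(surveys)
                taus[label] = np.median(
                    model.posterior_.variance_draws("tau"))
            if taus["dirty"] > taus["clean"]:
                wins += 1
        assert wins >= 0.9 * n_reps


class TestPooling:
    def test_more_surveys_narrow_the_uncertainty_interval(self):
        widths = {}
        for n_surveys in (1, 3):
            config = WorldConfig(foods=(FOOD,), seed=31)
            world = generate_true_intakes(config)
            design = SurveyDesign([
                SurveySpec(c, 1995 + 5 * i) for c in world.countries
                for i in range(n_surveys)])
            surveys = energy_adjust_table(
                simulate_surveys(world, design, seed=32))
            model = IntakeModel(config=_quick_model(seed=2)).fit(surveys)
            country = world.countries[0]
            draws = model.predict_strata(country, 2005)
            lo, hi = np.percentile(draws.values, [2.5, 97.5], axis=1)
            widths[n_surveys] = np.mean(hi - lo)
        assert widths[3] < widths[1]


class TestPrediction:
    def test_full_grid_produces_264_strata(self):
        config = WorldConfig(foods=(FOOD,), n_regions=1,
                             countries_per_region=2, grid=StrataGrid.full(),
                             seed=17)
        world = generate_true_intakes(config)
        surveys = energy_adjust_table(simulate_surveys(
            world, SurveyDesign([SurveySpec(c, 2005)
                                 for c in world.countries]), seed=1))
        model = IntakeModel(config=_quick_model(n_draws=200, warmup=100)).fit(
            surveys)
        draws = model.predict_strata(world.countries[0], 2005)
        assert draws.values.shape[0] == 264
        assert (draws.values >= 0).all()

    def test_year_outside_range_requires_explicit_flag(self, fitted_model):
        with pytest.raises(ExtrapolationError):
            fitted_model.predict_strata("R1C1", 2050)
        draws = fitted_model.predict_strata("R1C1", 2050,
                                            allow_extrapolation=True)
        assert (draws.values >= 0).all()

    def test_unknown_country_without_region_rejected(self, fitted_model):
        with pytest.raises(KeyError, match="unknown country"):
            fitted_model.predict_strata("Atlantis", 2005)


class TestSummarizeStratum:
    def test_identical_values(self):
        e = summarize_stratum(np.full(4000, 3.0))
        assert (e.median, e.lower95, e.upper95) == (3.0, 3.0, 3.0)

    def test_requires_minimum_draws(self):
        with pytest.raises(ValueError):
            summarize_stratum(np.ones(50))


class TestConvergence:
    _DESIGN = _Design(["R1"], ["R1C1"], {"R1C1": "R1"}, ["20-24"])

    @classmethod
    def _fake_diagnostics(cls, beta_chains):
        var = {k: np.abs(beta_chains[..., 0]) + 0.1
               for k in ("sigma_region", "sigma_country", "sigma_slope",
                         "sigma_age", "tau")}
        return _diagnostics(beta_chains, var, cls._DESIGN)

    def test_well_mixed_chains_pass(self, rng):
        beta = rng.standard_normal((2, 500, self._DESIGN.p))
        diag = self._fake_diagnostics(beta)
        assert (diag["rhat"].dropna() < 1.05).all()

    def test_divergent_chains_flagged(self, rng):
        beta = rng.standard_normal((2, 500, self._DESIGN.p))
        beta[1] += 5.0
        diag = self._fake_diagnostics(beta)
        assert (diag["rhat"] > 1.1).any()

    def test_fitted_model_report(self, fitted_model):
        report = convergence_check(fitted_model.posterior_)
        assert {"param", "rhat", "ess", "flagged"} <= set(report.columns)
        assert not report["flagged"].fillna(False).all()


class TestEducationContrastStructure:
    def test_education_effects_sum_to_zero_in_every_draw(self, fitted_model):
        effects = fitted_model.posterior_.education_effect_draws()
        np.testing.assert_allclose(effects.sum(axis=1), 0.0, atol=1e-12)

    def test_variance_components_positive_in_every_draw(self, fitted_model):
        for name in ("sigma_region", "sigma_country", "sigma_slope",
                     "sigma_age", "tau"):
            assert (fitted_model.posterior_.variance_draws(name) > 0).all()


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("delta", 0.0), ("n_draws", 50), ("prior_tau", -1.0)])
    def test_invalid_model_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            ModelConfig(**{field: value})

    def test_sklearn_param_interface(self):
        m = IntakeModel()
        cfg = ModelConfig(n_draws=200)
        m.set_params(config=cfg, food=FOOD)
        assert m.get_params() == {"config": cfg, "food": FOOD}
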