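"""Simulation studies that score the estimation machinery against truth.

These studies define the package's validation protocol on the scaled-down
synthetic world (3 regions x 4 countries, 6 age bands, 2 surveys per
country, moderate noise): parameter recovery, uncertainty-interval
calibration, trend recovery, and cross-validated predictive validity.
Both the test suite and ``scripts/acceptance.py`` run them.
"""

from __future__ import annotations

import numpy as np

from ._sampling import derive_seed
from .aggregate import weighted_mean
from .crossval import cross_validate
from .harmonize import energy_adjust_table
from .intake_model import IntakeModel, ModelConfig
from .synthetic import (SurveyDesign, SurveySpec, WorldConfig,
                        generate_true_intakes, simulate_availability,
                        simulate_population, simulate_surveys)
from .trend_model import TrendConfig, fit_trend_model

FOOD = "unprocessed_red_meat"


def _scaled_world(seed: int, **config_overrides):
    config = WorldConfig(foods=(FOOD,), seed=derive_seed(seed, "world"),
                         **config_overrides)
    world = generate_true_intakes(config)
    design = SurveyDesign.default(world, surveys_per_country=2,
                                  seed=derive_seed(seed, "design"))
    surveys = energy_adjust_table(
        simulate_surveys(world, design, seed=derive_seed(seed, "surveys")))
    return world, surveys


def recovery_study(seed: int = 0, n_draws: int = 1000, warmup: int = 300,
                   year: int = 2005) -> dict:
    """Country-level population-weighted posterior medians versus truth.

    Returns the mean absolute relative error (percent) across countries of
    the scaled-down world.
    """
    world, surveys = _scaled_world(seed)
    population = simulate_population(world.config,
                                     seed=derive_seed(seed, "population"))
    pop_year = population[population["year"] == year]
    model = IntakeModel(config=ModelConfig(
        n_draws=n_draws, n_chains=2, warmup=warmup,
        seed=derive_seed(seed, "fit"))).fit(surveys)
    errors = []
    for country in world.countries:
        est = weighted_mean(model.predict_strata(country, year), pop_year)
        truth = world.country_mean(country, year, FOOD)
        errors.append(abs(est.median - truth) / truth)
    return {"mare_pct": 100.0 * float(np.mean(errors)),
            "n_countries": len(world.countries),
            "converged": model.converged_}


def calibration_study(seed: int = 0, n_reps: int = 20, n_draws: int = 400,
                      warmup: int = 200, year: int = 2005) -> dict:
    """Share of true stratum means covered by the 95% UI, pooled over
    replicate worlds."""
    hits = total = 0
    for rep in range(n_reps):
        world, surveys = _scaled_world(derive_seed(seed, f"rep{rep}"))
        model = IntakeModel(config=ModelConfig(
            n_draws=n_draws, n_chains=2, warmup=warmup,
            seed=derive_seed(seed, f"fit{rep}"))).fit(surveys)
        for country in world.countries:
            draws = model.predict_strata(country, year)
            truth = world.stratum_means(country, year, FOOD)
            lo, hi = np.percentile(draws.values, [2.5, 97.5], axis=1)
            hits += int(((truth >= lo) & (truth <= hi)).sum())
            total += len(truth)
    return {"coverage_pct": 100.0 * hits / total, "n_strata": total,
            "n_reps": n_reps}


def trend_recovery_study(seed: int = 0, n_draws: int = 1000,
                         warmup: int = 300) -> dict:
    """Varying-slopes model: recovery of a common log-linear availability
    slope (0.02/year) and of an intercept-slope correlation of 0.6 across
    50 countries."""
    tc = TrendConfig(n_draws=n_draws, n_chains=2, warmup=warmup,
                     seed=derive_seed(seed, "trendfit"))
    # common known slope, low noise
    slope_cfg = WorldConfig(
        foods=(FOOD,), n_regions=5, countries_per_region=10, region_sd=0.0,
        slope_mean=0.02, slope_sd=0.0, availability_noise_sd=0.02,
        seed=derive_seed(seed, "slopeworld"))
    world = generate_true_intakes(slope_cfg)
    avail = simulate_availability(world, seed=derive_seed(seed, "avail1"))
    post = fit_trend_model(avail, tc)
    slopes = [float(np.median(post.country_slope(c)))
              for c in post.countries]
    # correlated intercepts and slopes; the country supply-scale noise is
    # off so the availability intercepts carry exactly the configured
    # correlation with the slopes
    rho_cfg = WorldConfig(
        foods=(FOOD,), n_regions=5, countries_per_region=10, region_sd=0.0,
        slope_rho=0.6, availability_noise_sd=0.03,
        availability_scale_sd=0.0,
        seed=derive_seed(seed, "rhoworld"))
    world2 = generate_true_intakes(rho_cfg)
    avail2 = simulate_availability(world2, seed=derive_seed(seed, "avail2"))
    post2 = fit_trend_model(avail2, tc)
    return {"slope_true": 0.02,
            "slope_recovered": float(np.median(slopes)),
            "rho_true": 0.6,
            "rho_recovered": float(np.median(post2.rho)),
            "n_countries": len(post.countries)}


def cv_study(seed: int = 0, n_draws: int = 200, warmup: int = 120) -> dict:
    """Five-fold cross-validation on noiseless surveys and on surveys with
    outcomes permuted across rows (predictability destroyed)."""
    config = WorldConfig(foods=(FOOD,), survey_cv=0.0, nonrep_extra_sd=0.0,
                         energy_noise_sd=0.0, seed=derive_seed(seed, "cvw"))
    world = generate_true_intakes(config)
    # five survey years per country: survey-level holdout then always
    # leaves several anchors per country in training
    design = SurveyDesign([SurveySpec(c, y) for c in world.countries
                           for y in (1992, 1998, 2004, 2010, 2016)])
    surveys = energy_adjust_table(
        simulate_surveys(world, design, seed=derive_seed(seed, "cvs")))
    mc = ModelConfig(n_draws=n_draws, n_chains=2, warmup=warmup,
                     seed=derive_seed(seed, "cvfit"))
    clean = cross_validate(surveys, config=mc, k=5,
                           seed=derive_seed(seed, "cvfold"),
                           stratify="country")
    rng = np.random.default_rng(derive_seed(seed, "perm"))
    permuted = surveys.copy()
    permuted["mean_g_day"] = rng.permutation(
        permuted["mean_g_day"].to_numpy())
    null = cross_validate(permuted, config=mc, k=5,
                          seed=derive_seed(seed, "cvfold"),
                          stratify="country")
    return {"r2_noiseless": float(clean.pooled["r2"]),
            "r2_permuted": float(null.pooled["r2"]),
            "rmse_noiseless": float(clean.pooled["rmse"]),
            "n_surveys": len(clean.fold_assignment)}
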