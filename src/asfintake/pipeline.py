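"""End-to-end reproducible runs: simulate -> harmonise -> fit -> combine ->
aggregate -> cross-validate, driven by one YAML/JSON config.

Every stage derives its own seed from the global seed by stage-name
hashing, so re-running one stage keeps its random stream even when other
stages change.  Outputs are CSV/JSON plus a manifest recording the config
hash and seeds; a rerun with the same config reproduces every table
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import sys
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._sampling import derive_seed
from .aggregate import (count_exceeding, spearman_matrix, subgroup_difference,
                        time_change, weighted_mean)
from .crossval import cross_validate
from .harmonize import FOODS, energy_adjust_table, validate_surveys
from .intake_model import IntakeModel, ModelConfig, predict_strata
from .strata import StrataGrid, is_child
from .synthetic import (SurveyDesign, WorldConfig, generate_true_intakes,
                        read_table, simulate_availability, simulate_population,
                        simulate_surveys, write_table)
from .trend_model import TrendConfig, TrendModel, combine_posteriors

log = logging.getLogger("asfintake")
logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                    format="%(name)s: %(message)s")

ALL_STAGES = ("simulate", "harmonize", "fit", "trend", "aggregate",
              "crossval", "report")


def load_config(config_path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {config_path} did not parse to a mapping")
    return cfg


def _config_hash(config: dict) -> str:
    # identifies the scientific configuration; output paths don't change
    # results, so they are excluded
    canon = json.dumps({k: v for k, v in config.items() if k != "paths"},
                       sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _world_config(config: dict) -> WorldConfig:
    spec = dict(config.get("world") or {})
    if spec.pop("full_grid", False):
        spec.setdefault("grid", StrataGrid.full())
    if "foods" in spec:
        spec["foods"] = tuple(spec["foods"])
    if "years" in spec:
        spec["years"] = tuple(spec["years"])
    if "urban_share" in spec and isinstance(spec["urban_share"], list):
        spec["urban_share"] = tuple(spec["urban_share"])
    return WorldConfig(**spec)


def _model_config(config: dict, seed: int) -> ModelConfig:
    spec = dict(config.get("model") or {})
    spec.setdefault("seed", seed)
    if "years" in spec:
        spec["years"] = tuple(spec["years"])
    return ModelConfig(**spec)


class PipelineError(RuntimeError):
    pass


def run_pipeline(config_path_or_dict, out=None, seed=None,
                 stages=None) -> Path:
    """Run the configured stages; returns the artifact directory.

    ``stages`` defaults to all of ``simulate, harmonize, fit, trend,
    aggregate, crossval, report``.  Later stages read the earlier stages'
    files from the artifact directory, so stages can be run in separate
    invocations.
    """
    if isinstance(config_path_or_dict, (str, Path)):
        config = load_config(config_path_or_dict)
    else:
        config = dict(config_path_or_dict)
    if seed is not None:
        config["seed"] = int(seed)
    config.setdefault("seed", 0)
    if out is not None:
        config.setdefault("paths", {})["out"] = str(out)
    outdir = Path(config.get("paths", {}).get("out", "asfintake_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "FAILED").unlink(missing_ok=True)
    stages = tuple(stages or ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")

    global_seed = int(config["seed"])
    manifest = {
        "config_hash": _config_hash(config),
        "seed": global_seed,
        "stage_seeds": {s: derive_seed(global_seed, s) for s in ALL_STAGES},
        "version": __version__,
        "stages_run": list(stages),
        "outputs": [],
    }

    for stage in stages:
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, outdir, manifest)
        except Exception:
            (outdir / "FAILED").write_text(
                f"stage {stage} failed; outputs are partial\n")
            raise
        log.info("stage %-9s done in %.1fs", stage, time.time() - t0)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config, outdir, manifest):
    wc = _world_config(config)
    seed = manifest["stage_seeds"]["simulate"]
    wc.seed = derive_seed(seed, "world")
    world = generate_true_intakes(wc)
    design = SurveyDesign.default(
        world, config.get("surveys_per_country", 2),
        seed=derive_seed(seed, "design"))
    surveys = simulate_surveys(world, design, seed=derive_seed(seed, "surveys"))
    availability = simulate_availability(world,
                                         seed=derive_seed(seed, "availability"))
    population = simulate_population(wc, seed=derive_seed(seed, "population"))
    truth_years = sorted({int(y) for y in
                          (config.get("aggregate", {}) or {})
                          .get("years", [wc.years[0], wc.years[1]])})
    truth = world.truth_frame(years=truth_years)
    for name, df in [("surveys.csv", surveys),
                     ("availability.csv", availability),
                     ("population.csv", population),
                     ("truth.csv", truth)]:
        write_table(df, outdir / name, seed=seed)
        manifest["outputs"].append(name)
    with open(outdir / "world.pkl", "wb") as fh:
        pickle.dump(world, fh)


def _stage_harmonize(config, outdir, manifest):
    surveys = read_table(outdir / "surveys.csv")
    issues = validate_surveys(surveys)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise PipelineError(f"{len(errors)} validation errors; see issues.json")
    harmonized = energy_adjust_table(surveys)
    write_table(harmonized, outdir / "harmonized_surveys.csv")
    with open(outdir / "issues.json", "w") as fh:
        json.dump([i.to_dict() for i in issues], fh, indent=2)
    manifest["outputs"] += ["harmonized_surveys.csv", "issues.json"]


def _stage_fit(config, outdir, manifest):
    surveys = read_table(outdir / "harmonized_surveys.csv")
    seed = manifest["stage_seeds"]["fit"]
    posteriors = {}
    diag_rows = []
    draw_frames = []
    for food in sorted(surveys["food"].unique()):
        mc = _model_config(config, derive_seed(seed, food))
        model = IntakeModel(config=mc, food=food).fit(surveys)
        posteriors[food] = model.posterior_
        d = model.diagnostics_.copy()
        d.insert(0, "food", food)
        d["converged"] = model.converged_
        diag_rows.append(d)
        beta = model.posterior_.flat_beta()
        df = pd.DataFrame(beta, columns=[f"beta_{i}" for i in range(beta.shape[1])])
        df.insert(0, "draw", np.arange(len(df)))
        df.insert(0, "food", food)
        draw_frames.append(df)
    with open(outdir / "posteriors.pkl", "wb") as fh:
        pickle.dump(posteriors, fh)
    write_table(pd.concat(draw_frames, ignore_index=True),
                outdir / "posterior_draws.csv")
    diag = pd.concat(diag_rows, ignore_index=True)
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(diag.to_dict(orient="records"), fh, indent=2)
    manifest["outputs"] += ["posterior_draws.csv", "diagnostics.json"]


def _stage_trend(config, outdir, manifest):
    availability = read_table(outdir / "availability.csv")
    with open(outdir / "posteriors.pkl", "rb") as fh:
        posteriors = pickle.load(fh)
    seed = manifest["stage_seeds"]["trend"]
    spec = dict(config.get("trend") or {})
    use_trend = spec.pop("enabled", True)
    combined = {}
    summaries = []
    for food, post in posteriors.items():
        if not use_trend:
            combined[food] = None
            continue
        tc = TrendConfig(seed=derive_seed(seed, food),
                         n_draws=post.n_draws, **spec)
        tp = TrendModel(config=tc, food=food).fit(availability).posterior_
        slopes = combine_posteriors(post, tp)
        combined[food] = slopes
        summaries.append({
            "food": food,
            "rho_median": float(np.median(tp.rho)),
            "beta_bar_median": float(np.median(tp.mu[:, 1])),
            "sigma_a_median": float(np.median(tp.sigma_a)),
            "kappa": tp.kappa,
        })
    with open(outdir / "combined_slopes.pkl", "wb") as fh:
        pickle.dump(combined, fh)
    with open(outdir / "trend_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2)
    manifest["outputs"].append("trend_summary.json")


def _predictions(config, outdir):
    """StratumDraws for every (food, country, requested year)."""
    with open(outdir / "posteriors.pkl", "rb") as fh:
        posteriors = pickle.load(fh)
    combined_path = outdir / "combined_slopes.pkl"
    combined = {}
    if combined_path.exists():
        with open(combined_path, "rb") as fh:
            combined = pickle.load(fh)
    agg = config.get("aggregate") or {}
    years = [int(y) for y in agg.get("years", [1990, 2018])]
    preds = {}
    for food, post in posteriors.items():
        slopes = combined.get(food)
        for country in post.design.countries:
            for year in years:
                sl = slopes[country] if slopes else None
                preds[(food, country, year)] = predict_strata(
                    post, country, year, slope_draws=sl)
    return preds, years


def _stage_aggregate(config, outdir, manifest):
    population = read_table(outdir / "population.csv")
    preds, years = _predictions(config, outdir)
    agg = config.get("aggregate") or {}
    foods = sorted({k[0] for k in preds})
    countries = sorted({k[1] for k in preds})
    with open(outdir / "posteriors.pkl", "rb") as fh:
        posteriors = pickle.load(fh)
    region_of = {c: r for f in posteriors.values()
                 for c, r in f.design.country_region.items()}
    regions = sorted(set(region_of.values()))
    child_bands = None

    est_rows, agg_rows = [], []
    for (food, country, year), sd in sorted(preds.items()):
        if child_bands is None:
            child_bands = [b for b in sd.strata["age_group"].unique()
                           if is_child(b)]
        lo, med, hi = np.percentile(sd.values, [2.5, 50, 97.5], axis=1)
        for i, row in sd.strata.iterrows():
            est_rows.append((country, year, food, row.age_group, row.sex,
                             row.education, row.urbanicity,
                             med[i], lo[i], hi[i]))
        e = weighted_mean(sd, population)
        agg_rows.append(("country", country, food, year, "all",
                         e.median, e.lower95, e.upper95))
    estimates = pd.DataFrame(est_rows, columns=[
        "country", "year", "food", "age_group", "sex", "education",
        "urbanicity", "median", "lower95", "upper95"])
    write_table(estimates, outdir / "estimates.csv")

    def blocks_for(scope_countries, food, year):
        return [preds[(food, c, year)] for c in scope_countries
                if (food, c, year) in preds]

    age_classes = {"all": None,
                   "children": {"age_group": child_bands},
                   "adults": {"age_group": [b for b in
                                            preds[next(iter(preds))].strata
                                            ["age_group"].unique()
                                            if not is_child(b)]}}
    for food in foods:
        for year in years:
            for scope, names in [("region", regions), ("global", ["world"])]:
                for name in names:
                    scope_countries = (
                        [c for c in countries if region_of[c] == name]
                        if scope == "region" else countries)
                    blocks = blocks_for(scope_countries, food, year)
                    for cls, subset in age_classes.items():
                        e = weighted_mean(blocks, population, subset)
                        agg_rows.append((scope, name, food, year, cls,
                                         e.median, e.lower95, e.upper95))
    aggregates = pd.DataFrame(agg_rows, columns=[
        "scope", "name", "food", "year", "age_class",
        "median", "lower95", "upper95"])
    write_table(aggregates, outdir / "aggregates.csv")

    # subgroup differences and standardised time change (global scope)
    year_hi = max(years)
    year_lo = min(years)
    pop_std = population[population["year"] == population["year"].max()]
    diff_rows = []
    contrasts = agg.get("contrasts", ["education", "urbanicity", "sex"])
    contrast_groups = {
        "education": ({"education": "high"}, {"education": "low"}),
        "urbanicity": ({"urbanicity": "urban"}, {"urbanicity": "rural"}),
        "sex": ({"sex": "female"}, {"sex": "male"}),
    }
    for food in foods:
        blocks = blocks_for(countries, food, year_hi)
        for contrast in contrasts:
            ga, gb = contrast_groups[contrast]
            d = subgroup_difference(blocks, pop_std, ga, gb, food=food,
                                    unit="servings/week")
            diff_rows.append((contrast, food, "global", year_hi,
                              d.absolute.median, d.absolute.lower95,
                              d.absolute.upper95, d.relative_pct.median,
                              d.significant, d.unit))
        if year_hi != year_lo:
            d = time_change(blocks_for(countries, food, year_lo), blocks,
                            pop_std, food=food, unit="servings/week")
            diff_rows.append((f"change_{year_lo}_{year_hi}", food, "global",
                              year_hi, d.absolute.median, d.absolute.lower95,
                              d.absolute.upper95, d.relative_pct.median,
                              d.significant, d.unit))
    differences = pd.DataFrame(diff_rows, columns=[
        "contrast", "food", "scope", "year", "absolute_median",
        "absolute_lower95", "absolute_upper95", "relative_pct_median",
        "significant", "unit"])
    write_table(differences, outdir / "differences.csv")

    # national medians for the latest year: thresholds and correlations
    national = aggregates[(aggregates["scope"] == "country")
                          & (aggregates["year"] == year_hi)
                          & (aggregates["age_class"] == "all")]
    national = national.rename(columns={"name": "country"})[
        ["country", "food", "median"]]
    pop_country = (pop_std.groupby("country", as_index=False)["population"]
                   .sum())
    thr_rows = []
    for spec in agg.get("thresholds", []):
        res = count_exceeding(national, spec["foods"],
                              float(spec["threshold"]), pop_country,
                              direction=spec.get("direction", ">="),
                              per=spec.get("per", "day"))
        thr_rows.append({"foods": "+".join(spec["foods"]),
                         "threshold": spec["threshold"],
                         "per": spec.get("per", "day"),
                         "direction": spec.get("direction", ">="),
                         **{k: v for k, v in res.to_dict().items()
                            if k != "countries"}})
    write_table(pd.DataFrame(thr_rows), outdir / "thresholds.csv")
    if len(foods) > 1:
        corr = spearman_matrix(national)
        corr.to_csv(outdir / "correlations.csv")
        manifest["outputs"].append("correlations.csv")
    manifest["outputs"] += ["estimates.csv", "aggregates.csv",
                            "differences.csv", "thresholds.csv"]


def _stage_crossval(config, outdir, manifest):
    surveys = read_table(outdir / "harmonized_surveys.csv")
    spec = dict(config.get("crossval") or {})
    seed = manifest["stage_seeds"]["crossval"]
    food = spec.get("food", sorted(surveys["food"].unique())[0])
    mc = _model_config(config, derive_seed(seed, "cvfit"))
    if "n_draws" in spec:
        mc.n_draws = int(spec["n_draws"])
    metrics = cross_validate(surveys, config=mc, k=int(spec.get("k", 5)),
                             seed=seed, food=food)
    write_table(metrics.to_frame(), outdir / "cv_metrics.csv")
    with open(outdir / "cv_folds.json", "w") as fh:
        json.dump(metrics.fold_assignment, fh, indent=2)
    manifest["outputs"] += ["cv_metrics.csv", "cv_folds.json"]


def _stage_report(config, outdir, manifest):
    make_report(outdir)
    manifest["outputs"] += ["report_region_table.csv",
                            "report_country_food.csv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "harmonize": _stage_harmonize,
    "fit": _stage_fit,
    "trend": _stage_trend,
    "aggregate": _stage_aggregate,
    "crossval": _stage_crossval,
    "report": _stage_report,
}


def make_report(artifact_dir):
    """Summary tables from a finished run.

    ``report_region_table.csv``: per food, region and age class (all ages /
    children < 20 years / adults >= 20 years) median intake with 95% UI,
    latest aggregated year.  ``report_country_food.csv``: country x food
    matrix of national median intakes.
    """
    artifact_dir = Path(artifact_dir)
    est_path = artifact_dir / "estimates.csv"
    if not est_path.exists():
        raise FileNotFoundError(f"missing estimates file: {est_path}")
    estimates = read_table(est_path)
    if estimates.empty:
        raise ValueError(f"estimates file is empty: {est_path}")
    aggregates = read_table(artifact_dir / "aggregates.csv")
    year = aggregates["year"].max()

    reg = aggregates[(aggregates["scope"].isin(["region", "global"]))
                     & (aggregates["year"] == year)].copy()
    reg["value"] = [f"{m:.1f} ({lo:.1f}-{hi:.1f})" for m, lo, hi in
                    zip(reg["median"], reg["lower95"], reg["upper95"])]
    region_table = reg.pivot_table(index=["food", "age_class"],
                                   columns="name", values="value",
                                   aggfunc="first").reset_index()
    region_table.to_csv(artifact_dir / "report_region_table.csv", index=False)

    nat = aggregates[(aggregates["scope"] == "country")
                     & (aggregates["year"] == year)
                     & (aggregates["age_class"] == "all")]
    matrix = nat.pivot(index="name", columns="food", values="median")
    matrix.to_csv(artifact_dir / "report_country_food.csv")
    return region_table, matrix
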