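"""Nested Bayesian hierarchical model for survey-reported intakes.

One observation is a survey-stratum mean ``y_i`` (g/day, energy-adjusted).
On the log scale the model is

    log(y_i + delta) ~ Normal(theta_i, s_i^2 + od_i * tau^2)

where ``s_i^2`` is the delta-method sampling variance of the reported mean
and ``od_i`` flags surveys that are not nationally representative or not
fully stratified: those receive extra study-level variance ``tau^2``
(overdispersion), which down-weights them.  The linear predictor nests
random effects globally, by region and by country, with country-specific
time slopes, a smoothed age curve, sex / education / urbanicity effects,
and survey-characteristic bias coefficients (assessment method, metric
type) with the 24-hour recall / individual-level / nationally
representative survey as the reference:

    theta_i = alpha + u_region + u_country + phi_country * (year - 2004)
              + a_age + b_sex + d_edu + h_urban + gamma' w_i + lambda' z_ct

Location parameters are conditionally jointly Gaussian, so inference is a
blocked Gibbs sampler: an exact multivariate-normal draw of all
coefficients, then slice-sampling updates of the variance components
(half-normal priors) and of tau.  Predictions are made at the reference
survey characteristics and back-transformed as ``exp(theta) - delta``
floored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from ._sampling import derive_seed, slice_sample
from .strata import COLLAPSED, StrataGrid
from .uncertainty import Estimate, summarize_draws

YEAR_CENTER = 2004


class ExtrapolationError(ValueError):
    """Prediction requested outside the modelled year range."""


# sum-to-zero contrast for the three education levels (orthonormal columns)
_EDU_CONTRAST = np.array([
    [1.0 / np.sqrt(2.0), 1.0 / np.sqrt(6.0)],     # low
    [-1.0 / np.sqrt(2.0), 1.0 / np.sqrt(6.0)],    # medium
    [0.0, -2.0 / np.sqrt(6.0)],                   # high
])
_EDU_INDEX = {"low": 0, "medium": 1, "high": 2}
_METHOD_COLUMNS = ("FFQ", "ShortQ", "HBS")  # 24HR is the reference


@dataclass
class ModelConfig:
    """Transform, priors and sampler settings for the intake model."""

    delta: float = 0.5               # g/day offset of the log transform
    n_draws: int = 4000              # retained draws across all chains
    n_chains: int = 2
    warmup: int = 500
    years: tuple[int, int] = (1990, 2018)   # modelled prediction range
    prior_sigma_region: float = 1.0  # half-normal scales
    prior_sigma_country: float = 1.0
    prior_sigma_slope: float = 0.03
    prior_sigma_age: float = 0.5     # random-walk smoothness of the age curve
    prior_tau: float = 0.5
    coef_sd: float = 1.0             # fixed-effect prior SD
    intercept_sd: float = 10.0
    global_slope_sd: float = 0.05
    min_obs_var: float = 1e-4        # floor on the log-scale sampling variance
    covariate_columns: tuple[str, ...] = ()
    rhat_limit: float = 1.1
    seed: int = 0

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        for name in ("prior_sigma_region", "prior_sigma_country",
                     "prior_sigma_slope", "prior_sigma_age", "prior_tau",
                     "coef_sd", "intercept_sd", "global_slope_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


class _Design:
    """Maps observation / prediction rows to design-matrix rows.

    Collapsed survey cells (``sex='both'`` etc.) get the uniform average of
    the level codes of the covered categories, which is the exact regression
    representation of an aggregated observation under uniform within-cell
    weights.
    """

    def __init__(self, regions, countries, country_region, age_bands,
                 covariate_columns=()):
        self.regions = tuple(regions)
        self.countries = tuple(countries)
        self.country_region = dict(country_region)
        self.age_bands = tuple(age_bands)
        self.covariate_columns = tuple(covariate_columns)
        self.blocks: dict[str, slice] = {}
        p = 0
        for name, width in [
                ("intercept", 1),
                ("region", len(self.regions)),
                ("country", len(self.countries)),
                ("gslope", 1),
                ("cslope", len(self.countries)),
                ("age", len(self.age_bands)),
                ("sex", 1), ("edu", 2), ("urban", 1),
                ("method", len(_METHOD_COLUMNS)), ("metric", 1),
                ("cov", len(self.covariate_columns))]:
            self.blocks[name] = slice(p, p + width)
            p += width
        self.p = p
        self._region_ix = {r: i for i, r in enumerate(self.regions)}
        self._country_ix = {c: i for i, c in enumerate(self.countries)}
        self._age_ix = {a: i for i, a in enumerate(self.age_bands)}

    def row(self, country, year, age_group, sex, education, urbanicity,
            method="24HR", metric="individual", covariates=None,
            region=None) -> np.ndarray:
        x = np.zeros(self.p)
        b = self.blocks
        x[b["intercept"]] = 1.0
        t = float(year) - YEAR_CENTER
        if country in self._country_ix:
            region = self.country_region[country]
            ci = self._country_ix[country]
            x[b["country"].start + ci] = 1.0
            x[b["cslope"].start + ci] = t
        elif region is None or region not in self._region_ix:
            raise KeyError(
                f"unknown country {country!r}; pass its region to predict "
                "at the region level (new-country effects are sampled)")
        x[b["region"].start + self._region_ix[region]] = 1.0
        x[b["gslope"]] = t
        if age_group == COLLAPSED["age_group"]:
            x[b["age"]] = 1.0 / len(self.age_bands)
        else:
            if age_group not in self._age_ix:
                raise KeyError(f"age band {age_group!r} not in the model grid")
            x[b["age"].start + self._age_ix[age_group]] = 1.0
        x[b["sex"]] = {"female": 0.0, "male": 1.0,
                       COLLAPSED["sex"]: 0.5}[sex]
        if education == COLLAPSED["education"]:
            x[b["edu"]] = _EDU_CONTRAST.mean(axis=0)  # zero by construction
        else:
            x[b["edu"]] = _EDU_CONTRAST[_EDU_INDEX[education]]
        x[b["urban"]] = {"rural": 0.0, "urban": 1.0,
                         COLLAPSED["urbanicity"]: 0.5}[urbanicity]
        for j, m in enumerate(_METHOD_COLUMNS):
            if method == m:
                x[b["method"].start + j] = 1.0
        x[b["metric"]] = 1.0 if metric == "household" else 0.0
        if self.covariate_columns:
            vals = covariates if covariates is not None else \
                np.zeros(len(self.covariate_columns))
            x[b["cov"]] = np.asarray(vals, dtype=float)
        return x

    def matrix(self, df: pd.DataFrame,
               covariates: pd.DataFrame | None = None) -> np.ndarray:
        cov_lookup = None
        if self.covariate_columns and covariates is not None:
            cov_lookup = covariates.set_index(["country", "year"])[
                list(self.covariate_columns)]
        rows = []
        for rec in df.itertuples(index=False):
            cov = None
            if cov_lookup is not None:
                try:
                    cov = cov_lookup.loc[(rec.country, rec.year)].to_numpy()
                except KeyError:
                    cov = np.zeros(len(self.covariate_columns))
            rows.append(self.row(
                rec.country, rec.year, rec.age_group, rec.sex, rec.education,
                rec.urbanicity, getattr(rec, "method", "24HR"),
                getattr(rec, "metric", "individual"), cov,
                region=getattr(rec, "region", None)))
        return np.array(rows)

    def is_new_country(self, country: str) -> bool:
        return country not in self._country_ix


@dataclass
class StratumDraws:
    """Posterior predictive draws of mean intake for one country-year-food.

    ``values`` is strata x n_draws, in the order of ``strata`` (which
    follows the grid ordering); g/day, energy-standardised, at the
    reference survey characteristics.
    """

    country: str
    year: int
    food: str
    strata: pd.DataFrame
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape[0] != len(self.strata):
            raise ValueError("stratum axis does not match the grid")
        if (self.values < 0).any():
            raise ValueError("predicted intakes must be >= 0")

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long export: one row per stratum per draw."""
        s = self.strata.copy()
        s.insert(0, "food", self.food)
        s.insert(0, "year", self.year)
        s.insert(0, "country", self.country)
        long = s.loc[s.index.repeat(self.n_draws)].reset_index(drop=True)
        long["draw"] = np.tile(np.arange(self.n_draws), len(self.strata))
        long["value"] = self.values.ravel()
        return long


@dataclass
class IntakePosterior:
    """Fitted parameters of the intake model, as retained MCMC draws."""

    config: ModelConfig
    food: str
    design: _Design
    beta: np.ndarray                  # (n_chains, draws_per_chain, p)
    variances: dict[str, np.ndarray]  # name -> (n_chains, draws_per_chain)
    covariates: pd.DataFrame | None
    diagnostics: pd.DataFrame
    converged: bool
    max_rhat: float

    @property
    def n_draws(self) -> int:
        return min(self.config.n_draws,
                   self.beta.shape[0] * self.beta.shape[1])

    def flat_beta(self) -> np.ndarray:
        """Coefficient draws pooled across chains, trimmed to n_draws."""
        p = self.beta.shape[-1]
        return self.beta.reshape(-1, p)[: self.n_draws]

    def block_draws(self, name: str) -> np.ndarray:
        return self.flat_beta()[:, self.design.blocks[name]]

    def education_effect_draws(self) -> np.ndarray:
        """Draws of the three education effects (sum to zero by contrast)."""
        return self.block_draws("edu") @ _EDU_CONTRAST.T

    def country_slope(self, country: str) -> np.ndarray:
        """Total time-slope draws for a country (global + deviation)."""
        ci = self.design._country_ix[country]
        b = self.flat_beta()
        return (b[:, self.design.blocks["gslope"].start]
                + b[:, self.design.blocks["cslope"].start + ci])

    def variance_draws(self, name: str) -> np.ndarray:
        return self.variances[name].reshape(-1)[: self.n_draws]

    def new_country_effects(self, country: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-draw intercept and slope deviations for a country absent
        from the training data, drawn from the fitted hierarchical
        distributions (deterministic given seed and country name)."""
        rng = np.random.default_rng(
            derive_seed(self.config.seed, f"newcountry-{country}"))
        u = rng.standard_normal(self.n_draws) * self.variance_draws("sigma_country")
        phi = rng.standard_normal(self.n_draws) * self.variance_draws("sigma_slope")
        return u, phi


def _prepare_observations(surveys: pd.DataFrame, config: ModelConfig):
    y = surveys["mean_g_day"].to_numpy(dtype=float)
    sd = pd.to_numeric(surveys["sd_g_day"], errors="coerce").to_numpy(float)
    n = surveys["n"].to_numpy(dtype=float)
    # missing SDs: impute from the food-specific median coefficient of
    # variation (deterministic, documented)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / y
    valid = np.isfinite(cv) & (cv > 0)
    cv_med = float(np.median(cv[valid])) if valid.any() else 0.25
    sd = np.where(np.isfinite(sd), sd, cv_med * y)
    z = np.log(y + config.delta)
    v0 = (sd / np.sqrt(n)) ** 2 / (y + config.delta) ** 2
    v0 = np.maximum(v0, config.min_obs_var)
    fully = (surveys[["strat_age", "strat_sex", "strat_edu", "strat_urban"]]
             .all(axis=1).to_numpy()
             if "strat_age" in surveys.columns
             else np.ones(len(surveys), dtype=bool))
    od = ((surveys["representativeness"] != "national").to_numpy() | ~fully)
    return z, v0, od


def _rw1_penalty(n_bands: int) -> np.ndarray:
    d = np.diff(np.eye(n_bands), axis=0)
    return d.T @ d


def _std_normal_lower_trunc(a: float, rng: np.random.Generator) -> float:
    """Draw from a standard normal truncated to (a, inf) by inverse CDF."""
    from scipy.stats import norm
    p = norm.cdf(a)
    u = p + (1.0 - p) * rng.random()
    return float(norm.ppf(min(u, 1.0 - 1e-16)))


class IntakeModel(BaseEstimator):
    """Scikit-learn-style estimator for the hierarchical intake model.

    Parameters mirror :class:`ModelConfig`; ``fit`` consumes a validated,
    energy-adjusted survey-stratum table for a single food.
    ``get_params``/``set_params``/``clone`` come from the sklearn base
    class.
    """

    def __init__(self, config: ModelConfig | None = None, food: str | None = None):
        self.config = config
        self.food = food

    # fitting --------------------------------------------------------------
    def fit(self, surveys: pd.DataFrame,
            covariates: pd.DataFrame | None = None) -> "IntakeModel":
        config = self.config or ModelConfig()
        foods = surveys["food"].unique()
        food = self.food
        if food is None:
            if len(foods) != 1:
                raise ValueError(
                    "surveys table contains multiple foods; fit one food at "
                    "a time (set food=...)")
            food = foods[0]
        df = surveys[surveys["food"] == food].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"no survey rows for food {food!r}")
        if df["region"].isna().any():
            bad = df.loc[df["region"].isna(), "country"].unique()
            raise ValueError(f"countries without a region mapping: {list(bad)}")

        country_region = (df.drop_duplicates("country")
                          .set_index("country")["region"].to_dict())
        regions = sorted(set(country_region.values()))
        countries = sorted(country_region)
        age_bands = [a for a in df["age_group"].unique()
                     if a != COLLAPSED["age_group"]]
        age_bands = _order_age_bands(age_bands)
        design = _Design(regions, countries, country_region, age_bands,
                         config.covariate_columns)

        X = design.matrix(df, covariates)
        z, v0, od = _prepare_observations(df, config)
        posterior = _run_gibbs(X, z, v0, od, design, config, food)
        self.config_ = config
        self.posterior_ = posterior
        self.posterior_.covariates = covariates
        self.design_ = design
        self.diagnostics_ = posterior.diagnostics
        self.converged_ = posterior.converged
        return self

    # prediction -----------------------------------------------------------
    def predict_strata(self, country: str, year: int,
                       grid: StrataGrid | None = None,
                       slope_draws: np.ndarray | None = None,
                       region: str | None = None,
                       allow_extrapolation: bool = False) -> StratumDraws:
        return predict_strata(self.posterior_, country, year, grid,
                              slope_draws=slope_draws, region=region,
                              allow_extrapolation=allow_extrapolation)

    def predict_observations(self, rows: pd.DataFrame) -> np.ndarray:
        """Predictive draws (rows x n_draws) at each row's own survey
        characteristics — used for cross-validation scoring.  Rows from
        countries absent in training are predicted at the region level
        plus sampled new-country effects."""
        post = self.posterior_
        X = post.design.matrix(rows, post.covariates)
        theta = X @ post.flat_beta().T
        for c in rows["country"].unique():
            if post.design.is_new_country(c):
                u, phi = post.new_country_effects(c)
                mask = (rows["country"] == c).to_numpy()
                t = rows.loc[mask, "year"].to_numpy(float) - YEAR_CENTER
                theta[mask] += u[None, :] + phi[None, :] * t[:, None]
        return np.maximum(np.exp(theta) - post.config.delta, 0.0)


def _order_age_bands(bands):
    from .strata import age_band_midpoint
    return tuple(sorted(bands, key=age_band_midpoint))


def _run_gibbs(X, z, v0, od, design, config, food) -> IntakePosterior:
    """Collapsed Gibbs: the five variance hyperparameters are slice-sampled
    on the marginal likelihood with every location parameter integrated out
    analytically (the model is linear-Gaussian given the variances), then
    the full coefficient vector is drawn exactly from its Gaussian
    conditional.  This sidesteps the centred-parametrisation funnel that
    makes naive Gibbs mix poorly when random effects are only partially
    identified."""
    n, p = X.shape
    b = design.blocks
    clean = ~od
    Xc, Xo = X[clean], X[od]
    zc, zo = z[clean], z[od]
    vc, vo = v0[clean], v0[od]
    A_clean = (Xc / vc[:, None]).T @ Xc if clean.any() else np.zeros((p, p))
    b_clean = (Xc / vc[:, None]).T @ zc if clean.any() else np.zeros(p)
    zwz_clean = float(zc @ (zc / vc)) if clean.any() else 0.0
    logv_clean = float(np.sum(np.log(vc))) if clean.any() else 0.0

    rw1 = _rw1_penalty(len(design.age_bands))
    fixed_prec = np.zeros(p)
    fixed_prec[b["intercept"]] = 1.0 / config.intercept_sd ** 2
    fixed_prec[b["gslope"]] = 1.0 / config.global_slope_sd ** 2
    for name in ("sex", "edu", "urban", "method", "metric", "cov"):
        fixed_prec[b[name]] = 1.0 / config.coef_sd ** 2

    def prior_precision(sig_r, sig_c, sig_phi, sig_age):
        P = np.diag(fixed_prec.copy())
        P[b["region"], b["region"]] += np.eye(len(design.regions)) / sig_r ** 2
        P[b["country"], b["country"]] += np.eye(len(design.countries)) / sig_c ** 2
        P[b["cslope"], b["cslope"]] += np.eye(len(design.countries)) / sig_phi ** 2
        P[b["age"], b["age"]] += rw1 / sig_age ** 2 + 0.01 * np.eye(len(design.age_bands))
        return P

    # data-side quantities depend only on tau; cache them between the
    # slice evaluations that vary a sigma
    tau_cache: dict[float, tuple] = {}

    def data_parts(tau):
        key = round(float(tau), 14)
        if key not in tau_cache:
            if od.any():
                w = 1.0 / (vo + tau ** 2)
                A = A_clean + (Xo * w[:, None]).T @ Xo
                rhs = b_clean + Xo.T @ (w * zo)
                zwz = zwz_clean + float(zo @ (w * zo))
                logv = logv_clean + float(np.sum(np.log(vo + tau ** 2)))
            else:
                A, rhs, zwz, logv = A_clean, b_clean, zwz_clean, logv_clean
            if len(tau_cache) > 64:
                tau_cache.clear()
            tau_cache[key] = (A, rhs, zwz, logv)
        return tau_cache[key]

    def marginal_loglik(sig_r, sig_c, sig_phi, sig_age, tau):
        A, rhs, zwz, logv = data_parts(tau)
        P = prior_precision(sig_r, sig_c, sig_phi, sig_age)
        try:
            L = linalg.cholesky(A + P, lower=True)
        except linalg.LinAlgError:
            return -np.inf
        mu = linalg.cho_solve((L, True), rhs)
        logdet_q = 2.0 * float(np.sum(np.log(np.diag(L))))
        sign, logdet_p = np.linalg.slogdet(P)
        if sign <= 0:
            return -np.inf
        return -0.5 * (logv + zwz - float(rhs @ mu) + logdet_q - logdet_p)

    prior_scales = {"sigma_region": config.prior_sigma_region,
                    "sigma_country": config.prior_sigma_country,
                    "sigma_slope": config.prior_sigma_slope,
                    "sigma_age": config.prior_sigma_age,
                    "tau": config.prior_tau}

    draws_per_chain = int(np.ceil(config.n_draws / config.n_chains))
    beta_store = np.empty((config.n_chains, draws_per_chain, p))
    var_store = {k: np.empty((config.n_chains, draws_per_chain))
                 for k in prior_scales}

    for chain in range(config.n_chains):
        rng = np.random.default_rng(
            derive_seed(config.seed, f"intake-{food}-chain{chain}"))
        sig = {name: scale * (0.3 + 0.7 * rng.random())
               for name, scale in prior_scales.items()}
        for it in range(config.warmup + draws_per_chain):
            for name in prior_scales:
                if name == "tau" and not od.any():
                    sig["tau"] = abs(rng.normal(0.0, config.prior_tau))
                    continue

                def logpost(log_s, _name=name):
                    s = float(np.exp(log_s))
                    trial = {**sig, _name: s}
                    return (marginal_loglik(
                        trial["sigma_region"], trial["sigma_country"],
                        trial["sigma_slope"], trial["sigma_age"],
                        trial["tau"])
                        - s ** 2 / (2.0 * prior_scales[_name] ** 2)
                        + log_s)
                sig[name] = float(np.exp(slice_sample(
                    np.log(sig[name]), logpost, rng)))

            # exact joint draw of all location parameters
            A, rhs, _, _ = data_parts(sig["tau"])
            Q = A + prior_precision(sig["sigma_region"], sig["sigma_country"],
                                    sig["sigma_slope"], sig["sigma_age"])
            L = linalg.cholesky(Q, lower=True)
            mu = linalg.cho_solve((L, True), rhs)
            beta = mu + linalg.solve_triangular(
                L.T, rng.standard_normal(p), lower=False)

            if it >= config.warmup:
                j = it - config.warmup
                beta_store[chain, j] = beta
                for name in prior_scales:
                    var_store[name][chain, j] = sig[name]

    diagnostics = _diagnostics(beta_store, var_store, design)
    finite = diagnostics["rhat"].dropna()
    max_rhat = float(finite.max()) if len(finite) else float("nan")
    converged = not (np.isfinite(max_rhat) and max_rhat >= config.rhat_limit)
    if not converged:
        warnings.warn(
            f"intake model for {food!r} failed the R-hat gate "
            f"(max R-hat {max_rhat:.3f} >= {config.rhat_limit}); "
            "result flagged as non-converged", RuntimeWarning)
    return IntakePosterior(config=config, food=food, design=design,
                           beta=beta_store, variances=var_store,
                           covariates=None, diagnostics=diagnostics,
                           converged=converged, max_rhat=max_rhat)


def _diagnostics(beta_store, var_store, design) -> pd.DataFrame:
    import arviz as az
    data = {name: arr for name, arr in var_store.items()}
    data["beta"] = beta_store
    idata = az.from_dict(posterior=data)
    single_chain = beta_store.shape[0] < 2
    if single_chain:
        warnings.warn("convergence diagnostics are limited with a single "
                      "chain", RuntimeWarning)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata) if not single_chain else None
        ess = az.ess(idata)
    for name in var_store:
        r = float(rhat[name].values) if rhat is not None else np.nan
        rows.append((name, r, float(ess[name].values)))
    if rhat is not None:
        r_beta = np.asarray(rhat["beta"].values)
    else:
        r_beta = np.full(beta_store.shape[-1], np.nan)
    e_beta = np.asarray(ess["beta"].values)
    for block, sl in design.blocks.items():
        for j in range(sl.start, sl.stop):
            rows.append((f"beta[{block}:{j - sl.start}]", r_beta[j], e_beta[j]))
    return pd.DataFrame(rows, columns=["param", "rhat", "ess"])


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the estimator)

def fit_intake_model(surveys: pd.DataFrame,
                     covariates: pd.DataFrame | None = None,
                     config: ModelConfig | None = None,
                     food: str | None = None) -> IntakePosterior:
    """Fit the hierarchical model; returns the posterior object."""
    model = IntakeModel(config=config, food=food).fit(surveys, covariates)
    return model.posterior_


def predict_strata(posterior: IntakePosterior, country: str, year: int,
                   grid: StrataGrid | None = None,
                   slope_draws: np.ndarray | None = None,
                   region: str | None = None,
                   allow_extrapolation: bool = False) -> StratumDraws:
    """Per-stratum posterior predictive draws for a country-year.

    Predictions are at the reference survey characteristics (24HR,
    individual metric, nationally representative), back-transformed as
    ``exp(theta) - delta`` and floored at zero.  ``slope_draws`` (one per
    retained draw) replaces the country's own time slope — used when
    combining with the availability trend model.  A country without any
    training surveys is predicted at its region's level (pass ``region``)
    with intercept/slope deviations sampled from the fitted hierarchical
    distributions, so it shrinks toward its own region's mean.
    """
    config = posterior.config
    lo, hi = config.years
    if not (lo <= year <= hi) and not allow_extrapolation:
        raise ExtrapolationError(
            f"year {year} outside modelled range {config.years}; pass "
            "allow_extrapolation=True to override")
    grid = grid or StrataGrid(age_bands=posterior.design.age_bands)
    frame = grid.to_frame()
    frame.insert(0, "year", year)
    frame.insert(0, "country", country)
    if region is not None:
        frame.insert(0, "region", region)
    X = posterior.design.matrix(frame, posterior.covariates)
    beta = posterior.flat_beta()
    theta = X @ beta.T                     # strata x n_draws
    if posterior.design.is_new_country(country):
        u, phi = posterior.new_country_effects(country)
        theta = theta + u[None, :] + phi[None, :] * (year - YEAR_CENTER)
    if slope_draws is not None:
        slope_draws = np.asarray(slope_draws, dtype=float)
        if slope_draws.shape != (posterior.n_draws,):
            raise ValueError("slope_draws must have one value per retained draw")
        own = posterior.country_slope(country)
        theta = theta + (slope_draws - own)[None, :] * (year - YEAR_CENTER)
    values = np.maximum(np.exp(theta) - config.delta, 0.0)
    return StratumDraws(country=country, year=year, food=posterior.food,
                        strata=grid.to_frame(), values=values)


def summarize_stratum(draws: np.ndarray, min_draws: int = 100) -> Estimate:
    """Median and 95% UI of one stratum's draw vector."""
    return summarize_draws(draws, min_draws=min_draws)


def convergence_check(posterior: IntakePosterior,
                      rhat_warn: float = 1.05) -> pd.DataFrame:
    """Diagnostics report: R-hat and effective sample size per parameter.

    Adds a ``flagged`` column for R-hat >= ``rhat_warn``; constant
    (zero-variance) parameters report R-hat as NaN ("not applicable").
    """
    report = posterior.diagnostics.copy()
    report["flagged"] = report["rhat"] >= rhat_warn
    if report["rhat"].isna().any() and posterior.beta.shape[0] >= 2:
        warnings.warn("some parameters have undefined R-hat (zero variance)",
                      RuntimeWarning)
    return report
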