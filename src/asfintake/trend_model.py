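"""Varying-slopes time model on national food-availability series.

Per-capita availability series (e.g. food balance sheets) carry long,
annual time signal that sparse survey inventories lack.  The model is a
bivariate partial-pooling regression on the log scale:

    log A_ct ~ Normal(eta_c + beta_c * (t - 2004), sigma_A^2)
    (eta_c, beta_c) ~ BivariateNormal((eta_bar, beta_bar), Sigma)

with the intercept-slope correlation rho estimated across countries.  The
two-dimensional pooling regularises both parameters and shrinks
short-series countries toward the population trend.  All conditionals are
conjugate (Gaussian / inverse-Wishart / inverse-gamma), so inference is a
plain Gibbs sampler.

``combine_posteriors`` merges the availability slope (rescaled to the
intake scale by a coefficient kappa) with the intake model's own country
slope by draw-level inverse-variance weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._sampling import derive_seed

YEAR_CENTER = 2004


@dataclass
class TrendConfig:
    n_draws: int = 4000
    n_chains: int = 2
    warmup: int = 500
    min_points: int = 3            # countries with fewer are pooled-only
    mu_prior_sd: tuple[float, float] = (10.0, 1.0)   # (intercept, slope)
    wishart_df: float = 4.0
    wishart_scale: tuple[float, float] = (0.25 ** 2, 0.02 ** 2)
    sigma_a: tuple[float, float] = (2.0, 0.02)       # IG(shape, rate) prior
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        if self.wishart_df <= 3:
            raise ValueError("wishart_df must exceed 3 for a proper prior")


@dataclass
class TrendPosterior:
    """Retained draws of the varying-slopes model."""

    config: TrendConfig
    food: str
    countries: tuple[str, ...]
    pooled_only: tuple[str, ...]
    eta: np.ndarray        # (n_draws, C)
    beta: np.ndarray       # (n_draws, C)
    mu: np.ndarray         # (n_draws, 2) population (eta_bar, beta_bar)
    rho: np.ndarray        # (n_draws,)
    sigma_a: np.ndarray    # (n_draws,)
    kappa: float = 1.0     # availability-to-intake slope scaling

    @property
    def n_draws(self) -> int:
        return self.eta.shape[0]

    def country_slope(self, country: str) -> np.ndarray:
        ci = self.countries.index(country)
        return self.beta[:, ci]


class TrendModel(BaseEstimator):
    """Scikit-learn-style estimator for the availability trend model."""

    def __init__(self, config: TrendConfig | None = None,
                 food: str | None = None):
        self.config = config
        self.food = food

    def fit(self, availability: pd.DataFrame) -> "TrendModel":
        config = self.config or TrendConfig()
        food = self.food
        if "food" in availability.columns:
            foods = availability["food"].unique()
            if food is None:
                if len(foods) != 1:
                    raise ValueError("availability table has multiple foods; "
                                     "set food=...")
                food = foods[0]
            availability = availability[availability["food"] == food]
        food = food or "availability"
        df = availability.dropna(subset=["availability_g_day"])
        df = df[df["availability_g_day"] > 0]

        countries = tuple(sorted(df["country"].unique()))
        series = {}
        pooled_only = []
        for c in countries:
            sub = df[df["country"] == c]
            t = sub["year"].to_numpy(float) - YEAR_CENTER
            w = np.log(sub["availability_g_day"].to_numpy(float))
            if len(t) < config.min_points:
                pooled_only.append(c)
                series[c] = (np.empty(0), np.empty(0))
            else:
                series[c] = (t, w)
        if pooled_only:
            warnings.warn(
                f"countries with fewer than {config.min_points} availability "
                f"points are pooled-only: {pooled_only}", RuntimeWarning)
        if len(countries) == len(pooled_only):
            raise ValueError("no country has enough availability points to fit")

        self.config_ = config
        self.posterior_ = _trend_gibbs(series, countries, tuple(pooled_only),
                                       config, food)
        return self


def _trend_gibbs(series, countries, pooled_only, config, food) -> TrendPosterior:
    C = len(countries)
    draws_per_chain = int(np.ceil(config.n_draws / config.n_chains))
    total = draws_per_chain * config.n_chains
    eta_s = np.empty((total, C))
    beta_s = np.empty((total, C))
    mu_s = np.empty((total, 2))
    rho_s = np.empty(total)
    sig_s = np.empty(total)

    V0_inv = np.diag(1.0 / np.array(config.mu_prior_sd) ** 2)
    nu0 = config.wishart_df
    S0 = np.diag(config.wishart_scale) * (nu0 - 3.0)  # prior mean ~ scale
    a0, b0 = config.sigma_a
    n_obs = sum(len(t) for t, _ in series.values())

    # per-country sufficient statistics
    TT = {c: np.array([[len(t), t.sum()], [t.sum(), (t * t).sum()]])
          for c, (t, _) in series.items()}
    Tw = {c: np.array([w.sum(), (t * w).sum()]) for c, (t, w) in series.items()}

    row = 0
    for chain in range(config.n_chains):
        rng = np.random.default_rng(
            derive_seed(config.seed, f"trend-{food}-chain{chain}"))
        # initialise from per-country least squares where possible
        xb = np.zeros((C, 2))
        for i, c in enumerate(countries):
            t, w = series[c]
            if len(t) >= 2 and np.ptp(t) > 0:
                slope, intercept = np.polyfit(t, w, 1)
                xb[i] = (intercept, slope)
            elif len(t):
                xb[i] = (w.mean(), 0.0)
        mu = xb.mean(axis=0)
        Sigma = np.diag([0.1, 0.001])
        sig2 = 0.05 ** 2 * (1 + rng.random())

        for it in range(config.warmup + draws_per_chain):
            Sigma_inv = np.linalg.inv(Sigma)
            # country-level (eta, beta)
            for i, c in enumerate(countries):
                t, w = series[c]
                if len(t):
                    prec = Sigma_inv + TT[c] / sig2
                    rhs = Sigma_inv @ mu + Tw[c] / sig2
                else:
                    prec = Sigma_inv
                    rhs = Sigma_inv @ mu
                cov = np.linalg.inv(prec)
                xb[i] = rng.multivariate_normal(cov @ rhs, cov,
                                                method="cholesky")
            # population mean
            prec_mu = V0_inv + C * Sigma_inv
            cov_mu = np.linalg.inv(prec_mu)
            mu = rng.multivariate_normal(cov_mu @ (Sigma_inv @ xb.sum(axis=0)),
                                         cov_mu, method="cholesky")
            # population covariance (inverse-Wishart)
            dev = xb - mu
            Sigma = stats.invwishart.rvs(df=nu0 + C, scale=S0 + dev.T @ dev,
                                         random_state=rng)
            # residual variance (inverse-gamma)
            ss = 0.0
            for i, c in enumerate(countries):
                t, w = series[c]
                if len(t):
                    r = w - xb[i, 0] - xb[i, 1] * t
                    ss += float(r @ r)
            sig2 = 1.0 / rng.gamma(a0 + 0.5 * n_obs, 1.0 / (b0 + 0.5 * ss))

            if it >= config.warmup:
                eta_s[row] = xb[:, 0]
                beta_s[row] = xb[:, 1]
                mu_s[row] = mu
                rho_s[row] = Sigma[0, 1] / np.sqrt(Sigma[0, 0] * Sigma[1, 1])
                sig_s[row] = np.sqrt(sig2)
                row += 1

    keep = min(config.n_draws, total)
    return TrendPosterior(config=config, food=food, countries=countries,
                          pooled_only=pooled_only, eta=eta_s[:keep],
                          beta=beta_s[:keep], mu=mu_s[:keep],
                          rho=rho_s[:keep], sigma_a=sig_s[:keep])


# ---------------------------------------------------------------------------
# module-level operations

def fit_trend_model(availability: pd.DataFrame,
                    config: TrendConfig | None = None,
                    food: str | None = None) -> TrendPosterior:
    return TrendModel(config=config, food=food).fit(availability).posterior_


def estimate_kappa(intake_posterior, trend_posterior) -> float:
    """Availability-to-intake slope scaling: through-origin regression of
    the intake model's posterior-median country slopes on the trend
    model's.  Falls back to 1 when availability slopes carry no signal."""
    shared = [c for c in trend_posterior.countries
              if c in intake_posterior.design._country_ix]
    if not shared:
        return 1.0
    phi = np.array([np.median(intake_posterior.country_slope(c))
                    for c in shared])
    beta = np.array([np.median(trend_posterior.country_slope(c))
                     for c in shared])
    denom = float(beta @ beta)
    if denom < 1e-12:
        return 1.0
    return float(phi @ beta / denom)


def combine_posteriors(intake_posterior, trend_posterior,
                       method_config: dict | None = None
                       ) -> dict[str, np.ndarray]:
    """Draw-level inverse-variance combination of country time slopes.

    Per draw ``d``: ``(p_I * phi_d + p_T * kappa * beta_d) / (p_I + p_T)``
    with p the inverse posterior variance of each slope.  Draws are paired
    by index, so the combined draw always lies between the two inputs.
    ``method_config`` keys: ``kappa`` (override the estimated scaling) and
    ``trend_weight`` (override p_T / (p_I + p_T); 0 reproduces the intake
    model exactly).  Countries absent from the trend model keep the intake
    slope alone.
    """
    cfg = method_config or {}
    kappa = cfg.get("kappa")
    if kappa is None:
        kappa = estimate_kappa(intake_posterior, trend_posterior)
    trend_weight = cfg.get("trend_weight")

    out: dict[str, np.ndarray] = {}
    n = intake_posterior.n_draws
    for c in intake_posterior.design.countries:
        phi = intake_posterior.country_slope(c)
        if c not in trend_posterior.countries:
            out[c] = phi
            continue
        kb = kappa * trend_posterior.country_slope(c)
        if len(kb) != n:
            raise ValueError(
                f"draw counts differ (intake {n}, trend {len(kb)}); "
                "fit both models with the same n_draws")
        if trend_weight is not None:
            wT = float(trend_weight)
        else:
            p_i = 1.0 / max(float(np.var(phi)), 1e-18)
            p_t = 1.0 / max(float(np.var(kb)), 1e-18)
            wT = p_t / (p_i + p_t)
        out[c] = (1.0 - wT) * phi + wT * kb
    return out
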