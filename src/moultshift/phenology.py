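"""Hierarchical Bayesian change-point model of the seasonal coat-colour moult.

Model
-----
Each hare *i* carries a latent moult trajectory that is piecewise linear in
time: fully brown (0% white) before its initiation date, ramping linearly to
fully white (100%) over its moult duration in autumn, and the mirror image in
spring.  Individual initiation dates are exchangeable around a population
mean,

    init_i = mu_init + eps_i,        eps_i ~ Normal(0, sigma_ind^2),

while the moult *rate* is shared across hares up to covariate effects.
Covariates (mean snow cover, mean degree days over the seasonal window, and
sex) modify the base duration ``dbar`` multiplicatively through an
exponential link, with sex entering as an additive days-equivalent offset:

    duration_i = dbar * exp(b_snow * snow_i + b_temp * dd_i) + b_sex * sex_i,

``sex_i`` coded 0 for males and -1 for females, so a positive ``b_sex``
shortens the female moult.  Observed whiteness scores are the latent
trajectory plus Gaussian observation error ``sigma_obs`` (grid scores are
treated as point observations).

Fitting is by adaptive random-walk Metropolis-within-Gibbs over the global
parameters, with the per-hare effects updated in a vectorised elementwise
block (they are conditionally independent given the globals).  Two or more
chains are run from overdispersed starts; convergence is monitored with the
split-chain R-hat statistic.  The population completion date is derived per
draw as ``mu_init + duration`` at the sample covariate means.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .observations import HareObservation, SiteConfig, TemperatureSeries
from .camouflage import degree_days

__all__ = [
    "Season",
    "MoultModelSpec",
    "MCMCConfig",
    "ModelParams",
    "PhenologyData",
    "PhenologyFit",
    "ReactionNorm",
    "season_anchor",
    "moult_season_of",
    "expected_whiteness",
    "effective_duration",
    "log_likelihood",
    "log_posterior",
    "prepare_phenology_data",
    "fit_changepoint",
    "covariate_shift",
    "reaction_norms",
    "fit_trajectory_ls",
]

Season = Literal["autumn", "spring"]

GLOBAL_PARAMS = ("mu_init", "dbar", "sigma_ind", "sigma_obs",
                 "beta_snow", "beta_temp", "beta_sex")


def season_anchor(season: Season, year: int) -> _dt.date:
    """Calendar origin of the season's day axis (day 0)."""
    if season == "autumn":
        return _dt.date(year, 8, 1)
    if season == "spring":
        return _dt.date(year, 2, 1)
    raise ValueError(f"season must be 'autumn' or 'spring', got {season!r}")


def moult_season_of(date: _dt.date) -> tuple[Season, int]:
    """Which moult (and moult-year) a sighting belongs to.

    August-December sightings belong to that year's autumn brown-to-white
    moult; January-July sightings to that year's spring white-to-brown moult.
    """
    if date.month >= 8:
        return "autumn", date.year
    return "spring", date.year


def expected_whiteness(t, init, duration, season: Season):
    """Latent % whiteness of the piecewise-linear change-point trajectory.

    Autumn: 100 * clamp((t - init) / duration, 0, 1); spring is the mirrored
    white-to-brown ramp.  Vectorised over any broadcastable arguments.
    """
    duration = np.asarray(duration, dtype=float)
    if np.any(duration <= 0):
        raise ValueError("duration must be positive")
    frac = np.clip((np.asarray(t, dtype=float) - init) / duration, 0.0, 1.0)
    if season == "autumn":
        return 100.0 * frac
    if season == "spring":
        return 100.0 * (1.0 - frac)
    raise ValueError(f"season must be 'autumn' or 'spring', got {season!r}")


def effective_duration(dbar, snow_mean, dd_mean, sex, beta_snow=0.0,
                       beta_temp=0.0, beta_sex=0.0):
    """Covariate-adjusted moult duration in days (floored at 1 day).

    ``sex`` is coded 0 (male) / -1 (female): a positive ``beta_sex`` makes
    the female moult shorter.  Snow and degree-day effects act
    multiplicatively through an exponential link, so a positive ``beta_snow``
    lengthens the duration (slows the moult) under snowier conditions.
    """
    if np.any(np.asarray(dbar, dtype=float) <= 0):
        raise ValueError("base duration dbar must be positive")
    dur = (np.asarray(dbar, dtype=float)
           * np.exp(beta_snow * np.asarray(snow_mean, dtype=float)
                    + beta_temp * np.asarray(dd_mean, dtype=float))
           + beta_sex * np.asarray(sex, dtype=float))
    return np.maximum(dur, 1.0)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MoultModelSpec:
    """Priors and structure of the change-point model.

    Priors: uniform window for the population initiation date; uniform
    positive half-ranges for the base duration and the two standard
    deviations; diffuse Normal(0, beta_prior_sd^2) for the rate coefficients.
    """

    season: Season
    mu_init_window: tuple[float, float] = (0.0, 150.0)
    dbar_range: tuple[float, float] = (1.0, 120.0)
    sigma_ind_max: float = 30.0
    sigma_obs_max: float = 40.0
    #: prior sd of the per-percent / per-degree-day rate coefficients; 0.01
    #: already allows a 2.7-fold duration change over a 100-unit covariate
    #: span at one prior sd, i.e. effects far larger than plausible
    rate_beta_prior_sd: float = 0.01
    #: prior sd of the additive sex offset (days)
    sex_beta_prior_sd: float = 10.0
    include_covariates: bool = True


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; the seed is mandatory (no hidden global state)."""

    seed: int
    n_chains: int = 2
    n_warmup: int = 1500
    n_draws: int = 1500
    adapt_interval: int = 25
    target_accept: float = 0.44
    rhat_threshold: float = 1.05


@dataclass
class ModelParams:
    """One point in parameter space (globals plus per-hare effects)."""

    mu_init: float
    dbar: float
    sigma_ind: float
    sigma_obs: float
    beta_snow: float = 0.0
    beta_temp: float = 0.0
    beta_sex: float = 0.0
    eps: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass(frozen=True)
class PhenologyData:
    """Prepared per-observation and per-hare arrays for one site-season-year.

    Covariates are stored centred at their sample means (kept in
    ``covariate_means``) so the derived completion date at covariate means is
    simply ``mu_init + dbar`` and the sampler mixes well.
    Days count from :func:`season_anchor`.
    """

    season: Season
    site: str
    year: int
    hare_ids: tuple[str, ...]
    obs_hare: np.ndarray      # (n_obs,) int index into hare_ids
    obs_day: np.ndarray       # (n_obs,) float days since anchor
    obs_whiteness: np.ndarray  # (n_obs,) float percent
    snow_c: np.ndarray        # (n_hares,) centred mean snow over the window
    dd_c: np.ndarray          # (n_hares,) centred mean degree days
    sex_c: np.ndarray         # (n_hares,) centred sex code (0 male / -1 female)
    covariate_means: dict

    @property
    def n_hares(self) -> int:
        return len(self.hare_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_day)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

_LOG_2PI = float(np.log(2.0 * np.pi))


def _per_obs_loglik(params: ModelParams, data: PhenologyData) -> np.ndarray:
    init = params.mu_init + params.eps
    dur = effective_duration(
        params.dbar, data.snow_c, data.dd_c, data.sex_c,
        params.beta_snow, params.beta_temp, params.beta_sex,
    )
    mu = expected_whiteness(
        data.obs_day, init[data.obs_hare], dur[data.obs_hare], data.season
    )
    resid = data.obs_whiteness - mu
    s2 = params.sigma_obs ** 2
    return -0.5 * (_LOG_2PI + np.log(s2) + resid * resid / s2)


def log_likelihood(params: ModelParams, data: PhenologyData) -> float:
    """Joint log density of the data and the per-hare random effects.

    Sum of Normal(observed | expected_whiteness, sigma_obs^2) log densities
    over all sightings, plus the Normal(0, sigma_ind^2) log densities of the
    per-hare initiation effects.  ``sigma_obs = 0`` (or ``sigma_ind = 0``
    with non-zero effects) gives -inf: a degenerate observation model cannot
    explain any residual.
    """
    if params.sigma_obs <= 0:
        return float("-inf")
    out = float(np.sum(_per_obs_loglik(params, data)))
    if data.n_hares and params.eps.size:
        if params.sigma_ind <= 0:
            if np.any(params.eps != 0.0):
                return float("-inf")
        else:
            s2 = params.sigma_ind ** 2
            out += float(np.sum(
                -0.5 * (_LOG_2PI + np.log(s2) + params.eps ** 2 / s2)
            ))
    return out


def _log_prior(params: ModelParams, spec: MoultModelSpec) -> float:
    lo, hi = spec.mu_init_window
    if not (lo <= params.mu_init <= hi):
        return float("-inf")
    dlo, dhi = spec.dbar_range
    if not (dlo <= params.dbar <= dhi):
        return float("-inf")
    if not (0.0 < params.sigma_ind <= spec.sigma_ind_max):
        return float("-inf")
    if not (0.0 < params.sigma_obs <= spec.sigma_obs_max):
        return float("-inf")
    lp = 0.0
    if spec.include_covariates:
        s2 = spec.rate_beta_prior_sd ** 2
        lp += -0.5 * (params.beta_snow ** 2 + params.beta_temp ** 2) / s2
        lp += -0.5 * params.beta_sex ** 2 / spec.sex_beta_prior_sd ** 2
    return lp


def log_posterior(params: ModelParams, data: PhenologyData,
                  spec: MoultModelSpec) -> float:
    lp = _log_prior(params, spec)
    if not np.isfinite(lp):
        return float("-inf")
    return lp + log_likelihood(params, data)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def _window_cov_means(site: str, season: Season, year: int,
                      snow_daily: "pd.Series | None",
                      temps: TemperatureSeries | None) -> tuple[float, float]:
    """Mean snow % and mean cumulative degree days over the seasonal window."""
    anchor = season_anchor(season, year)
    if season == "autumn":
        end = _dt.date(year, 12, 31)
    else:
        end = _dt.date(year, 7, 15)
    snow_mean = 0.0
    if snow_daily is not None:
        vals = [v for d, v in snow_daily.items() if anchor <= d <= end]
        snow_mean = float(np.mean(vals)) if vals else 0.0
    dd_mean = 0.0
    if temps is not None:
        series = [s for s in degree_days(temps, season) if s.year == year]
        if series:
            dd_mean = float(np.mean(series[0].dd))
    return snow_mean, dd_mean


def prepare_phenology_data(
    records: Iterable[HareObservation],
    season: Season,
    site: str,
    year: int,
    temps: TemperatureSeries | None = None,
    snow_daily: "dict[_dt.date, float] | None" = None,
) -> PhenologyData:
    """Assemble the fitting arrays for one site, moult season and year.

    Per-hare covariates are window summaries: the site-level mean snow cover
    and mean cumulative degree days over the seasonal window (shared across
    hares of a site-year when only site-level series are available — the
    per-hare snow experience is approximated by the site climatology), plus
    the hare's sex code.  Covariates are centred before fitting.
    """
    recs = [
        r for r in records
        if r.site == site and moult_season_of(r.date) == (season, year)
    ]
    if not recs:
        raise ValueError(f"no observations for {site!r} {season} {year}")
    anchor = season_anchor(season, year)
    hare_ids = tuple(sorted({r.hare_id for r in recs}))
    index = {h: i for i, h in enumerate(hare_ids)}
    obs_hare = np.array([index[r.hare_id] for r in recs], dtype=int)
    obs_day = np.array([(r.date - anchor).days for r in recs], dtype=float)
    obs_w = np.array([r.whiteness for r in recs], dtype=float)

    sex_by_hare = {}
    for r in recs:
        sex_by_hare[r.hare_id] = -1.0 if r.sex == "female" else 0.0
    sex = np.array([sex_by_hare[h] for h in hare_ids], dtype=float)

    snow_series = None
    if snow_daily is not None:
        snow_series = pd.Series(snow_daily)
    snow_mean, dd_mean = _window_cov_means(site, season, year, snow_series, temps)
    if snow_series is not None:
        # site climatology window mean: the covariate every hare of this
        # site-year experiences, free of detection/mortality sampling bias
        snow_by_hare = np.full(len(hare_ids), snow_mean, dtype=float)
    else:
        # no daily series: fall back to the mean snow each hare was sighted in
        snow_by_hare = np.zeros(len(hare_ids))
        for i, h in enumerate(hare_ids):
            vals = [r.snow10m for r in recs if r.hare_id == h]
            snow_by_hare[i] = float(np.mean(vals)) if vals else 0.0
    dd = np.full(len(hare_ids), dd_mean, dtype=float)

    means = {
        "snow": float(np.mean(snow_by_hare)),
        "dd": float(np.mean(dd)),
        "sex": float(np.mean(sex)),
    }
    return PhenologyData(
        season=season,
        site=site,
        year=year,
        hare_ids=hare_ids,
        obs_hare=obs_hare,
        obs_day=obs_day,
        obs_whiteness=obs_w,
        snow_c=snow_by_hare - means["snow"],
        dd_c=dd - means["dd"],
        sex_c=sex - means["sex"],
        covariate_means=means,
    )


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


@dataclass
class PhenologyFit:
    """Posterior draws and summaries from :func:`fit_changepoint`.

    ``draws`` maps parameter name -> array of shape (chains, draws); the
    derived ``completion`` (mu_init + duration at covariate means) and
    ``duration`` are included.  Credible intervals are equal-tailed 95%.
    """

    season: Season
    draws: dict
    hare_ids: tuple[str, ...]
    eps_mean: np.ndarray
    eps_sd: np.ndarray
    covariate_means: dict
    accept_rates: dict
    rhat: dict
    converged: bool
    warning: str | None
    include_covariates: bool
    seed: int

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        x = self.flat(name)
        return (float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a)))

    def posterior_mean(self, name: str) -> float:
        return float(np.mean(self.flat(name)))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.draws:
            lo, hi = self.ci(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": self.posterior_mean(name),
                    "sd": float(np.std(self.flat(name))),
                    "ci_low": lo,
                    "ci_high": hi,
                    "rhat": self.rhat.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (rank-free version)."""
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n:2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    b = n * np.var(means, ddof=1)
    w = float(np.mean(np.var(halves, axis=1, ddof=1)))
    if w <= 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def _initial_params(data: PhenologyData, spec: MoultModelSpec,
                    rng: np.random.Generator) -> ModelParams:
    lo, hi = spec.mu_init_window
    span = hi - lo
    dlo, dhi = spec.dbar_range
    return ModelParams(
        mu_init=float(rng.uniform(lo + 0.2 * span, hi - 0.2 * span)),
        dbar=float(rng.uniform(max(dlo, 25.0), min(dhi, 60.0))
                   if dhi > 25.0 else rng.uniform(dlo, dhi)),
        sigma_ind=float(rng.uniform(0.1, min(10.0, spec.sigma_ind_max))),
        sigma_obs=float(rng.uniform(0.5, min(15.0, 0.9 * spec.sigma_obs_max))),
        beta_snow=0.0,
        beta_temp=0.0,
        beta_sex=0.0,
        eps=np.zeros(data.n_hares),
    )


def _run_chain(data: PhenologyData, spec: MoultModelSpec, cfg: MCMCConfig,
               rng: np.random.Generator) -> tuple[dict, np.ndarray, dict]:
    params = _initial_params(data, spec, rng)
    names = list(GLOBAL_PARAMS) if spec.include_covariates else list(GLOBAL_PARAMS[:4])
    scales = {
        "mu_init": 2.0, "dbar": 2.0, "sigma_ind": 1.0, "sigma_obs": 1.0,
        "beta_snow": 0.003, "beta_temp": 0.003, "beta_sex": 1.0,
    }
    eps_scale = 3.0
    shift_scale = 2.0
    shift_acc_window, shift_tries_window = 0, 0
    acc = {name: 0 for name in names}
    tries = {name: 0 for name in names}
    acc_window = {name: 0 for name in names}
    tries_window = {name: 0 for name in names}
    eps_acc_window, eps_tries_window = 0, 0

    lp = log_posterior(params, data, spec)
    total = cfg.n_warmup + cfg.n_draws
    store = {name: np.empty(cfg.n_draws) for name in names}
    store["duration"] = np.empty(cfg.n_draws)
    store["completion"] = np.empty(cfg.n_draws)
    eps_sum = np.zeros(data.n_hares)
    eps_sq = np.zeros(data.n_hares)

    for it in range(total):
        for name in names:
            tries[name] += 1
            tries_window[name] += 1
            prop = replace(params)
            setattr(prop, name, getattr(params, name) + rng.normal(0.0, scales[name]))
            prop.eps = params.eps
            lp_prop = log_posterior(prop, data, spec)
            if np.log(rng.uniform()) < lp_prop - lp:
                params, lp = prop, lp_prop
                acc[name] += 1
                acc_window[name] += 1

        # Elementwise block update of the per-hare effects: conditionally
        # independent given the globals, so accept/reject per hare.
        if data.n_hares:
            eps_tries_window += 1
            cur_obs = _per_obs_loglik(params, data)
            cur_by_hare = np.bincount(data.obs_hare, weights=cur_obs,
                                      minlength=data.n_hares)
            prop_eps = params.eps + rng.normal(0.0, eps_scale, size=data.n_hares)
            prop_params = replace(params, eps=prop_eps)
            prop_obs = _per_obs_loglik(prop_params, data)
            prop_by_hare = np.bincount(data.obs_hare, weights=prop_obs,
                                       minlength=data.n_hares)
            s2 = params.sigma_ind ** 2
            diff = (prop_by_hare - cur_by_hare
                    - 0.5 * (prop_eps ** 2 - params.eps ** 2) / s2)
            keep = np.log(rng.uniform(size=data.n_hares)) < diff
            new_eps = np.where(keep, prop_eps, params.eps)
            params = replace(params, eps=new_eps)
            lp = log_posterior(params, data, spec)
            eps_acc_window += float(np.mean(keep))

        # joint shift of mu_init and the random effects: init_i = mu + eps_i
        # is invariant, so the data term cancels and only the priors decide.
        # Breaks the mu/eps posterior correlation that stalls plain updates.
        if data.n_hares:
            shift_tries_window += 1
            delta = rng.normal(0.0, shift_scale)
            mu_new = params.mu_init + delta
            lo_w, hi_w = spec.mu_init_window
            if lo_w <= mu_new <= hi_w:
                s2 = params.sigma_ind ** 2
                eps_new = params.eps - delta
                dlog = -0.5 * float(np.sum(eps_new ** 2 - params.eps ** 2)) / s2
                if np.log(rng.uniform()) < dlog:
                    params = replace(params, mu_init=mu_new, eps=eps_new)
                    lp = log_posterior(params, data, spec)
                    shift_acc_window += 1

        if it < cfg.n_warmup and (it + 1) % cfg.adapt_interval == 0:
            for name in names:
                rate = acc_window[name] / max(tries_window[name], 1)
                scales[name] *= float(np.exp(rate - cfg.target_accept))
                acc_window[name] = 0
                tries_window[name] = 0
            if eps_tries_window:
                rate = eps_acc_window / eps_tries_window
                eps_scale *= float(np.exp(rate - cfg.target_accept))
                eps_acc_window, eps_tries_window = 0, 0.0
            if shift_tries_window:
                rate = shift_acc_window / shift_tries_window
                shift_scale *= float(np.exp(rate - cfg.target_accept))
                shift_acc_window, shift_tries_window = 0, 0

        if it >= cfg.n_warmup:
            j = it - cfg.n_warmup
            for name in names:
                store[name][j] = getattr(params, name)
            dur = float(effective_duration(
                params.dbar, 0.0, 0.0, 0.0,
                params.beta_snow, params.beta_temp, params.beta_sex,
            ))
            store["duration"][j] = dur
            store["completion"][j] = params.mu_init + dur
            eps_sum += params.eps
            eps_sq += params.eps ** 2

    eps_mean = eps_sum / cfg.n_draws
    eps_var = np.maximum(eps_sq / cfg.n_draws - eps_mean ** 2, 0.0)
    rates = {name: acc[name] / max(tries[name], 1) for name in names}
    return store, np.vstack([eps_mean, np.sqrt(eps_var)]), rates


def fit_changepoint(data: PhenologyData, spec: MoultModelSpec,
                    mcmc: MCMCConfig) -> PhenologyFit:
    """Sample the change-point model posterior.

    Requires at least 2 hares with at least 3 sightings each.  Runs
    ``mcmc.n_chains`` adaptive Metropolis-within-Gibbs chains from
    overdispersed starts; flags (but still returns) a non-converged fit when
    any split-chain R-hat exceeds the configured threshold.
    """
    counts = np.bincount(data.obs_hare, minlength=data.n_hares)
    if data.n_hares < 2 or np.sort(counts)[-2] < 3:
        raise ValueError(
            "fit_changepoint needs >=2 hares with >=3 observations each "
            f"(got {data.n_hares} hares, obs counts {sorted(counts.tolist())})"
        )
    if mcmc.n_chains < 2:
        raise ValueError("need >=2 chains for split-chain convergence checks")

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chain_stores, chain_eps, chain_rates = [], [], []
    for s in seeds:
        store, eps_stats, rates = _run_chain(
            data, spec, mcmc, np.random.Generator(np.random.PCG64(s))
        )
        chain_stores.append(store)
        chain_eps.append(eps_stats)
        chain_rates.append(rates)

    draws = {
        name: np.vstack([c[name] for c in chain_stores])
        for name in chain_stores[0]
    }
    rhat = {name: _split_rhat(draws[name]) for name in draws}
    watched = [n for n in ("mu_init", "dbar", "sigma_obs", "completion") if n in rhat]
    worst = max(rhat[n] for n in watched)
    converged = bool(worst <= mcmc.rhat_threshold)
    warning = None
    if not converged:
        warning = (f"split-chain R-hat {worst:.3f} exceeds "
                   f"{mcmc.rhat_threshold}; treat intervals with caution")

    eps_mean = np.mean([e[0] for e in chain_eps], axis=0)
    eps_sd = np.mean([e[1] for e in chain_eps], axis=0)
    accept = {
        name: float(np.mean([r[name] for r in chain_rates]))
        for name in chain_rates[0]
    }
    return PhenologyFit(
        season=data.season,
        draws=draws,
        hare_ids=data.hare_ids,
        eps_mean=eps_mean,
        eps_sd=eps_sd,
        covariate_means=dict(data.covariate_means),
        accept_rates=accept,
        rhat=rhat,
        converged=converged,
        warning=warning,
        include_covariates=spec.include_covariates,
        seed=mcmc.seed,
    )


def covariate_shift(fit: PhenologyFit, covariate: str, low: float,
                    high: float) -> dict:
    """Posterior of the completion-date shift when one covariate moves.

    Per draw: the difference in completion date between covariate values
    ``high`` and ``low`` with the other covariates held at their sample
    means.  For snow and degree days this is
    ``dbar * (exp(beta*(high - mean)) - exp(beta*(low - mean)))``; for sex
    (codes 0 male / -1 female) it is the additive ``beta_sex * (high - low)``.
    """
    if not fit.include_covariates:
        raise ValueError("fit was run without covariates")
    if covariate not in ("snow", "temp", "sex"):
        raise ValueError(f"unknown covariate {covariate!r}")
    dbar = fit.flat("dbar")
    if covariate == "sex":
        shift = fit.flat("beta_sex") * (high - low)
    else:
        name = "beta_snow" if covariate == "snow" else "beta_temp"
        mean = fit.covariate_means["snow" if covariate == "snow" else "dd"]
        beta = fit.flat(name)
        shift = dbar * (np.exp(beta * (high - mean)) - np.exp(beta * (low - mean)))
    return {
        "mean": float(np.mean(shift)),
        "ci_low": float(np.quantile(shift, 0.025)),
        "ci_high": float(np.quantile(shift, 0.975)),
        "draws": shift,
    }


# ---------------------------------------------------------------------------
# Reaction norms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionNorm:
    """Per-year moult trajectories of one hare observed in >=2 years."""

    hare_id: str
    season: Season
    years: tuple[int, ...]
    trajectories: dict          # year -> list[(day, whiteness)]
    fitted_init: dict           # year -> day (season axis)
    fitted_completion: dict     # year -> day
    init_difference_days: float  # max - min fitted initiation across years


def fit_trajectory_ls(days: np.ndarray, whiteness: np.ndarray,
                      season: Season) -> tuple[float, float]:
    """Least-squares (init, duration) for a single observed trajectory.

    Coarse grid search followed by a local refinement; used for per-hare-year
    reaction-norm fits where a full posterior is unnecessary.
    """
    from scipy.optimize import minimize

    days = np.asarray(days, dtype=float)
    whiteness = np.asarray(whiteness, dtype=float)

    def sse(theta):
        init, dur = theta
        if dur < 1.0:
            return 1e12
        mu = expected_whiteness(days, init, dur, season)
        return float(np.sum((whiteness - mu) ** 2))

    inits = np.arange(days.min() - 60.0, days.max() + 1.0, 3.0)
    durs = np.arange(10.0, 81.0, 5.0)
    best = None
    for i0 in inits:
        for d0 in durs:
            v = sse((i0, d0))
            if best is None or v < best[0]:
                best = (v, i0, d0)
    res = minimize(sse, x0=[best[1], best[2]], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000})
    init, dur = res.x
    return float(init), float(max(dur, 1.0))


def reaction_norms(records: Iterable[HareObservation], season: Season,
                   min_obs: int = 3) -> list[ReactionNorm]:
    """Individual moult reaction norms across years of the same season.

    Only hares with usable trajectories (>= ``min_obs`` sightings) in at
    least two different years of the given season qualify.
    """
    by_hare_year: dict[tuple[str, int], list[HareObservation]] = {}
    for rec in records:
        s, year = moult_season_of(rec.date)
        if s == season:
            by_hare_year.setdefault((rec.hare_id, year), []).append(rec)

    by_hare: dict[str, dict[int, list[HareObservation]]] = {}
    for (hare, year), recs in by_hare_year.items():
        if len(recs) >= min_obs:
            by_hare.setdefault(hare, {})[year] = recs

    out: list[ReactionNorm] = []
    for hare, years in sorted(by_hare.items()):
        if len(years) < 2:
            continue
        trajectories, fitted_init, fitted_comp = {}, {}, {}
        for year, recs in sorted(years.items()):
            anchor = season_anchor(season, year)
            pts = sorted(((r.date - anchor).days, r.whiteness) for r in recs)
            days = np.array([p[0] for p in pts], dtype=float)
            white = np.array([p[1] for p in pts], dtype=float)
            init, dur = fit_trajectory_ls(days, white, season)
            trajectories[year] = pts
            fitted_init[year] = init
            fitted_comp[year] = init + dur
        inits = list(fitted_init.values())
        out.append(
            ReactionNorm(
                hare_id=hare,
                season=season,
                years=tuple(sorted(years)),
                trajectories=trajectories,
                fitted_init=fitted_init,
                fitted_completion=fitted_comp,
                init_difference_days=float(max(inits) - min(inits)),
            )
        )
    return out
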