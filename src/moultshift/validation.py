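"""Simulation-based validation experiments for the whole pipeline.

Each function runs a self-contained parameter-recovery, oracle-equivalence
or calibration experiment on synthetic data and returns plain numbers, so
the same experiments back both the test suite and the reproducibility
script.  Expected values are always produced by an independent route
(closed forms, brute-force summation or grid search, generator truth) —
never by the code path under test.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import behaviour as beh
from . import camouflage as cam
from . import phenology as ph
from . import synthetic as syn
from .observations import SNOW_GRID, WHITENESS_GRID, frame_to_observations

__all__ = [
    "phenology_recovery_experiment",
    "likelihood_oracle_discrepancy",
    "cox_closed_form_checks",
    "resting_bruteforce_discrepancy",
    "resting_recovery_experiment",
    "habituation_experiment",
    "metric_exhaustiveness_checks",
    "null_calibration_experiment",
]


# ---------------------------------------------------------------------------
# Phenology parameter recovery
# ---------------------------------------------------------------------------


def phenology_recovery_experiment(n_reps: int = 20, base_seed: int = 1000,
                                  mcmc_draws: int = 1500) -> dict:
    """Coverage of the generating moult dates by the 95% credible intervals.

    Each replicate simulates the full two-site study design (30 hares per
    site per year, two years) with a fresh seed, fits the change-point model
    to one site's autumn (sites alternate across replicates), and checks
    whether the generating population initiation and completion dates fall
    inside the fitted equal-tailed 95% intervals.
    """
    init_cover = comp_cover = 0
    mu_bias = []
    for rep in range(n_reps):
        site = "gardiner" if rep % 2 else "seeley"
        fx = syn.make_fixture("full_study", seed=base_seed + rep)
        records = frame_to_observations(fx.observations)
        snow = dict(fx.snow[(site, 2010)].items())
        data = ph.prepare_phenology_data(
            records, "autumn", site, 2010,
            temps=fx.temperatures[site], snow_daily=snow)
        fit = ph.fit_changepoint(
            data, ph.MoultModelSpec(season="autumn"),
            ph.MCMCConfig(seed=rep, n_warmup=mcmc_draws, n_draws=mcmc_draws))
        truth = fx.truth
        snow_mean, dd_mean = ph._window_cov_means(
            site, "autumn", 2010, pd.Series(snow), fx.temperatures[site])
        mu_true = truth.mu_init[(site, "autumn")]
        comp_true = mu_true + float(ph.effective_duration(
            truth.dbar["autumn"], snow_mean, dd_mean,
            fit.covariate_means["sex"], truth.beta_snow, truth.beta_temp,
            truth.beta_sex))
        lo, hi = fit.ci("mu_init")
        init_cover += lo <= mu_true <= hi
        lo, hi = fit.ci("completion")
        comp_cover += lo <= comp_true <= hi
        mu_bias.append(fit.posterior_mean("mu_init") - mu_true)
    return {
        "n": n_reps,
        "init_coverage": init_cover / n_reps,
        "completion_coverage": comp_cover / n_reps,
        "mu_init_bias_days": float(np.mean(mu_bias)),
    }


# ---------------------------------------------------------------------------
# Likelihood oracle
# ---------------------------------------------------------------------------


def likelihood_oracle_discrepancy(seed: int = 12, n_fixtures: int = 5) -> float:
    """Max |log_likelihood - brute-force scipy summation| over small fixtures."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        days = np.sort(rng.uniform(40, 110, size=5))
        hare = rng.integers(0, 2, size=5)
        white = rng.choice(np.array(WHITENESS_GRID), size=5)
        eps = rng.normal(0, 3, size=2)
        params = ph.ModelParams(
            mu_init=float(rng.uniform(50, 70)), dbar=float(rng.uniform(30, 50)),
            sigma_ind=float(rng.uniform(2, 6)), sigma_obs=float(rng.uniform(5, 12)),
            eps=eps)
        data = ph.PhenologyData(
            season="autumn", site="x", year=2010, hare_ids=("a", "b"),
            obs_hare=hare, obs_day=days, obs_whiteness=white,
            snow_c=np.zeros(2), dd_c=np.zeros(2), sex_c=np.zeros(2),
            covariate_means={"snow": 0.0, "dd": 0.0, "sex": 0.0})
        expected = 0.0
        for d, h, w in zip(days, hare, white):
            mu = ph.expected_whiteness(d, params.mu_init + eps[h], params.dbar,
                                       "autumn")
            expected += float(stats.norm.logpdf(w, mu, params.sigma_obs))
        for e in eps:
            expected += float(stats.norm.logpdf(e, 0.0, params.sigma_ind))
        worst = max(worst, abs(ph.log_likelihood(params, data) - expected))
    return worst


# ---------------------------------------------------------------------------
# Cox partial likelihood closed forms
# ---------------------------------------------------------------------------


def cox_closed_form_checks(seed: int = 4) -> dict:
    """Null partial log-likelihood against -sum log(risk-set size)."""
    two = abs(beh.cox_partial_loglik([1.0, 2.0], [True, True],
                                     [[1.0], [0.0]], [0.0]) - (-np.log(2.0)))
    rng = np.random.default_rng(seed)
    n = 50
    time = rng.permutation(np.arange(1, n + 1)).astype(float)  # tie-free
    event = rng.uniform(size=n) < 0.7
    X = rng.normal(size=(n, 3))
    ll = beh.cox_partial_loglik(time, event, X, np.zeros(3))
    expected = -sum(np.log(np.sum(time >= t)) for t in time[event])
    return {"two_subject_abs_error": float(two),
            "random_fixture_abs_error": float(abs(ll - expected))}


# ---------------------------------------------------------------------------
# Resting-spot oracle and recovery
# ---------------------------------------------------------------------------


def _choice_observation(hare, date, used_snow, slices, whiteness=100.0):
    row = {"hare_id": hare, "site": "gardiner", "date": date, "sex": "male",
           "whiteness": whiteness, "snow1m": used_snow, "snow10m": used_snow,
           "concealment": 1, "fid_m": None, "fled": None, "attempt_index": 1}
    for i, s in enumerate(slices):
        row[f"slice_{i + 1}"] = s
    return row


def simulate_choice_rows(n_locations: int, beta: float, seed: int,
                         snow_spread: float = 25.0) -> pd.DataFrame:
    """Used-available rows from a log-linear 1-of-9 choice process."""
    rng = np.random.default_rng(seed)
    grid = np.asarray(SNOW_GRID)
    obs = []
    for i in range(n_locations):
        local = rng.uniform(0, 100)
        cand = syn.snap_to_grid(
            np.clip(local + rng.normal(0, snow_spread, size=9), 0, 100), grid)
        pref = np.exp(beta * cand)
        used = int(rng.choice(9, p=pref / pref.sum()))
        slices = [c for j, c in enumerate(cand) if j != used]
        obs.append(_choice_observation(
            f"h{i % 40}", f"2011-01-{1 + i % 28:02d}T{i}",
            float(cand[used]), slices))
    return beh.build_choice_rows(pd.DataFrame(obs))


def resting_bruteforce_discrepancy(seed: int = 8, n_locations: int = 10) -> float:
    """|GLM slope - grid-search MLE of the exact binomial likelihood|."""
    rows = simulate_choice_rows(n_locations, -0.016, seed=seed)
    fit = beh.fit_resting_spot(rows, random_effects=False)
    x = rows["snow"].to_numpy(float)
    y = rows["used"].to_numpy(float)

    def negll(theta):
        eta = theta[0] + theta[1] * x
        return -np.sum(y * eta - np.log1p(np.exp(eta)))

    grid = [(a, b) for a in np.linspace(-5, 2, 71)
            for b in np.linspace(-0.2, 0.2, 81)]
    a0, b0 = min(grid, key=negll)
    res = optimize.minimize(negll, [a0, b0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    return float(abs(fit.snow["glm_coef"] - res.x[1]))


def resting_recovery_experiment(n_reps: int = 20, base_seed: int = 700,
                                n_locations: int = 300,
                                beta: float = -0.016) -> dict:
    """Conditional-logit recovery of the generating snow preference."""
    hits = 0
    estimates = []
    for rep in range(n_reps):
        rows = simulate_choice_rows(n_locations, beta, seed=base_seed + rep)
        fit = beh.fit_resting_spot(rows, random_effects=False)
        est = fit.snow["conditional_coef"]
        se = fit.snow["conditional_se"]
        hits += abs(est - beta) <= 2.0 * se
        estimates.append(est)
    return {"n": n_reps, "within_2se_rate": hits / n_reps,
            "mean_estimate": float(np.mean(estimates))}


# ---------------------------------------------------------------------------
# Habituation truncation
# ---------------------------------------------------------------------------


def _habituation_truth(onset: int | None) -> syn.SyntheticTruth:
    """Habituation-only generator: no other concealment structure."""
    big = 10**6
    return syn.SyntheticTruth(
        conceal_season={"winter": 0, "spring": 0, "summer": 0, "autumn": 0},
        conceal_site={"seeley": 0, "gardiner": 0},
        conceal_contrast=0.0, conceal_contrast2=0.0,
        conceal_habituation_onset=big if onset is None else onset,
        weekly_mortality=0.0, detection_prob=1.0,
        fid_trial_prob=0.0, slices_prob=0.0,
        entry_stagger_weeks=0)


def habituation_experiment(n_reps: int = 20, base_seed: int = 300,
                           onset: int = 9, n_hares: int = 60,
                           max_attempts: int = 14) -> dict:
    """Recovery of a known habituation onset plus the flat-response control."""
    scen = [s for s in syn.default_scenarios([2010]) if s.site == "gardiner"]
    recovered = 0
    for rep in range(n_reps):
        frame, _ = syn.simulate_hares(_habituation_truth(onset), scen,
                                      n_hares, [2010], seed=base_seed + rep)
        frame = frame[frame["attempt_index"] <= max_attempts]
        res = beh.habituation_truncation(frame, "concealment")
        recovered += res.truncation_index == onset
    flat, _ = syn.simulate_hares(_habituation_truth(None), scen, n_hares,
                                 [2010], seed=base_seed)
    flat = flat[flat["attempt_index"] <= max_attempts]
    flat_res = beh.habituation_truncation(flat, "concealment")
    return {
        "n": n_reps,
        "recovery_rate": recovered / n_reps,
        "flat_truncation_index": flat_res.truncation_index,
        "flat_max_attempt": int(flat["attempt_index"].max()),
    }


# ---------------------------------------------------------------------------
# Metric exhaustiveness
# ---------------------------------------------------------------------------


def metric_exhaustiveness_checks() -> dict:
    """Mismatch classification over every legal grid pair; degree-day sums."""
    import datetime as dt
    from .observations import TemperatureSeries

    disagreements = 0
    n_pairs = 0
    for w, s in itertools.product(WHITENESS_GRID, SNOW_GRID):
        n_pairs += 1
        c = cam.colour_contrast(w, s)
        expected = ("positive" if c >= 60
                    else "negative" if c <= -60 else "none")
        if cam.classify_mismatch(c) != expected:
            disagreements += 1

    def series(start, temps):
        dates = tuple(start + dt.timedelta(days=i) for i in range(len(temps)))
        return TemperatureSeries(site="x", dates=dates, tmean_c=tuple(temps))

    autumn = cam.degree_days(series(dt.date(2011, 10, 1), [-2.0, 3.0, -1.0]),
                             "autumn")[0].dd
    spring = cam.degree_days(series(dt.date(2011, 4, 1), [1.0, -2.0, 4.0]),
                             "spring")[0].dd
    dd_err = max(abs(a - b) for a, b in zip(autumn, (2.0, 2.0, 3.0)))
    dd_err = max(dd_err, max(abs(a - b) for a, b in zip(spring, (1.0, 1.0, 5.0))))
    return {"n_grid_pairs": n_pairs, "mismatch_disagreements": disagreements,
            "degree_day_abs_error": float(dd_err)}


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------


def _null_truth() -> syn.SyntheticTruth:
    big = 10**6
    return syn.SyntheticTruth(
        conceal_season={"winter": 0, "spring": 0, "summer": 0, "autumn": 0},
        conceal_site={"seeley": 0, "gardiner": 0},
        conceal_contrast=0.0, conceal_contrast2=0.0,
        conceal_habituation_onset=big, fid_habituation_onset=big,
        fid_beta_concealment=0.0,
        fid_site={"seeley": 0.0, "gardiner": 0.0},
        fid_season={"winter": 0, "spring": 0, "summer": 0, "autumn": 0},
        fid_sex_female=0.0,
        fid_mismatch_negative=0.0, fid_mismatch_positive=0.0,
        resting_beta_snow=0.0)


def null_calibration_experiment(n_reps: int = 20, base_seed: int = 500,
                                n_hares: int = 30) -> dict:
    """95% interval coverage of zero under data with no behavioural effects."""
    scen = [s for s in syn.default_scenarios([2010]) if s.site == "gardiner"]
    cov_c = cov_f = cov_r = 0
    for rep in range(n_reps):
        frame, _ = syn.simulate_hares(_null_truth(), scen, n_hares, [2010],
                                      seed=base_seed + rep)
        frame["contrast1m"] = frame["whiteness"] - frame["snow1m"]
        frame["contrast10m"] = frame["whiteness"] - frame["snow10m"]

        fit_c = beh.fit_concealment(
            frame, beh.CandidateSet(models=(("contrast1m",),),
                                    excluded_pairs=()),
            seed=rep, n_samples=20_000)
        row = fit_c.coefficients.set_index("term").loc["contrast1m"]
        cov_c += row["hpd_low"] <= 0.0 <= row["hpd_high"]

        fit_f = beh.fit_fid(
            frame, beh.CandidateSet(models=(("contrast10m",),),
                                    excluded_pairs=()))
        r = fit_f.coefficients.iloc[0]
        cov_f += r["ci_low"] <= 0.0 <= r["ci_high"]

        rows = beh.build_choice_rows(frame)
        fit_r = beh.fit_resting_spot(rows, random_effects=False)
        est = fit_r.snow["conditional_coef"]
        se = fit_r.snow["conditional_se"]
        cov_r += abs(est) <= 1.96 * se
    return {"n": n_reps,
            "concealment_coverage": cov_c / n_reps,
            "fid_coverage": cov_f / n_reps,
            "resting_coverage": cov_r / n_reps}
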