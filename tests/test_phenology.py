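import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from moultshift import phenology as ph
from moultshift import synthetic as syn
from moultshift.observations import frame_to_observations


def _tiny_data(days, whiteness, hare=None, n_hares=1, season="autumn"):
    days = np.asarray(days, dtype=float)
    hare = np.zeros(len(days), dtype=int) if hare is None else np.asarray(hare)
    return ph.PhenologyData(
        season=season, site="gardiner", year=2010,
        hare_ids=tuple(f"h{i}" for i in range(n_hares)),
        obs_hare=hare, obs_day=days,
        obs_whiteness=np.asarray(whiteness, dtype=float),
        snow_c=np.zeros(n_hares), dd_c=np.zeros(n_hares),
        sex_c=np.zeros(n_hares),
        covariate_means={"snow": 0.0, "dd": 0.0, "sex": 0.0},
    )


class TestTrajectory:
    def test_pre_initiation_is_brown(self):
        assert ph.expected_whiteness(10.0, 50.0, 40.0, "autumn") == 0.0

    def test_midpoint_of_ramp(self):
        assert ph.expected_whiteness(70.0, 50.0, 40.0, "autumn") == 50.0

    def test_spring_clamps_to_brown_after_completion(self):
        assert ph.expected_whiteness(500.0, 50.0, 40.0, "spring") == 0.0

    def test_monotone_and_bounded(self):
        t = np.linspace(-50, 250, 400)
        w = ph.expected_whiteness(t, 60.0, 40.0, "autumn")
        assert np.all(np.diff(w) >= 0) and w.min() >= 0 and w.max() <= 100
        w = ph.expected_whiteness(t, 60.0, 40.0, "spring")
        assert np.all(np.diff(w) <= 0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            ph.expected_whiteness(10.0, 5.0, 0.0, "autumn")


class TestEffectiveDuration:
    def test_null_covariates_return_base(self):
        assert ph.effective_duration(41.9, 50.0, 100.0, -1.0) == 41.9

    def test_snow_slows_the_spring_moult(self):
        base = ph.effective_duration(41.9, 0.0, 0.0, 0.0, beta_snow=0.0007)
        snowy = ph.effective_duration(41.9, 100.0, 0.0, 0.0, beta_snow=0.0007)
        assert snowy > base

    def test_female_offset_sign_convention(self):
        male = ph.effective_duration(40.0, 0.0, 0.0, 0.0, beta_sex=2.0)
        female = ph.effective_duration(40.0, 0.0, 0.0, -1.0, beta_sex=2.0)
        assert female == male - 2.0

    def test_floor_at_one_day(self):
        assert ph.effective_duration(2.0, 0.0, 0.0, -1.0, beta_sex=5.0) == 1.0


class TestLogLikelihood:
    def test_single_on_trajectory_closed_form(self):
        # observation exactly on the ramp; N(0 | 0, 10^2) log density
        data = _tiny_data([70.0], [50.0])
        params = ph.ModelParams(mu_init=50.0, dbar=40.0, sigma_ind=5.0,
                                sigma_obs=10.0, eps=np.zeros(1))
        expected = float(stats.norm.logpdf(0.0, 0.0, 10.0)
                         + stats.norm.logpdf(0.0, 0.0, 5.0))
        assert ph.log_likelihood(params, data) == pytest.approx(expected, abs=1e-12)
        # the data term alone is -log(10 sqrt(2 pi)) ~ -3.2215
        assert float(stats.norm.logpdf(0.0, 0.0, 10.0)) == pytest.approx(
            -3.2215, abs=5e-5)

    def test_duplication_doubles_data_term(self):
        data1 = _tiny_data([70.0, 95.0], [40.0, 100.0])
        data2 = _tiny_data([70.0, 95.0] * 2, [40.0, 100.0] * 2)
        params = ph.ModelParams(mu_init=50.0, dbar=40.0, sigma_ind=5.0,
                                sigma_obs=8.0, eps=np.zeros(1))
        re_term = float(stats.norm.logpdf(0.0, 0.0, 5.0))
        d1 = ph.log_likelihood(params, data1) - re_term
        d2 = ph.log_likelihood(params, data2) - re_term
        assert d2 == pytest.approx(2.0 * d1, abs=1e-9)

    def test_matches_bruteforce_summation_oracle(self):
        # independent per-observation summation with scipy on a 5-obs fixture
        rng = np.random.default_rng(12)
        days = np.array([55.0, 62.0, 70.0, 81.0, 92.0])
        hare = np.array([0, 0, 1, 1, 1])
        white = np.array([0.0, 20.0, 60.0, 80.0, 100.0])
        data = _tiny_data(days, white, hare=hare, n_hares=2)
        params = ph.ModelParams(mu_init=58.0, dbar=35.0, sigma_ind=4.0,
                                sigma_obs=7.0, eps=np.array([1.5, -2.0]))
        expected = 0.0
        for d, h, w in zip(days, hare, white):
            mu = ph.expected_whiteness(d, 58.0 + params.eps[h], 35.0, "autumn")
            expected += float(stats.norm.logpdf(w, mu, 7.0))
        for e in params.eps:
            expected += float(stats.norm.logpdf(e, 0.0, 4.0))
        assert ph.log_likelihood(params, data) == pytest.approx(expected,
                                                                abs=1e-9)

    def test_degenerate_observation_sd(self):
        data = _tiny_data([70.0], [40.0])
        params = ph.ModelParams(mu_init=50.0, dbar=40.0, sigma_ind=5.0,
                                sigma_obs=0.0, eps=np.zeros(1))
        assert ph.log_likelihood(params, data) == -np.inf


def _prepared(seed, sigma_ind=None, sigma_obs=None, n_hares=12):
    kwargs = {}
    if sigma_ind is not None:
        kwargs["sigma_ind"] = sigma_ind
    if sigma_obs is not None:
        kwargs["sigma_obs"] = sigma_obs
    truth = syn.SyntheticTruth(detection_prob=1.0, weekly_mortality=0.0,
                               fid_trial_prob=0.0, slices_prob=0.0,
                               entry_stagger_weeks=0, **kwargs)
    scen = [s for s in syn.default_scenarios([2010]) if s.site == "gardiner"]
    frame, truth = syn.simulate_hares(truth, scen, n_hares, [2010], seed=seed)
    records = frame_to_observations(frame)
    data = ph.prepare_phenology_data(records, "autumn", "gardiner", 2010)
    return data, truth


class TestFitChangepoint:
    CFG = ph.MCMCConfig(seed=2, n_warmup=400, n_draws=400)

    def test_seeded_sampler_is_deterministic(self):
        data, _ = _prepared(seed=5, n_hares=6)
        spec = ph.MoultModelSpec(season="autumn", include_covariates=False)
        f1 = ph.fit_changepoint(data, spec, self.CFG)
        f2 = ph.fit_changepoint(data, spec, self.CFG)
        for name in f1.draws:
            np.testing.assert_array_equal(f1.draws[name], f2.draws[name])

    def test_noise_free_recovery_within_one_day(self):
        data, truth = _prepared(seed=5, sigma_ind=0.0, sigma_obs=2.0)
        spec = ph.MoultModelSpec(season="autumn", include_covariates=False)
        fit = ph.fit_changepoint(data, spec, self.CFG)
        assert abs(fit.posterior_mean("mu_init")
                   - truth.mu_init[("gardiner", "autumn")]) < 1.0
        # completion > initiation in every retained draw
        assert np.all(fit.flat("completion") > fit.flat("mu_init"))

    def test_posterior_concentrates_as_obs_noise_prior_mass_shrinks(self):
        # fixed data; as the sigma_obs prior concentrates towards zero the
        # mu_init posterior must tighten (3-level monotonicity)
        rng = np.random.default_rng(6)
        n_hares, days = 12, np.arange(20.0, 150.0, 7.0)
        hare = np.repeat(np.arange(n_hares), len(days))
        t = np.tile(days, n_hares)
        white = np.asarray(ph.expected_whiteness(t, 55.0, 40.0, "autumn"))
        white = np.clip(white + rng.normal(0.0, 8.0, size=white.size), 0, 100)
        data = _tiny_data(t, white, hare=hare, n_hares=n_hares)
        widths = []
        for cap in (40.0, 5.0, 1.5):
            spec = ph.MoultModelSpec(season="autumn", include_covariates=False,
                                     sigma_obs_max=cap)
            fit = ph.fit_changepoint(data, spec, self.CFG)
            lo, hi = fit.ci("mu_init")
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_too_few_observations_rejected(self):
        data, _ = _prepared(seed=5, n_hares=6)
        starved = dataclasses.replace(
            data,
            obs_hare=data.obs_hare[:3], obs_day=data.obs_day[:3],
            obs_whiteness=data.obs_whiteness[:3])
        with pytest.raises(ValueError, match="hares"):
            ph.fit_changepoint(starved, ph.MoultModelSpec(season="autumn"),
                               self.CFG)


def _fake_fit(beta_snow_draws, dbar=40.0):
    n = len(beta_snow_draws)
    draws = {
        "mu_init": np.full((2, n // 2), 60.0),
        "dbar": np.full((2, n // 2), dbar),
        "beta_snow": np.asarray(beta_snow_draws).reshape(2, n // 2),
        "beta_temp": np.zeros((2, n // 2)),
        "beta_sex": np.zeros((2, n // 2)),
    }
    return ph.PhenologyFit(
        season="spring", draws=draws, hare_ids=("h0",),
        eps_mean=np.zeros(1), eps_sd=np.zeros(1),
        covariate_means={"snow": 50.0, "dd": 0.0, "sex": 0.0},
        accept_rates={}, rhat={}, converged=True, warning=None,
        include_covariates=True, seed=0)


class TestCovariateShift:
    def test_zero_coefficient_means_zero_shift(self):
        fit = _fake_fit(np.zeros(100))
        out = ph.covariate_shift(fit, "snow", 0.0, 100.0)
        assert out["mean"] == 0.0

    def test_shift_sign_follows_coefficient_sign(self):
        up = ph.covariate_shift(_fake_fit(np.full(100, 0.002)), "snow", 0, 100)
        down = ph.covariate_shift(_fake_fit(np.full(100, -0.002)), "snow", 0, 100)
        assert up["mean"] > 0 > down["mean"]

    def test_matches_analytic_formula(self):
        beta, dbar = 0.0007, 41.9
        fit = _fake_fit(np.full(100, beta), dbar=dbar)
        out = ph.covariate_shift(fit, "snow", 0.0, 100.0)
        expected = dbar * (np.exp(beta * 50.0) - np.exp(-beta * 50.0))
        assert out["mean"] == pytest.approx(expected, abs=1e-12)

    def test_requires_covariates_in_fit(self):
        fit = _fake_fit(np.zeros(100))
        fit.include_covariates = False
        with pytest.raises(ValueError):
            ph.covariate_shift(fit, "snow", 0, 100)
        fit.include_covariates = True
        with pytest.raises(ValueError):
            ph.covariate_shift(fit, "moon", 0, 100)


def _trajectory_records(hare, year, init, dur, season="spring", step=7):
    import datetime as dt
    from moultshift.observations import HareObservation

    anchor = ph.season_anchor(season, year)
    recs = []
    for i, day in enumerate(range(20, 160, step)):
        w = float(ph.expected_whiteness(day, init, dur, season))
        w = float(syn.snap_to_grid(w, np.array([0, 5, 20, 40, 60, 80, 95, 100]))[0])
        recs.append(HareObservation(
            hare_id=hare, site="gardiner",
            date=anchor + dt.timedelta(days=day), sex="male",
            whiteness=w, snow1m=0.0, snow10m=0.0, attempt_index=i + 1))
    return recs


class TestReactionNorms:
    def test_single_year_hare_excluded(self):
        recs = _trajectory_records("h1", 2011, 90.0, 40.0)
        assert ph.reaction_norms(recs, "spring") == []

    def test_identical_years_give_zero_difference(self):
        recs = (_trajectory_records("h1", 2011, 90.0, 40.0)
                + _trajectory_records("h1", 2012, 90.0, 40.0))
        (norm,) = ph.reaction_norms(recs, "spring")
        assert norm.years == (2011, 2012)
        assert norm.init_difference_days == pytest.approx(0.0, abs=1.5)

    def test_fifteen_day_shift_recovered(self):
        recs = (_trajectory_records("h1", 2011, 80.0, 40.0)
                + _trajectory_records("h1", 2012, 95.0, 40.0))
        (norm,) = ph.reaction_norms(recs, "spring")
        assert norm.init_difference_days == pytest.approx(15.0, abs=3.0)
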