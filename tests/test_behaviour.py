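import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from moultshift import behaviour as beh
from moultshift import synthetic as syn


class TestAICc:
    def test_direct_formula_value(self):
        assert beh.aicc(-5.0, 2, 10) == pytest.approx(10 + 4 + 12 / 7, abs=1e-9)

    def test_zero_parameters(self):
        assert beh.aicc(-5.0, 0, 10) == 10.0

    def test_large_n_limit_equals_aic(self):
        assert beh.aicc(-5.0, 3, 10**9) == pytest.approx(16.0, abs=1e-6)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            beh.aicc(-5.0, 4, 5)

    def test_ranking_invariant_to_loglik_shift(self):
        lls = [-10.0, -12.5, -9.0]
        ks = [2, 3, 4]
        base = [beh.aicc(ll, k, 50) for ll, k in zip(lls, ks)]
        shifted = [beh.aicc(ll + 7.0, k, 50) for ll, k in zip(lls, ks)]
        assert np.argsort(base).tolist() == np.argsort(shifted).tolist()


class TestBuildCandidates:
    CORR = pd.DataFrame(
        [[1.0, 0.85, -0.5], [0.85, 1.0, 0.1], [-0.5, 0.1, 1.0]],
        index=["whiteness", "snow1m", "contrast1m"],
        columns=["whiteness", "snow1m", "contrast1m"],
    )

    def test_highly_correlated_pair_never_co_included(self):
        cands = beh.build_candidates(["whiteness", "snow1m", "contrast1m"],
                                     self.CORR)
        for model in cands:
            assert not ("whiteness" in model and "snow1m" in model)

    def test_moderately_correlated_pair_allowed(self):
        cands = beh.build_candidates(["whiteness", "snow1m", "contrast1m"],
                                     self.CORR)
        assert any("snow1m" in m and "contrast1m" in m for m in cands)

    def test_quadratic_only_with_linear(self):
        cands = beh.build_candidates(["contrast1m", "snow1m"], self.CORR,
                                     quadratic_for=("contrast1m",))
        for model in cands:
            if "contrast1m^2" in model:
                assert "contrast1m" in model

    def test_null_model_present_and_empty_terms_rejected(self):
        cands = beh.build_candidates(["contrast1m"], self.CORR)
        assert () in tuple(cands)
        with pytest.raises(ValueError):
            beh.build_candidates([], self.CORR)


def _habituation_frame(rng, n_hares=30, n_attempts=12, onset=None, slope=0.0,
                       step=0.0):
    rows = []
    for h in range(n_hares):
        base = 2.5 + rng.normal(0, 0.3)
        for a in range(1, n_attempts + 1):
            y = base + rng.normal(0, 0.6)
            if onset is not None and a > onset:
                y -= step + slope * (a - onset)
            rows.append({"hare_id": f"h{h}", "attempt_index": a,
                         "concealment": y, "fid_m": np.nan})
    return pd.DataFrame(rows)


class TestHabituationTruncation:
    def test_flat_response_keeps_everything(self):
        frame = _habituation_frame(np.random.default_rng(1))
        res = beh.habituation_truncation(frame, "concealment")
        assert res.truncation_index == 12
        assert len(res.truncated) == len(frame)
        assert res.warning is None

    def test_monotone_decline_from_first_attempt_warns(self):
        frame = _habituation_frame(np.random.default_rng(2), onset=0,
                                   slope=0.5)
        res = beh.habituation_truncation(frame, "concealment")
        assert res.truncation_index == 3
        assert res.warning is not None

    def test_decline_after_onset_recovered(self):
        frame = _habituation_frame(np.random.default_rng(3), n_hares=60,
                                   onset=8, slope=0.5, step=1.0)
        res = beh.habituation_truncation(frame, "concealment")
        assert res.truncation_index == 8

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            beh.habituation_truncation(pd.DataFrame(), "weight")


class TestCoxPartialLoglik:
    def test_two_subject_hand_computation(self):
        # events at progress 1 and 2; at beta=0 risk sets have sizes 2 and 1
        ll = beh.cox_partial_loglik([1.0, 2.0], [True, True],
                                    [[1.0], [0.0]], [0.0])
        assert ll == pytest.approx(-np.log(2.0), abs=1e-12)

    def test_null_closed_form_on_tie_free_fixture(self):
        rng = np.random.default_rng(4)
        n = 40
        time = rng.permutation(np.arange(1, n + 1)).astype(float)
        event = rng.uniform(size=n) < 0.7
        X = rng.normal(size=(n, 2))
        ll = beh.cox_partial_loglik(time, event, X, np.zeros(2))
        expected = -sum(np.log(np.sum(time >= t)) for t in time[event])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_lifelines_at_fitted_coefficients(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        event = t < np.quantile(t, 0.8)
        t = np.minimum(t, np.quantile(t, 0.8))
        df = pd.DataFrame({"t": t, "e": event, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        ours = beh.cox_partial_loglik(t, event, x[:, None],
                                      cph.params_.to_numpy())
        assert ours == pytest.approx(float(cph.log_likelihood_), abs=1e-6)
        # and our evaluation is maximised near the lifelines estimate
        betas = np.linspace(-0.5, 1.5, 41)
        lls = [beh.cox_partial_loglik(t, event, x[:, None], [b]) for b in betas]
        assert abs(betas[int(np.argmax(lls))]
                   - float(cph.params_.iloc[0])) < 0.06


class TestFitFID:
    def test_constant_covariate_dropped_with_warning(self, behaviour_frame):
        frame = behaviour_frame.copy()
        frame["constant"] = 1.0
        cands = beh.CandidateSet(models=((), ("constant",), ("concealment",)),
                                 excluded_pairs=())
        fit = beh.fit_fid(frame, cands)
        assert "constant" in fit.dropped_terms
        assert any("constant" in note for note in fit.warnings_)

    def test_event_and_censoring_bookkeeping(self, behaviour_frame):
        cands = beh.CandidateSet(models=((), ("concealment",)),
                                 excluded_pairs=())
        fit = beh.fit_fid(behaviour_frame, cands)
        n_trials = int(behaviour_frame["fid_m"].notna().sum())
        assert fit.n_events + fit.n_censored == n_trials
        assert (fit.coefficients["hazard_ratio"] > 0).all()
        assert not fit.proportionality.empty

    def test_no_events_rejected(self, behaviour_frame):
        frame = behaviour_frame.copy()
        frame.loc[frame["fid_m"].notna(), "fled"] = False
        frame.loc[frame["fid_m"].notna(), "fid_m"] = 3.0
        with pytest.raises(ValueError, match="event"):
            beh.fit_fid(frame, beh.CandidateSet(models=((),),
                                                excluded_pairs=()))


def _choice_obs(hare, date, used_snow, slices, whiteness=100.0):
    row = {"hare_id": hare, "site": "gardiner", "date": date, "sex": "male",
           "whiteness": whiteness, "snow1m": used_snow, "snow10m": used_snow,
           "concealment": 1, "fid_m": None, "fled": None, "attempt_index": 1}
    for i, s in enumerate(slices):
        row[f"slice_{i + 1}"] = s
    return row


class TestBuildChoiceRows:
    def test_nine_rows_per_retained_location(self):
        frame = pd.DataFrame([
            _choice_obs("h1", "2011-01-01", 40.0, [0, 20, 0, 40, 0, 0, 20, 0]),
            _choice_obs("h2", "2011-01-02", 0.0, [0] * 8),     # all snow-free
            _choice_obs("h3", "2011-01-03", 100.0, [100] * 8),  # all snow-covered
            _choice_obs("h4", "2011-01-04", 100.0, [100] * 7 + [80]),  # boundary
        ])
        rows = beh.build_choice_rows(frame)
        assert len(rows) == 18  # h1 and h4 retained
        assert set(rows.hare_id) == {"h1", "h4"}
        assert (rows.groupby("location_id").used.sum() == 1).all()

    def test_exclusion_filter_idempotent(self, full_study_fixture):
        rows = beh.build_choice_rows(full_study_fixture.observations)
        n_loc = rows.location_id.nunique()
        assert len(rows) == 9 * n_loc
        # re-expanding the retained sightings changes nothing
        kept = full_study_fixture.observations.copy()
        keys = set(rows.location_id)
        kept["loc"] = kept.hare_id + "@" + kept.date
        again = beh.build_choice_rows(kept[kept["loc"].isin(keys)])
        assert len(again) == len(rows)

    def test_partial_slices_rejected(self):
        obs = _choice_obs("h1", "2011-01-01", 40.0, [0, 20, 0, 40, 0, 0, 20, 0])
        obs["slice_8"] = None
        with pytest.raises(ValueError, match="8"):
            beh.build_choice_rows(pd.DataFrame([obs]))


def _choice_fixture(n_locations, beta, seed, snow_spread=25.0):
    """Locations with 9 candidate spots; used spot drawn by log-linear preference."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_locations):
        local = rng.uniform(0, 100)
        cand = syn.snap_to_grid(
            np.clip(local + rng.normal(0, snow_spread, size=9), 0, 100),
            np.array([0.0, 20.0, 40.0, 60.0, 80.0, 100.0]))
        pref = np.exp(beta * cand)
        used = int(rng.choice(9, p=pref / pref.sum()))
        slices = [c for j, c in enumerate(cand) if j != used]
        frames.append(_choice_obs(f"h{i % 40}", f"2011-01-{1 + i % 28:02d}T{i}",
                                  float(cand[used]), slices))
    return beh.build_choice_rows(pd.DataFrame(frames))


class TestRestingSpot:
    def test_glm_matches_bruteforce_grid_search(self):
        """Slope agrees with direct maximisation of the exact binomial likelihood."""
        rows = _choice_fixture(10, -0.016, seed=8)
        fit = beh.fit_resting_spot(rows, random_effects=False)
        x = rows.snow.to_numpy(float)
        y = rows.used.to_numpy(float)

        def negll(theta):
            eta = theta[0] + theta[1] * x
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        # coarse grid then polish, independent of the GLM route
        grid = [(a, b) for a in np.linspace(-5, 2, 71)
                for b in np.linspace(-0.2, 0.2, 81)]
        a0, b0 = min(grid, key=negll)
        res = optimize.minimize(negll, [a0, b0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.snow["glm_coef"] == pytest.approx(res.x[1], abs=1e-3)

    def test_conditional_logit_recovers_generating_preference(self):
        rows = _choice_fixture(400, -0.016, seed=9)
        fit = beh.fit_resting_spot(rows, random_effects=False)
        est, se = fit.snow["conditional_coef"], fit.snow["conditional_se"]
        assert abs(est - (-0.016)) < 2 * se

    def test_probability_ratio_consistent_with_curve(self):
        rows = _choice_fixture(120, -0.016, seed=10)
        fit = beh.fit_resting_spot(rows, random_effects=False)
        p0 = float(fit.curve.loc[fit.curve.snow == 0, "prob"].iloc[0])
        p100 = float(fit.curve.loc[fit.curve.snow == 100, "prob"].iloc[0])
        assert fit.prob_ratio == pytest.approx(p0 / p100, abs=1e-9)
        assert ((fit.curve.prob > 0) & (fit.curve.prob < 1)).all()

    def test_aicc_favours_snow_model_under_preference(self):
        rows = _choice_fixture(400, -0.016, seed=11)
        fit = beh.fit_resting_spot(rows, random_effects=False)
        assert fit.aicc_snow < fit.aicc_null

    def test_too_few_locations_rejected(self):
        rows = _choice_fixture(1, -0.016, seed=12)
        with pytest.raises(ValueError):
            beh.fit_resting_spot(rows)


class TestFitConcealment:
    def test_quadratic_contrast_curvature_recovered(self, behaviour_frame):
        """Data generated with a concave contrast effect select it and keep its sign."""
        truth = syn.SyntheticTruth(
            conceal_season={"winter": 0, "spring": 0, "summer": 0, "autumn": 0},
            conceal_site={"seeley": 0, "gardiner": 0},
            conceal_contrast=0.03, conceal_contrast2=-0.0006,
            conceal_habituation_onset=10**6,
            weekly_mortality=0.0, detection_prob=1.0,
            fid_trial_prob=0.0, slices_prob=0.0)
        scen = [s for s in syn.default_scenarios([2010])]
        frame, _ = syn.simulate_hares(truth, scen, 40, [2010], seed=21)
        frame["contrast1m"] = frame.whiteness - frame.snow1m
        corr = frame[["whiteness", "snow1m", "contrast1m"]].corr()
        cands = beh.build_candidates(["contrast1m"], corr,
                                     quadratic_for=("contrast1m",))
        fit = beh.fit_concealment(frame, cands, seed=0, n_samples=20_000)
        assert ("contrast1m", "contrast1m^2") in fit.best_models
        quad = fit.coefficients.loc[
            fit.coefficients.term.str.contains("\\*\\* 2"), "estimate"]
        assert float(quad.iloc[0]) < 0

    def test_best_set_and_hpd_structure(self, behaviour_frame):
        corr = behaviour_frame[["whiteness", "snow1m", "contrast1m"]].corr()
        cands = beh.build_candidates(["contrast1m", "site"], corr)
        fit = beh.fit_concealment(behaviour_frame, cands, seed=0,
                                  n_samples=20_000)
        assert len(fit.best_models) >= 1
        assert (fit.table.delta_aicc >= 0).all()
        assert (fit.coefficients.hpd_low <= fit.coefficients.hpd_high).all()
        assert fit.posterior_method == "normal_approximation_at_ml_mode"
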