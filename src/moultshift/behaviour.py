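"""Anti-predatory behaviour analyses.

Three questions, one per fitted family:

* **Concealment** — do hares hide in vegetation more when colour-mismatched?
  Linear mixed models of the ordinal 1-4 concealment score with a random
  intercept per hare, candidate fixed-effect sets screened for collinearity
  (|r| >= 0.8) and ranked by AICc; the precision of the best model's fixed
  effects is summarised by 95% HPD intervals of a 100 000-draw sample.
* **Flight initiation distance (FID)** — do mismatched hares flee sooner?
  Cox proportional-hazards regression on the 20->3 m approach, flight being
  the event; "no flush" trials are right-censored at the 3-m minimum
  approach.  Efron handling of metre-rounded ties; proportionality checked
  with score tests on scaled Schoenfeld residuals.
* **Resting spots** — do hares choose the spot in their immediate vicinity
  that minimises contrast (or snow)?  Used-available binomial logit over the
  chosen 1-m spot versus the eight surrounding "pie slices", with random
  effects for hare and location, plus an exact conditional-logit fit over
  the 1-of-9 choice sets as a cross-check.

Both behavioural datasets are first truncated for habituation to the human
observer: the response is regressed on the cumulative location attempt and
the data cut back to the largest attempt count at which no significant
decline is detectable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "HabituationResult",
    "CandidateSet",
    "ConcealmentFit",
    "FIDFit",
    "RestingSpotFit",
    "aicc",
    "habituation_truncation",
    "build_candidates",
    "fit_concealment",
    "cox_partial_loglik",
    "prepare_fid_frame",
    "fit_fid",
    "build_choice_rows",
    "conditional_logit",
    "fit_resting_spot",
]

FID_PROGRESS_CENSOR = 17.0  # metres of approach from 20 m down to the 3-m minimum


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc needs n > k+1 (got n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# ---------------------------------------------------------------------------
# Habituation truncation
# ---------------------------------------------------------------------------


@dataclass
class HabituationResult:
    response: str
    truncation_index: int
    table: pd.DataFrame          # per-k slope, se, ci, n
    truncated: pd.DataFrame      # rows with attempt_index <= truncation_index
    warning: str | None = None


def _attempt_slope(frame: pd.DataFrame, response: str) -> tuple[float, float]:
    """Slope (and SE) of response ~ attempt_index with a per-hare intercept."""
    import statsmodels.formula.api as smf

    if frame["hare_id"].nunique() < 2:
        raise ValueError("need >=2 hares for the habituation screen")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.mixedlm(f"{response} ~ attempt_index", frame,
                              groups=frame["hare_id"]).fit(reml=False,
                                                           method="lbfgs")
            return float(res.params["attempt_index"]), float(res.bse["attempt_index"])
        except Exception:
            res = smf.ols(f"{response} ~ attempt_index", frame).fit()
            return float(res.params["attempt_index"]), float(res.bse["attempt_index"])


def habituation_truncation(data: pd.DataFrame, response: str,
                           k_min: int = 3) -> HabituationResult:
    """Find the largest attempt count showing no significant response decline.

    For each k from ``k_min`` to the maximum attempt, the response is
    regressed on ``attempt_index`` (random intercept per hare) using only
    observations with ``attempt_index <= k``.  The truncation index is the
    largest k whose slope 95% interval still includes zero; data beyond it
    are discarded.  Taking the largest such k makes the screen robust both
    to isolated false positives at small k and to the lag before a real
    decline reaches significance.  A decline significant at every k
    truncates at ``k_min`` with a warning; a response flat in attempts keeps
    the full dataset (truncation at the maximum attempt).
    """
    if response == "fid":
        frame = data.loc[data["fid_m"].notna()].copy()
        frame["response"] = frame["fid_m"].astype(float)
    elif response == "concealment":
        frame = data.loc[data["concealment"].notna()].copy()
        frame["response"] = frame["concealment"].astype(float)
    else:
        raise ValueError(f"response must be 'concealment' or 'fid', got {response!r}")
    if "attempt_index" not in frame.columns:
        raise ValueError("attempt_index column required for habituation screening")

    k_max = int(frame["attempt_index"].max())
    rows = []
    z = stats.norm.ppf(0.975)
    for k in range(k_min, k_max + 1):
        sub = frame.loc[frame["attempt_index"] <= k]
        if sub["attempt_index"].nunique() < 2:
            continue
        slope, se = _attempt_slope(sub, "response")
        lo, hi = slope - z * se, slope + z * se
        rows.append({"k": k, "slope": slope, "se": se,
                     "ci_low": lo, "ci_high": hi, "n": len(sub)})
    table = pd.DataFrame(rows)

    warning = None
    nonsig = table.loc[table["ci_high"] >= 0.0, "k"]
    if len(nonsig):
        index = int(nonsig.max())
    else:
        index = k_min
        warning = (f"response declines significantly at every window from "
                   f"k={k_min}; truncated at the minimum window")
    truncated = data.loc[data["attempt_index"] <= index].copy()
    return HabituationResult(response=response, truncation_index=index,
                             table=table, truncated=truncated, warning=warning)


# ---------------------------------------------------------------------------
# Candidate model sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateSet:
    """Admissible fixed-effect term combinations after collinearity screening."""

    models: tuple          # tuple of tuples of term names; () is the null model
    excluded_pairs: tuple  # ((a, b, r), ...) pairs never co-included

    def __iter__(self):
        return iter(self.models)

    def __len__(self) -> int:
        return len(self.models)


def build_candidates(terms: Sequence[str], correlations: pd.DataFrame,
                     threshold: float = 0.8,
                     quadratic_for: Sequence[str] = (),
                     max_terms: int | None = None) -> CandidateSet:
    """Enumerate admissible term subsets.

    Pairs of covariates with |r| >= ``threshold`` are never included in the
    same model; each subset containing a term listed in ``quadratic_for``
    additionally yields a variant with that term's quadratic (the quadratic
    only ever appears alongside its linear term).  The null (intercept-only)
    model is always included.
    """
    if not terms:
        raise ValueError("empty candidate term list")
    forbidden = []
    for a, b in itertools.combinations(terms, 2):
        if a in correlations.index and b in correlations.columns:
            r = float(correlations.loc[a, b])
            if abs(r) >= threshold:
                forbidden.append((a, b, r))
    models: list[tuple[str, ...]] = [()]
    for size in range(1, len(terms) + 1):
        if max_terms is not None and size > max_terms:
            break
        for combo in itertools.combinations(terms, size):
            if any(a in combo and b in combo for a, b, _ in forbidden):
                continue
            models.append(combo)
            quads = [t for t in combo if t in quadratic_for]
            for qn in range(1, len(quads) + 1):
                for qs in itertools.combinations(quads, qn):
                    models.append(combo + tuple(f"{t}^2" for t in qs))
    if not models:
        raise ValueError("screening left no admissible candidate models")
    return CandidateSet(models=tuple(models), excluded_pairs=tuple(forbidden))


_CATEGORICAL = {"site", "season", "sex", "mismatch1m", "mismatch10m",
                "abs_mismatch1m", "abs_mismatch10m"}


def _formula_terms(terms: Sequence[str]) -> list[str]:
    out = []
    for t in terms:
        if t.endswith("^2"):
            base = t[:-2]
            out.append(f"I({base} ** 2)")
        elif t in _CATEGORICAL:
            out.append(f"C({t})")
        else:
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# Concealment
# ---------------------------------------------------------------------------


@dataclass
class ConcealmentFit:
    """AICc table, best set and posterior summaries of the best model."""

    table: pd.DataFrame            # model_id, terms, k, loglik, aicc, delta_aicc
    best_models: tuple             # term tuples with delta AICc <= 2
    best_terms: tuple
    coefficients: pd.DataFrame     # term, estimate, sd, hpd_low, hpd_high
    samples: np.ndarray            # posterior draws of the best fixed effects
    posterior_method: str
    singular: tuple                # models flagged for singular RE fits
    random_effect_var: float


def _fit_one_mixedlm(data: pd.DataFrame, response: str, terms: Sequence[str]):
    import statsmodels.formula.api as smf

    rhs = " + ".join(_formula_terms(terms)) if terms else "1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{response} ~ {rhs}", data, groups=data["hare_id"])
        last_exc = None
        for method in ("lbfgs", None, "cg", "powell"):
            try:
                res = (model.fit(reml=False) if method is None
                       else model.fit(reml=False, method=method))
                if np.isfinite(res.llf) and np.all(np.isfinite(res.bse_fe)):
                    return res
            except Exception as exc:  # singular fits on degenerate designs
                last_exc = exc
    raise RuntimeError(
        f"mixed model {response} ~ {rhs} failed under every optimiser"
    ) from last_exc


def fit_concealment(data: pd.DataFrame, candidates: CandidateSet,
                    seed: int = 0, n_samples: int = 100_000) -> ConcealmentFit:
    """ML linear mixed fits of concealment over the candidate set.

    Each candidate has a random intercept per hare; k counts fixed effects
    plus the random-intercept and residual variances.  The best set holds
    every model within 2 AICc of the top model.  Fixed-effect precision for
    the best model comes from ``n_samples`` draws of the large-sample normal
    approximation at the ML mode (method recorded in the output), summarised
    as 95% HPD intervals.
    """
    import arviz as az

    frame = data.loc[data["concealment"].notna()].copy()
    frame["concealment"] = frame["concealment"].astype(float)
    n = len(frame)
    rows, fits, singular = [], {}, []
    for i, terms in enumerate(candidates):
        res = _fit_one_mixedlm(frame, "concealment", terms)
        k = len(res.fe_params) + 2
        ll = float(res.llf)
        rows.append({"model_id": i, "terms": "+".join(terms) if terms else "(null)",
                     "k": k, "loglik": ll, "aicc": aicc(ll, k, n)})
        fits[terms] = res
        if float(res.cov_re.iloc[0, 0]) < 1e-8:
            singular.append(terms)
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table = table.sort_values("aicc").reset_index(drop=True)

    best_ids = table.loc[table["delta_aicc"] <= 2.0, "model_id"].tolist()
    models = list(candidates)
    best_models = tuple(models[i] for i in best_ids)
    best_terms = models[int(table.iloc[0]["model_id"])]
    best = fits[best_terms]

    rng = np.random.default_rng(seed)
    mean = best.fe_params.to_numpy()
    cov = best.cov_params().iloc[: len(mean), : len(mean)].to_numpy()
    cov = (cov + cov.T) / 2.0 + 1e-10 * np.eye(len(mean))
    samples = rng.multivariate_normal(mean, cov, size=n_samples,
                                      method="eigh", check_valid="ignore")
    coef_rows = []
    for j, name in enumerate(best.fe_params.index):
        hdi = az.hdi(samples[:, j], hdi_prob=0.95)
        coef_rows.append({"term": name, "estimate": float(mean[j]),
                          "sd": float(np.std(samples[:, j])),
                          "hpd_low": float(hdi[0]), "hpd_high": float(hdi[1])})
    return ConcealmentFit(
        table=table, best_models=best_models, best_terms=best_terms,
        coefficients=pd.DataFrame(coef_rows), samples=samples,
        posterior_method="normal_approximation_at_ml_mode",
        singular=tuple(singular),
        random_effect_var=float(best.cov_re.iloc[0, 0]),
    )


# ---------------------------------------------------------------------------
# Flight initiation distance
# ---------------------------------------------------------------------------


def cox_partial_loglik(time: np.ndarray, event: np.ndarray, X: np.ndarray,
                       beta: np.ndarray, ties: str = "efron") -> float:
    """Cox partial log-likelihood with Efron (default) or Breslow ties.

    Independent of any fitting library; at beta = 0 on tie-free data this
    reduces to -sum over event times of log(risk-set size).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.shape[0]:
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    xb = X @ beta
    exb = np.exp(xb)
    ll = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        tied = event & (time == t)
        d = int(np.sum(tied))
        ll += float(np.sum(xb[tied]))
        risk_sum = float(np.sum(exb[at_risk]))
        tied_sum = float(np.sum(exb[tied]))
        if ties == "efron":
            for l in range(d):
                ll -= np.log(risk_sum - (l / d) * tied_sum)
        elif ties == "breslow":
            ll -= d * np.log(risk_sum)
        else:
            raise ValueError(f"unknown tie handling {ties!r}")
    return ll


def prepare_fid_frame(data: pd.DataFrame) -> pd.DataFrame:
    """Approach-progress representation of the flight trials.

    Progress runs from 0 at the 20-m reliability limit to 17 at the 3-m
    minimum approach; flight is the event, "no flush" right-censors at 17.
    A flight recorded at the full 20 m is placed just inside the origin
    (progress 0.25, half the metre-rounding interval).
    """
    frame = data.loc[data["fid_m"].notna()].copy()
    fled = frame["fled"]
    if fled.dtype != bool:
        fled = fled.astype(str).str.lower() == "true"
    frame["event"] = fled.to_numpy()
    progress = 20.0 - frame["fid_m"].astype(float)
    progress = np.where(frame["event"], progress, FID_PROGRESS_CENSOR)
    frame["progress"] = np.where(progress <= 0.0, 0.25, progress)
    return frame


@dataclass
class FIDFit:
    table: pd.DataFrame            # model_id, terms, k, loglik, aicc, delta_aicc
    best_models: tuple
    best_terms: tuple
    coefficients: pd.DataFrame     # term, coef, se, hazard_ratio, ci
    proportionality: pd.DataFrame  # per-term score test on scaled Schoenfeld resids
    n_events: int
    n_censored: int
    dropped_terms: tuple
    warnings_: tuple


def _design(frame: pd.DataFrame, terms: Sequence[str]) -> tuple[pd.DataFrame, list]:
    """One-hot design matrix (no intercept) for the Cox fits."""
    cols, dropped = {}, []
    for t in terms:
        if t.endswith("^2"):
            base = t[:-2]
            cols[t] = frame[base].astype(float) ** 2
        elif t in _CATEGORICAL:
            dummies = pd.get_dummies(frame[t].astype(str), prefix=t,
                                     drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c]
        else:
            cols[t] = frame[t].astype(float)
    X = pd.DataFrame(cols, index=frame.index)
    keep = []
    for c in X.columns:
        if X[c].nunique() > 1:
            keep.append(c)
        else:
            dropped.append(c)
    return X[keep], dropped


def fit_fid(data: pd.DataFrame, candidates: CandidateSet) -> FIDFit:
    """Cox proportional-hazards fits of FID over the candidate set.

    Partial-likelihood maximisation with Efron tie handling; AICc computed
    on the number of events (the information-carrying unit of a partial
    likelihood).  Constant covariates are dropped with a warning rather than
    fitted; non-proportionality is reported per term, never fatal.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    frame = prepare_fid_frame(data)
    n_events = int(frame["event"].sum())
    n_censored = int((~frame["event"]).sum())
    if n_events == 0:
        raise ValueError("no flight events; the Cox model cannot be fitted")

    rows, fitted, notes, dropped_all = [], {}, [], set()
    for i, terms in enumerate(candidates):
        X, dropped = _design(frame, terms)
        dropped_all.update(dropped)
        if dropped:
            notes.append(f"model {i}: dropped constant terms {dropped}")
        df = X.copy()
        df["progress"] = frame["progress"].to_numpy()
        df["event"] = frame["event"].to_numpy()
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="progress", event_col="event")
        ll = float(cph.log_likelihood_)
        k = X.shape[1]
        value = aicc(ll, k, n_events) if k else -2.0 * ll
        rows.append({"model_id": i, "terms": "+".join(terms) if terms else "(null)",
                     "k": k, "loglik": ll, "aicc": value})
        fitted[terms] = cph
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table = table.sort_values("aicc").reset_index(drop=True)
    models = list(candidates)
    best_ids = table.loc[table["delta_aicc"] <= 2.0, "model_id"].tolist()
    best_models = tuple(models[i] for i in best_ids)
    best_terms = models[int(table.iloc[0]["model_id"])]
    best = fitted[best_terms]

    # monotone partial likelihood (e.g. a mismatch class with no events)
    # sends a coefficient to +-inf; refit with a small ridge and flag it
    if len(best.params_) and (np.abs(best.params_).max() > 10.0
                              or best.summary["se(coef)"].max() > 1e2):
        notes.append("separation detected in the best model; "
                     "coefficients from a ridge-penalised refit (0.1)")
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(_refit_frame(frame, best_terms), duration_col="progress",
                    event_col="event")
        best = cph

    if len(best.params_):
        summ = best.summary.reset_index()
        coefficients = pd.DataFrame({
            "term": summ["covariate"],
            "coef": summ["coef"],
            "se": summ["se(coef)"],
            "hazard_ratio": summ["exp(coef)"],
            "ci_low": summ["coef lower 95%"],
            "ci_high": summ["coef upper 95%"],
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph = proportional_hazard_test(best, _refit_frame(frame, best_terms),
                                          time_transform="rank")
        prop = ph.summary.reset_index().rename(columns={"index": "term"})
    else:
        coefficients = pd.DataFrame(columns=["term", "coef", "se", "hazard_ratio",
                                             "ci_low", "ci_high"])
        prop = pd.DataFrame(columns=["term", "test_statistic", "p"])

    return FIDFit(table=table, best_models=best_models, best_terms=best_terms,
                  coefficients=coefficients, proportionality=prop,
                  n_events=n_events, n_censored=n_censored,
                  dropped_terms=tuple(sorted(dropped_all)),
                  warnings_=tuple(notes))


def _refit_frame(frame: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X, _ = _design(frame, terms)
    df = X.copy()
    df["progress"] = frame["progress"].to_numpy()
    df["event"] = frame["event"].to_numpy()
    return df


# ---------------------------------------------------------------------------
# Resting-spot choice
# ---------------------------------------------------------------------------


def build_choice_rows(observations) -> pd.DataFrame:
    """Expand pie-slice sightings into the 1-used + 8-available row design.

    Locations where the resting spot and all eight slices are entirely
    snow-covered (all 100) or entirely snow-free (all 0) carry no choice
    information and are excluded.  The filter is idempotent: re-expanding
    the retained locations changes nothing.
    """
    from .observations import observations_to_frame

    frame = observations
    if not isinstance(frame, pd.DataFrame):
        frame = observations_to_frame(observations)
    slice_cols = [f"slice_{i}" for i in range(1, 9)]
    has = frame[slice_cols].notna().all(axis=1)
    partial = frame[slice_cols].notna().any(axis=1) & ~has
    if partial.any():
        raise ValueError(
            f"{int(partial.sum())} rows have a pie-slice count other than 8"
        )
    rows = []
    for _, r in frame.loc[has].iterrows():
        values = [float(r["snow1m"])] + [float(r[c]) for c in slice_cols]
        if all(v == 0.0 for v in values) or all(v == 100.0 for v in values):
            continue
        loc = f"{r['hare_id']}@{r['date']}"
        white = float(r["whiteness"])
        for j, snow in enumerate(values):
            rows.append({
                "hare_id": r["hare_id"], "location_id": loc, "date": r["date"],
                "used": 1 if j == 0 else 0, "snow": snow,
                "contrast": white - snow, "whiteness": white,
            })
    return pd.DataFrame(rows, columns=["hare_id", "location_id", "date",
                                       "used", "snow", "contrast", "whiteness"])


def conditional_logit(rows: pd.DataFrame, covariate: str) -> dict:
    """Exact 1-of-9 conditional-logit fit, stratified by location.

    Maximises sum over locations of beta*x_used - log sum_k exp(beta*x_k);
    consistent for a log-linear within-location preference regardless of
    between-location snow differences.  Returns the estimate, its curvature
    SE, and the maximised log-likelihood.
    """
    groups = []
    for _, g in rows.groupby("location_id", sort=True):
        x = g[covariate].to_numpy(dtype=float)
        u = g["used"].to_numpy()
        if u.sum() != 1:
            raise ValueError("each location must contribute exactly one used row")
        groups.append((x, int(np.argmax(u))))

    def negll(beta: float) -> float:
        total = 0.0
        for x, used in groups:
            z = beta * x
            z -= z.max()
            total -= z[used] - np.log(np.sum(np.exp(z)))
        return total

    res = optimize.minimize_scalar(negll, bounds=(-2.0, 2.0), method="bounded",
                                   options={"xatol": 1e-10})
    beta = float(res.x)
    h = 1e-5
    second = (negll(beta + h) - 2.0 * negll(beta) + negll(beta - h)) / h ** 2
    se = float(1.0 / np.sqrt(second)) if second > 0 else float("nan")
    return {"coef": beta, "se": se, "loglik": -float(res.fun),
            "n_locations": len(groups)}


@dataclass
class RestingSpotFit:
    """Separate snow and contrast fits of the used-available design."""

    snow: dict                  # per-method {coef, se, ...}
    contrast: dict
    aicc_null: float
    aicc_snow: float
    aicc_contrast: float
    curve: pd.DataFrame         # snow 0..100: prob, ci_low, ci_high
    prob_ratio: float           # presence probability at snow 0 vs snow 100
    n_locations: int
    random_effects: bool
    flags: tuple


def _glm_logit(rows: pd.DataFrame, covariate: str | None):
    import statsmodels.api as sm

    y = rows["used"].to_numpy(dtype=float)
    if covariate is None:
        X = np.ones((len(rows), 1))
    else:
        X = np.column_stack([np.ones(len(rows)), rows[covariate].to_numpy(float)])
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    return res


def fit_resting_spot(choice_rows: pd.DataFrame, random_effects: bool = True,
                     seed: int = 0) -> RestingSpotFit:
    """Used-available logit fits for snow and (separately) colour contrast.

    The marginal binomial GLM supplies the presence-probability curve over
    snow cover 0-100 and the AICc comparison against the null; when
    ``random_effects`` is on, a variational binomial mixed model adds the
    hare and location (nested) intercepts, and the exact conditional-logit
    fit over each 1-of-9 choice set is always attached as a cross-check.
    Complete separation is flagged and the affected estimate replaced by the
    conditional fit.
    """
    if choice_rows["location_id"].nunique() < 2:
        raise ValueError("need at least 2 retained locations")
    n = len(choice_rows)
    flags: list[str] = []

    out: dict[str, dict] = {}
    glm_res: dict[str, object] = {}
    for cov in ("snow", "contrast"):
        res = _glm_logit(choice_rows, cov)
        entry = {
            "glm_coef": float(res.params[1]), "glm_se": float(res.bse[1]),
            "glm_intercept": float(res.params[0]), "glm_loglik": float(res.llf),
        }
        if not np.isfinite(res.bse).all() or float(res.bse[1]) > 1e3:
            flags.append(f"possible separation in {cov} GLM")
        entry.update({f"conditional_{k}": v
                      for k, v in conditional_logit(choice_rows, cov).items()})
        out[cov] = entry
        glm_res[cov] = res

    if random_effects:
        try:
            from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for cov in ("snow", "contrast"):
                    model = BinomialBayesMixedGLM.from_formula(
                        f"used ~ {cov}",
                        {"hare": "0 + C(hare_id)", "loc": "0 + C(location_id)"},
                        choice_rows,
                    )
                    fit = model.fit_vb()
                    idx = list(model.exog_names).index(cov)
                    out[cov]["mixed_coef"] = float(fit.fe_mean[idx])
                    out[cov]["mixed_sd"] = float(fit.fe_sd[idx])
        except Exception as exc:  # pragma: no cover - defensive
            flags.append(f"mixed fit failed: {exc}")

    null = _glm_logit(choice_rows, None)
    aicc_null = aicc(float(null.llf), 1, n)
    aicc_snow = aicc(out["snow"]["glm_loglik"], 2, n)
    aicc_contrast = aicc(out["contrast"]["glm_loglik"], 2, n)

    res = glm_res["snow"]
    grid = np.arange(0.0, 101.0, 1.0)
    Xg = np.column_stack([np.ones_like(grid), grid])
    eta = Xg @ res.params
    var = np.einsum("ij,jk,ik->i", Xg, res.cov_params(), Xg)
    z = stats.norm.ppf(0.975)
    prob = 1.0 / (1.0 + np.exp(-eta))
    lo = 1.0 / (1.0 + np.exp(-(eta - z * np.sqrt(var))))
    hi = 1.0 / (1.0 + np.exp(-(eta + z * np.sqrt(var))))
    curve = pd.DataFrame({"snow": grid, "prob": prob, "ci_low": lo, "ci_high": hi})
    prob_ratio = float(curve.iloc[0]["prob"] / curve.iloc[-1]["prob"])

    return RestingSpotFit(
        snow=out["snow"], contrast=out["contrast"],
        aicc_null=aicc_null, aicc_snow=aicc_snow, aicc_contrast=aicc_contrast,
        curve=curve, prob_ratio=prob_ratio,
        n_locations=int(choice_rows["location_id"].nunique()),
        random_effects=random_effects, flags=tuple(flags),
    )
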