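"""Synthetic observation and climate data with the structure the analyses assume.

The generator emulates a two-site radiotelemetry study of seasonal
coat-colour moult: weekly location attempts of radiocollared hares, visual
whiteness/snow scoring in 20% increments (5/95 endpoints), heavy
mortality-driven censoring, site phenologies offset by elevation (the high
site turns white earlier in autumn and brown later in spring), and the three
behavioural responses (concealment, flight initiation distance, resting-spot
choice) driven by configurable coefficients.  The generating truth is
retained so parameter-recovery tests can compare estimates with the values
that produced the data.

All randomness flows from a single seed through named streams
(:func:`stream_rng`), so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .observations import (
    WHITENESS_GRID,
    SNOW_GRID,
    DEFAULT_SITES,
    HareObservation,
    TemperatureSeries,
    assign_season,
    observations_to_frame,
    write_observations,
    write_temperatures,
)
from .phenology import (
    effective_duration,
    expected_whiteness,
    season_anchor,
    _window_cov_means,
)

__all__ = [
    "SyntheticTruth",
    "SnowScenario",
    "Fixture",
    "stream_rng",
    "snap_to_grid",
    "simulate_snow",
    "count_fluctuations",
    "simulate_temperature",
    "draw_lifespan_weeks",
    "simulate_hares",
    "make_fixture",
    "default_scenarios",
]

_WHITE = np.array(WHITENESS_GRID)
_SNOW = np.array(SNOW_GRID)


def stream_rng(seed: int, *keys) -> np.random.Generator:
    """Independent generator for a named stage of the simulation."""
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))


def snap_to_grid(values, grid) -> np.ndarray:
    """Snap values to the nearest member of a scoring grid.

    With the whiteness grid this reproduces the field convention that
    just-initiated / nearly-complete moults score 5 or 95% (midpoints of the
    0-5 and 5-20 intervals are 2.5 and 12.5).
    """
    grid = np.asarray(grid, dtype=float)
    values = np.atleast_1d(np.asarray(values, dtype=float))
    idx = np.argmin(np.abs(values[:, None] - grid[None, :]), axis=1)
    return grid[idx]


# ---------------------------------------------------------------------------
# Generating truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticTruth:
    """All generating parameters; the counterparts of the fitted quantities.

    Phenology: population mean initiation dates are on the season day axis
    (autumn: days since 1 Aug; spring: days since 1 Feb).  The high-elevation
    site initiates the autumn moult ~10 days earlier and the spring moult
    ~30 days later than the low site.  Base durations are ~40 days, rate
    coefficients scaled so that 0->100% snow shifts spring completion by
    ~3 days and the seasonal degree-day range by ~1 day, and females finish
    ~2 days earlier than males (sex coded 0 male / -1 female, positive
    beta_sex shortens the female moult).

    Behaviour: concealment is an ordered logit over the four classes; FID is
    generated on the approach-progress scale from a proportional-hazards
    model; resting spots are chosen among nine candidates with log-linear
    preference for low snow.
    """

    # phenology
    mu_init: dict = field(default_factory=lambda: {
        ("seeley", "autumn"): 65.0,   # ~5 Oct
        ("gardiner", "autumn"): 55.0,  # ~25 Sep
        ("seeley", "spring"): 63.0,   # ~5 Apr
        ("gardiner", "spring"): 93.0,  # ~5 May
    })
    dbar: dict = field(default_factory=lambda: {"autumn": 39.9, "spring": 41.9})
    sigma_ind: float = 5.0
    sigma_obs: float = 8.0
    beta_snow: float = 0.0007
    beta_temp: float = 8.0e-5
    beta_sex: float = 2.0

    # observation process
    detection_prob: float = 0.8
    weekly_mortality: float = 0.0263   # ~50% survive a 26-week season
    #: persistent per-hare offset of local snow from the site series (%);
    #: hares occupy microhabitats that hold more or less snow than average
    snow_microhabitat_sd: float = 10.0
    #: hares are trapped and collared throughout the year: each hare enters
    #: monitoring a uniform number of weeks (0..stagger) into the snow year,
    #: so attempt counts are not confounded with season
    entry_stagger_weeks: int = 40

    # concealment (ordered logit on levels 1-4)
    conceal_cutpoints: tuple = (-1.0, 0.6, 2.2)
    conceal_season: dict = field(default_factory=lambda: {
        "winter": 0.0, "spring": 0.0, "summer": 1.0, "autumn": 0.3})
    conceal_site: dict = field(default_factory=lambda: {
        "seeley": 0.45, "gardiner": 0.0})
    conceal_contrast: float = 0.010
    conceal_contrast2: float = -0.00017
    conceal_habituation_onset: int = 9
    conceal_habituation_step: float = 1.5    # latent drop on entering the habituated state
    conceal_habituation_slope: float = 0.6   # further latent drop per attempt past onset

    # flight initiation distance (hazard on the 20->3 m approach)
    fid_trial_prob: float = 0.55
    fid_baseline_rate: float = 0.08          # per metre of approach progress
    fid_beta_concealment: float = -0.30      # per ordinal level
    fid_site: dict = field(default_factory=lambda: {
        "seeley": 0.0, "gardiner": 0.64})
    fid_season: dict = field(default_factory=lambda: {
        "winter": 0.0, "spring": 0.0, "summer": 0.19, "autumn": 0.0})
    fid_sex_female: float = 0.10
    fid_mismatch_negative: float = -1.73     # brown hare on snow flees later
    fid_mismatch_positive: float = 0.0
    fid_habituation_onset: int = 5
    fid_habituation_slope: float = -0.25     # log-hazard per attempt past onset

    # resting-spot choice among 9 candidate spots
    slices_prob: float = 0.6
    slice_sd: float = 25.0                   # candidate snow spread around local snow
    resting_beta_snow: float = -0.016        # per % snow (preference for bare spots)

    seed: int = 0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["mu_init"] = {f"{k[0]}:{k[1]}": v for k, v in self.mu_init.items()}
        return out


@dataclass(frozen=True)
class SnowScenario:
    """One site-year snow course: autumn onset, spring melt, fluctuations."""

    site: str
    year: int                      # snow year: Aug `year` .. Jul `year`+1
    onset: _dt.date                # autumn 0->100 ramp starts here
    melt: _dt.date                 # spring ramp hits 0 here
    fluctuations_autumn: int = 2
    fluctuations_spring: int = 0
    amplitude: float = 60.0        # > 30% against the seasonal direction
    ramp_days: int = 10

    def __post_init__(self) -> None:
        if self.melt <= self.onset:
            raise ValueError("melt must follow onset")


def default_scenarios(years: Sequence[int]) -> list[SnowScenario]:
    """Site-year snow courses matching the sites' climatologies.

    The high site's snowpack persists from late October until May; the low
    site's from December until mid-April.  Autumns carry transient early
    snowfalls that melt out again; springs rarely do.
    """
    out = []
    for year in years:
        out.append(SnowScenario(
            site="seeley", year=year,
            onset=_dt.date(year, 11, 25), melt=_dt.date(year + 1, 4, 15),
            fluctuations_autumn=2, fluctuations_spring=0,
        ))
        out.append(SnowScenario(
            site="gardiner", year=year,
            onset=_dt.date(year, 10, 20), melt=_dt.date(year + 1, 5, 15),
            fluctuations_autumn=2, fluctuations_spring=1,
        ))
    return out


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------


def simulate_snow(scenario: SnowScenario, seed: int) -> pd.Series:
    """Daily % snow cover for one snow year, on the 20% grid.

    A 0->100 step-ramp at onset and 100->0 at melt, with the configured
    number of transient fluctuations of more than 30% amplitude against the
    seasonal direction: autumn melt-out dips after early snowfalls, and (if
    requested) post-melt spring snowstorms.
    """
    rng = stream_rng(seed, "snow", scenario.site, scenario.year)
    start = _dt.date(scenario.year, 8, 1)
    end = _dt.date(scenario.year + 1, 7, 31)
    n = (end - start).days + 1
    dates = [start + _dt.timedelta(days=i) for i in range(n)]
    day = {d: i for i, d in enumerate(dates)}

    level = np.zeros(n)
    ramp = scenario.ramp_days
    i_on = day[scenario.onset]
    i_melt = day[scenario.melt]
    level[i_on:i_on + ramp] = np.linspace(0, 100, ramp, endpoint=False)
    level[i_on + ramp:i_melt - ramp] = 100.0
    level[i_melt - ramp:i_melt] = np.linspace(100, 0, ramp, endpoint=False)
    level[i_melt:] = 0.0

    # autumn fluctuations: early transient snowfalls that melt out again
    # before the continuous snowpack builds (each melt-out is an excursion
    # > 30% against the seasonal direction); spring fluctuations are
    # snowstorms shortly after melt-out.  One bump per equal sub-window so
    # the configured count is met exactly.
    for count, lo, hi in (
        (scenario.fluctuations_autumn,
         day[_dt.date(scenario.year, 9, 5)], i_on - 4),
        (scenario.fluctuations_spring,
         i_melt + 3, min(i_melt + 45, n - 6)),
    ):
        if count <= 0:
            continue
        span = hi - lo
        seg = span // count
        if seg < 5:
            raise ValueError(
                f"window of {span} days cannot hold {count} fluctuations")
        for j in range(count):
            d = int(rng.integers(3, min(8, seg - 2)))
            s = lo + j * seg + int(rng.integers(0, seg - d - 1))
            level[s:s + d] = np.minimum(level[s:s + d] + scenario.amplitude,
                                        100.0)

    snapped = snap_to_grid(level, _SNOW)
    return pd.Series(snapped, index=pd.Index(dates, name="date"), name="snow")


def count_fluctuations(snow: pd.Series, season: str) -> int:
    """Count excursions > 30% against the seasonal direction.

    Autumn (Sep-Dec): maximal runs where cover drops more than 30% below its
    running maximum.  Spring (Mar-Jul): runs more than 30% above the running
    minimum.  This is the module's own detector, used to verify generated
    scenarios.
    """
    months = (9, 10, 11, 12) if season == "autumn" else (3, 4, 5, 6, 7)
    mask = np.array([d.month in months for d in snow.index])
    vals = snow.to_numpy(dtype=float)[mask]
    if vals.size == 0:
        return 0
    if season == "autumn":
        base = np.maximum.accumulate(vals)
        exc = vals < base - 30.0
    else:
        base = np.minimum.accumulate(vals)
        exc = vals > base + 30.0
    return int(np.sum(exc[1:] & ~exc[:-1]) + int(exc[0]))


def simulate_temperature(site: str, years: Sequence[int], seed: int,
                         noise_sd: float = 2.0) -> TemperatureSeries:
    """Sinusoidal daily mean temperature with the high site ~3°C colder.

    Covers Aug of the first year through Jul after the last year so both
    degree-day windows of every snow year are complete.
    """
    rng = stream_rng(seed, "temps", site)
    annual_mean = 5.0 if site == "seeley" else 2.0
    amp = 14.0
    start = _dt.date(min(years), 8, 1)
    end = _dt.date(max(years) + 1, 7, 31)
    n = (end - start).days + 1
    dates = [start + _dt.timedelta(days=i) for i in range(n)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    t = annual_mean - amp * np.cos(2.0 * np.pi * (doy - 200.0) / 365.25)
    t = t + rng.normal(0.0, noise_sd, size=n)
    return TemperatureSeries(site=site, dates=tuple(dates),
                             tmean_c=tuple(np.round(t, 2)))


def draw_lifespan_weeks(rng: np.random.Generator, weekly_hazard: float,
                        size: int = 1) -> np.ndarray:
    """Weeks survived under a constant discrete weekly mortality hazard.

    Geometric with mean 1/hazard; a hazard of 0 means no mortality (capped
    at a large sentinel).
    """
    if weekly_hazard <= 0:
        return np.full(size, 10_000, dtype=int)
    return rng.geometric(weekly_hazard, size=size)


# ---------------------------------------------------------------------------
# Hare simulation
# ---------------------------------------------------------------------------


def _latent_whiteness(date: _dt.date, year: int, init_a: float, dur_a: float,
                      init_s: float, dur_s: float) -> float:
    """Latent trajectory across one snow year (autumn ramp then spring ramp)."""
    if date.month >= 8:
        day = (date - season_anchor("autumn", year)).days
        return float(expected_whiteness(day, init_a, dur_a, "autumn"))
    day = (date - season_anchor("spring", year + 1)).days
    return float(expected_whiteness(day, init_s, dur_s, "spring"))


def simulate_hares(
    truth: SyntheticTruth,
    scenarios: Sequence[SnowScenario],
    n_hares: int,
    years: Sequence[int],
    seed: int,
    temps: "dict[str, TemperatureSeries] | None" = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a full observation table for the configured site-years.

    A fresh cohort of ``n_hares`` is collared at each site on 1 August of
    each snow year (mirroring replacement of depredated animals); each hare
    is attempted weekly, detected with the configured probability, and dies
    according to the weekly mortality hazard.  Observed whiteness is the
    latent change-point trajectory plus Gaussian error, snapped to the field
    scoring grid — except in the exact noise-free limit (``sigma_obs == 0``),
    where the latent value is reported unsnapped so the trajectory can be
    checked for exact equality.

    Returns the observation table and the truth (with ``seed`` filled in).
    """
    truth = dataclasses.replace(truth, seed=seed)
    sites = sorted({sc.site for sc in scenarios})
    snow = {(sc.site, sc.year): simulate_snow(sc, seed) for sc in scenarios}
    if temps is None:
        temps = {s: simulate_temperature(s, years, seed) for s in sites}

    # site-year covariate summaries shared by generation and analysis
    covs: dict[tuple[str, str, int], tuple[float, float]] = {}
    for sc in scenarios:
        daily = dict(snow[(sc.site, sc.year)].items())
        covs[(sc.site, "autumn", sc.year)] = _window_cov_means(
            sc.site, "autumn", sc.year, pd.Series(daily), temps.get(sc.site))
        covs[(sc.site, "spring", sc.year + 1)] = _window_cov_means(
            sc.site, "spring", sc.year + 1, pd.Series(daily), temps.get(sc.site))

    rows: list[dict] = []
    for year in years:
        for site in sites:
            if (site, year) not in snow:
                continue
            site_snow = snow[(site, year)]
            rng = stream_rng(seed, "hares", site, year)
            lifespans = draw_lifespan_weeks(rng, truth.weekly_mortality, n_hares)
            for k in range(n_hares):
                hare_id = f"{site}-{year}-{k:03d}"
                sex = "female" if rng.uniform() < 0.5 else "male"
                sex_code = -1.0 if sex == "female" else 0.0
                eps_a = rng.normal(0.0, truth.sigma_ind) if truth.sigma_ind > 0 else 0.0
                eps_s = rng.normal(0.0, truth.sigma_ind) if truth.sigma_ind > 0 else 0.0
                init_a = truth.mu_init[(site, "autumn")] + eps_a
                init_s = truth.mu_init[(site, "spring")] + eps_s
                micro = (rng.normal(0.0, truth.snow_microhabitat_sd)
                         if truth.snow_microhabitat_sd > 0 else 0.0)
                sn_a, dd_a = covs[(site, "autumn", year)]
                sn_s, dd_s = covs[(site, "spring", year + 1)]
                sn_a = float(np.clip(sn_a + micro, 0.0, 100.0))
                sn_s = float(np.clip(sn_s + micro, 0.0, 100.0))
                dur_a = float(effective_duration(
                    truth.dbar["autumn"], sn_a, dd_a, sex_code,
                    truth.beta_snow, truth.beta_temp, truth.beta_sex))
                dur_s = float(effective_duration(
                    truth.dbar["spring"], sn_s, dd_s, sex_code,
                    truth.beta_snow, truth.beta_temp, truth.beta_sex))

                start = _dt.date(year, 8, 1)
                entry = (int(rng.integers(0, truth.entry_stagger_weeks + 1))
                         if truth.entry_stagger_weeks > 0 else 0)
                weeks_alive = int(lifespans[k])
                attempt = 0
                for j in range(entry + 1, 52):
                    date = start + _dt.timedelta(days=7 * j)
                    if date > _dt.date(year + 1, 7, 31):
                        break
                    if j - entry > weeks_alive:
                        break
                    attempt += 1
                    if truth.detection_prob < 1.0 and rng.uniform() > truth.detection_prob:
                        continue
                    rows.append(_observe(
                        truth, rng, hare_id, site, date, year, sex, sex_code,
                        attempt, init_a, dur_a, init_s, dur_s, site_snow,
                        micro))

    frame = pd.DataFrame(rows, columns=list(observations_to_frame([]).columns))
    return frame, truth


def _observe(truth: SyntheticTruth, rng: np.random.Generator, hare_id: str,
             site: str, date: _dt.date, year: int, sex: str, sex_code: float,
             attempt: int, init_a: float, dur_a: float, init_s: float,
             dur_s: float, site_snow: pd.Series,
             micro: float = 0.0) -> dict:
    latent = _latent_whiteness(date, year, init_a, dur_a, init_s, dur_s)
    if truth.sigma_obs > 0:
        w = float(snap_to_grid(
            np.clip(latent + rng.normal(0.0, truth.sigma_obs), 0.0, 100.0),
            _WHITE)[0])
    else:
        w = latent

    local = float(np.clip(site_snow.get(date, 0.0) + micro, 0.0, 100.0))
    snow10 = float(snap_to_grid(local, _SNOW)[0])

    # resting-spot module: nine candidate spots, preference for low snow
    slices = None
    if rng.uniform() < truth.slices_prob:
        cand = snap_to_grid(
            np.clip(local + rng.normal(0.0, truth.slice_sd, size=9), 0.0, 100.0),
            _SNOW)
        pref = np.exp(truth.resting_beta_snow * cand)
        used = int(rng.choice(9, p=pref / pref.sum()))
        snow1 = float(cand[used])
        slices = tuple(float(v) for i, v in enumerate(cand) if i != used)
    else:
        snow1 = float(snap_to_grid(
            np.clip(local + rng.normal(0.0, 10.0), 0.0, 100.0), _SNOW)[0])

    contrast1 = w - snow1
    contrast10 = w - snow10
    season = assign_season(date, DEFAULT_SITES[site])

    # concealment: ordered logit on the latent scale
    latent_c = (truth.conceal_season[season]
                + truth.conceal_site[site]
                + truth.conceal_contrast * contrast1
                + truth.conceal_contrast2 * contrast1 ** 2)
    if attempt > truth.conceal_habituation_onset:
        latent_c -= (truth.conceal_habituation_step
                     + truth.conceal_habituation_slope
                     * (attempt - truth.conceal_habituation_onset))
    z = latent_c + rng.logistic(0.0, 1.0)
    concealment = int(1 + np.sum(z > np.asarray(truth.conceal_cutpoints)))

    # flight initiation distance on the 20 -> 3 m approach
    fid_m, fled = None, None
    if rng.uniform() < truth.fid_trial_prob:
        if contrast10 <= -60.0:
            mis = truth.fid_mismatch_negative
        elif contrast10 >= 60.0:
            mis = truth.fid_mismatch_positive
        else:
            mis = 0.0
        xb = (truth.fid_beta_concealment * concealment
              + truth.fid_site[site]
              + truth.fid_season[season]
              + (truth.fid_sex_female if sex == "female" else 0.0)
              + mis)
        if attempt > truth.fid_habituation_onset:
            xb += truth.fid_habituation_slope * (
                attempt - truth.fid_habituation_onset)
        rate = truth.fid_baseline_rate * float(np.exp(xb))
        progress = rng.exponential(1.0 / rate)
        if progress > 17.0:
            fid_m, fled = 3.0, False
        else:
            fid_m = float(np.clip(np.round(20.0 - progress), 3.0, 20.0))
            fled = True

    row = {
        "hare_id": hare_id, "site": site, "date": date.isoformat(), "sex": sex,
        "whiteness": w, "snow1m": snow1, "snow10m": snow10,
        "concealment": concealment, "fid_m": fid_m, "fled": fled,
        "attempt_index": attempt,
    }
    for i in range(8):
        row[f"slice_{i + 1}"] = None if slices is None else slices[i]
    return row


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    """A bundled synthetic dataset plus its generating truth."""

    name: str
    observations: pd.DataFrame
    temperatures: dict
    snow: dict
    scenarios: list
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> dict:
        """Write observation/temperature CSVs and a truth YAML; return paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        obs_path = out / "observations.csv"
        self.observations.to_csv(obs_path, index=False)
        temp_path = out / "temperatures.csv"
        write_temperatures(self.temperatures.values(), temp_path)
        snow_rows = []
        for (site, year), series in sorted(self.snow.items()):
            for d, v in series.items():
                snow_rows.append({"site": site, "snow_year": year,
                                  "date": d.isoformat(), "snow": v})
        snow_path = out / "snow.csv"
        pd.DataFrame(snow_rows).to_csv(snow_path, index=False)
        truth_path = out / "truth.yaml"
        with open(truth_path, "w") as fh:
            yaml.safe_dump(self.truth.to_dict(), fh, sort_keys=True)
        return {"observations": str(obs_path), "temperatures": str(temp_path),
                "snow": str(snow_path), "truth": str(truth_path)}


_FIXTURES = {
    "phenology_small": dict(sites=("gardiner",), n_hares=30, years=(2010, 2011),
                            default_seed=11),
    "behaviour_small": dict(sites=("seeley", "gardiner"), n_hares=20,
                            years=(2010,), default_seed=12),
    "full_study": dict(sites=("seeley", "gardiner"), n_hares=30,
                       years=(2010, 2011), default_seed=13),
}


def make_fixture(name: str, seed: int | None = None,
                 truth: SyntheticTruth | None = None) -> Fixture:
    """Deterministic packaged dataset sized for tests.

    ``full_study`` emulates the complete design: two sites with offset
    phenologies (the high site initiates autumn moults earlier and spring
    moults later), 30 hares per site per year over two years.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    cfg = _FIXTURES[name]
    if seed is None:
        seed = cfg["default_seed"]
    if truth is None:
        truth = SyntheticTruth()
    years = list(cfg["years"])
    scenarios = [sc for sc in default_scenarios(years) if sc.site in cfg["sites"]]
    temps = {s: simulate_temperature(s, years, seed) for s in cfg["sites"]}
    frame, truth = simulate_hares(truth, scenarios, cfg["n_hares"], years,
                                  seed, temps=temps)
    snow = {(sc.site, sc.year): simulate_snow(sc, seed) for sc in scenarios}
    return Fixture(name=name, observations=frame, temperatures=temps,
                   snow=snow, scenarios=scenarios, truth=truth)
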