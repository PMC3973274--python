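"""End-to-end study orchestration: metrics -> phenology -> behaviour.

A :class:`StudyConfig` names either a bundled synthetic fixture or external
observation/temperature CSVs, the site and moult season of interest, the
mismatch threshold, MCMC settings and seeds.  :func:`run_study` executes the
stages, writes every table as CSV under the output directory, and emits a
machine-readable JSON manifest (inputs, resolved config, seeds, output
checksums) so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behaviour, camouflage, phenology, synthetic
from .observations import DEFAULT_SITES, frame_to_observations, read_temperatures

log = logging.getLogger("moultshift")

__all__ = ["StudyConfig", "run_study"]


@dataclass
class StudyConfig:
    """Resolved configuration of one synthetic or data-driven study run."""

    out_dir: str
    seed: int
    fixture: str | None = "full_study"       # or None with explicit paths
    observations_path: str | None = None
    temperatures_path: str | None = None
    site: str = "gardiner"
    season: str = "autumn"
    year: int = 2010
    mismatch_threshold: float = 60.0
    mcmc_chains: int = 2
    mcmc_warmup: int = 600
    mcmc_draws: int = 600
    run_phenology: bool = True
    run_behaviour: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.mismatch_threshold <= 100.0):
            raise ValueError("mismatch threshold must lie in (0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    log.info("stage %s", name)


def run_study(config: StudyConfig) -> dict:
    """Run the configured study; return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    _stage("load")
    if config.fixture:
        fixture = synthetic.make_fixture(config.fixture, seed=config.seed)
        obs_frame = fixture.observations
        temps = fixture.temperatures
        snow = fixture.snow
        paths = fixture.write(out / "data")
        outputs.update({f"data/{k}": v for k, v in paths.items()})
        records = frame_to_observations(obs_frame)
    else:
        if not (config.observations_path and config.temperatures_path):
            raise ValueError("either a fixture name or both data paths required")
        obs_frame = pd.read_csv(config.observations_path)
        records = frame_to_observations(obs_frame)
        temps = read_temperatures(config.temperatures_path)
        snow = {}

    _stage("metrics")
    contrasts = camouflage.contrast_table(records, config.mismatch_threshold)
    p = out / "contrast.csv"
    contrasts.to_csv(p, index=False)
    outputs["contrast"] = str(p)
    weekly = camouflage.weekly_average(records, "whiteness")
    p = out / "weekly_whiteness.csv"
    weekly.to_csv(p, index=False)
    outputs["weekly_whiteness"] = str(p)
    weekly_snow = camouflage.weekly_average(records, "snow10m")
    p = out / "weekly_snow10m.csv"
    weekly_snow.to_csv(p, index=False)
    outputs["weekly_snow10m"] = str(p)
    dd_rows = []
    for site, series in temps.items():
        for season in ("autumn", "spring"):
            for dds in camouflage.degree_days(series, season):
                for d, v in zip(dds.dates, dds.dd):
                    dd_rows.append({"site": site, "season": season,
                                    "year": dds.year, "date": d.isoformat(),
                                    "dd": v})
    p = out / "degree_days.csv"
    pd.DataFrame(dd_rows).to_csv(p, index=False)
    outputs["degree_days"] = str(p)
    mismatch_counts = (
        contrasts.groupby("mismatch10m").size().rename("count").reset_index()
    )
    p = out / "mismatch_counts.csv"
    mismatch_counts.to_csv(p, index=False)
    outputs["mismatch_counts"] = str(p)

    summary: dict = {"mismatch_threshold": config.mismatch_threshold}

    if config.run_phenology:
        _stage("phenology")
        snow_daily = None
        key = (config.site, config.year if config.season == "autumn"
               else config.year - 1)
        if key in snow:
            snow_daily = dict(snow[key].items())
        data = phenology.prepare_phenology_data(
            records, config.season, config.site, config.year,
            temps=temps.get(config.site), snow_daily=snow_daily)
        spec = phenology.MoultModelSpec(season=config.season)
        fit = phenology.fit_changepoint(
            data, spec,
            phenology.MCMCConfig(seed=config.seed, n_chains=config.mcmc_chains,
                                 n_warmup=config.mcmc_warmup,
                                 n_draws=config.mcmc_draws))
        p = out / "phenology_summary.csv"
        fit.summary().to_csv(p, index=False)
        outputs["phenology_summary"] = str(p)
        shift = phenology.covariate_shift(fit, "snow", 0.0, 100.0)
        summary["phenology"] = {
            "site": config.site, "season": config.season, "year": config.year,
            "initiation_mean": fit.posterior_mean("mu_init"),
            "initiation_ci": list(fit.ci("mu_init")),
            "completion_mean": fit.posterior_mean("completion"),
            "completion_ci": list(fit.ci("completion")),
            "duration_mean": fit.posterior_mean("duration"),
            "snow_completion_shift_days": shift["mean"],
            "converged": fit.converged,
        }
        norms = phenology.reaction_norms(records, config.season)
        norm_rows = [
            {"hare_id": n.hare_id, "season": n.season,
             "years": ";".join(map(str, n.years)),
             "init_difference_days": n.init_difference_days}
            for n in norms
        ]
        p = out / "reaction_norms.csv"
        pd.DataFrame(norm_rows, columns=["hare_id", "season", "years",
                                         "init_difference_days"]).to_csv(
            p, index=False)
        outputs["reaction_norms"] = str(p)

    if config.run_behaviour:
        _stage("behaviour")
        beh = obs_frame.merge(
            contrasts[["hare_id", "date", "contrast1m", "contrast10m",
                       "mismatch1m", "mismatch10m"]],
            on=["hare_id", "date"], how="left")
        beh["season"] = [
            DEFAULT_SITES[s].season_map[pd.Timestamp(d).month]
            for s, d in zip(beh["site"], beh["date"])
        ]

        trunc_c = behaviour.habituation_truncation(beh, "concealment")
        corr = beh[["whiteness", "snow1m", "contrast1m"]].corr()
        cands = behaviour.build_candidates(
            ["contrast1m", "site", "season"], corr,
            quadratic_for=("contrast1m",))
        conceal = behaviour.fit_concealment(trunc_c.truncated, cands,
                                            seed=config.seed)
        p = out / "concealment_models.csv"
        conceal.table.to_csv(p, index=False)
        outputs["concealment_models"] = str(p)
        p = out / "concealment_coefficients.csv"
        conceal.coefficients.to_csv(p, index=False)
        outputs["concealment_coefficients"] = str(p)

        trunc_f = behaviour.habituation_truncation(beh, "fid")
        fid_c = behaviour.build_candidates(
            ["concealment", "site", "season", "mismatch10m"], corr)
        fid = behaviour.fit_fid(trunc_f.truncated, fid_c)
        p = out / "fid_models.csv"
        fid.table.to_csv(p, index=False)
        outputs["fid_models"] = str(p)
        p = out / "fid_coefficients.csv"
        fid.coefficients.to_csv(p, index=False)
        outputs["fid_coefficients"] = str(p)

        choice = behaviour.build_choice_rows(obs_frame)
        if choice["location_id"].nunique() >= 2:
            rest = behaviour.fit_resting_spot(choice, random_effects=False,
                                              seed=config.seed)
            p = out / "resting_curve.csv"
            rest.curve.to_csv(p, index=False)
            outputs["resting_curve"] = str(p)
            summary["resting"] = {
                "snow_coef_glm": rest.snow["glm_coef"],
                "snow_coef_conditional": rest.snow["conditional_coef"],
                "prob_ratio_snow0_vs_100": rest.prob_ratio,
                "delta_aicc_null_minus_snow": rest.aicc_null - rest.aicc_snow,
            }
        summary["concealment"] = {
            "truncation_index": trunc_c.truncation_index,
            "best_terms": list(conceal.best_terms),
        }
        summary["fid"] = {
            "truncation_index": trunc_f.truncation_index,
            "best_terms": list(fid.best_terms),
            "n_events": fid.n_events, "n_censored": fid.n_censored,
        }

    _stage("manifest")
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs["summary"] = str(p)
    manifest = {
        "config": dataclasses.asdict(config),
        "outputs": {
            k: {"path": v, "sha256": _sha256(Path(v))}
            for k, v in sorted(outputs.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                 sort_keys=True))
    return manifest
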