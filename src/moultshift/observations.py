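"""Core data model and tabular I/O for hare observation and temperature data.

One :class:`HareObservation` is a single radiotelemetry sighting of one hare:
its coat colour (% whiteness on the field scoring grid), the snow cover around
its resting spot at two radii, and the behavioural measurements taken at that
sighting (concealment class, flight-initiation trial, "pie-slice" snow
percentages of the eight sectors of the 10-m circle).

Field conventions
-----------------
* Whiteness is scored in 20% increments; hares that have only just initiated
  or nearly completed the moult are scored 5 or 95% rather than 0/100, so the
  legal grid is {0, 5, 20, 40, 60, 80, 95, 100}.
* Snow cover (both radii and all pie slices) is scored in 20% increments.
* Flight initiation distance (FID) is measured to the nearest metre between a
  20-m reliability limit and a 3-m minimum approach; a hare that does not
  flush at 3 m is recorded ``fled=False`` and is right-censored at 3 m.
* ``attempt_index`` counts cumulative location attempts per hare, including
  unsuccessful ones, so it is supplied with the data rather than recomputed
  from observation rows.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WHITENESS_GRID",
    "SNOW_GRID",
    "CONCEALMENT_LEVELS",
    "FID_MIN_M",
    "FID_MAX_M",
    "HareObservation",
    "SiteConfig",
    "TemperatureSeries",
    "ValidationError",
    "SchemaError",
    "SEELEY",
    "GARDINER",
    "DEFAULT_SITES",
    "assign_season",
    "read_observations",
    "write_observations",
    "observations_to_frame",
    "frame_to_observations",
    "read_temperatures",
    "write_temperatures",
]

#: Legal coat-whiteness scores: 20% increments with 5/95 endpoints.
WHITENESS_GRID: tuple[float, ...] = (0.0, 5.0, 20.0, 40.0, 60.0, 80.0, 95.0, 100.0)

#: Legal snow-cover scores (both radii and pie slices): 20% increments.
SNOW_GRID: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)

#: Ordinal concealment classes (1 = 0-25% of body concealed ... 4 = 75-100%).
CONCEALMENT_LEVELS: tuple[int, ...] = (1, 2, 3, 4)

FID_MIN_M: float = 3.0
FID_MAX_M: float = 20.0

SEASONS: tuple[str, ...] = ("winter", "spring", "summer", "autumn")

OBSERVATION_COLUMNS: tuple[str, ...] = (
    "hare_id",
    "site",
    "date",
    "sex",
    "whiteness",
    "snow1m",
    "snow10m",
    "concealment",
    "fid_m",
    "fled",
    "attempt_index",
    *[f"slice_{i}" for i in range(1, 9)],
)

TEMPERATURE_COLUMNS: tuple[str, ...] = ("site", "date", "tmean_c")


class ValidationError(ValueError):
    """A data row violates a field invariant (off-grid value, bad range...)."""


class SchemaError(ValueError):
    """A table is missing mandatory columns."""


@dataclass(frozen=True)
class HareObservation:
    """One sighting of one radiocollared hare."""

    hare_id: str
    site: str
    date: _dt.date
    sex: str  # "female" | "male"
    whiteness: float
    snow1m: float
    snow10m: float
    concealment: int | None = None
    fid_m: float | None = None
    fled: bool | None = None
    attempt_index: int = 1
    slices: tuple[float, ...] | None = None

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any field invariant is violated."""
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.whiteness not in WHITENESS_GRID:
            raise ValidationError(
                f"whiteness {self.whiteness!r} not on the legal grid {WHITENESS_GRID}"
            )
        for name in ("snow1m", "snow10m"):
            value = getattr(self, name)
            if value not in SNOW_GRID:
                raise ValidationError(
                    f"{name} {value!r} not on the 20% snow grid {SNOW_GRID}"
                )
        if self.concealment is not None and self.concealment not in CONCEALMENT_LEVELS:
            raise ValidationError(
                f"concealment {self.concealment!r} not an ordinal level 1-4"
            )
        if (self.fid_m is None) != (self.fled is None):
            raise ValidationError(
                "fid_m and fled must be present together (one flight trial) "
                "or both absent (no trial)"
            )
        if self.fid_m is not None:
            if not (FID_MIN_M <= self.fid_m <= FID_MAX_M):
                raise ValidationError(
                    f"fid_m {self.fid_m!r} outside [{FID_MIN_M}, {FID_MAX_M}] m"
                )
            if self.fled is False and self.fid_m != FID_MIN_M:
                raise ValidationError(
                    "fled=False means no flush at the minimum approach: "
                    f"fid_m must equal {FID_MIN_M}, got {self.fid_m!r}"
                )
        if self.attempt_index < 1:
            raise ValidationError(
                f"attempt_index must be a positive integer, got {self.attempt_index!r}"
            )
        if self.slices is not None:
            if len(self.slices) != 8:
                raise ValidationError(
                    f"slices must hold exactly 8 pie-slice values, got {len(self.slices)}"
                )
            for value in self.slices:
                if value not in SNOW_GRID:
                    raise ValidationError(
                        f"pie-slice snow {value!r} not on the 20% grid {SNOW_GRID}"
                    )


@dataclass(frozen=True)
class SiteConfig:
    """Site-specific season calendar and geography.

    ``season_map`` maps month number (1-12) to one of winter/spring/summer/
    autumn; the two study sites run different calendars because of their
    climate difference.
    """

    site: str
    season_map: Mapping[int, str]
    latitude: float
    elevation_m: float

    def __post_init__(self) -> None:
        missing = sorted(set(range(1, 13)) - set(self.season_map))
        if missing:
            raise ValidationError(
                f"season_map for site {self.site!r} leaves months {missing} unmapped"
            )
        bad = {s for s in self.season_map.values() if s not in SEASONS}
        if bad:
            raise ValidationError(f"unknown season labels {bad} for site {self.site!r}")


def _months(spec: Mapping[str, Sequence[int]]) -> dict[int, str]:
    out: dict[int, str] = {}
    for season, months in spec.items():
        for m in months:
            out[m] = season
    return out


#: Low-elevation site: winter Dec-Mar, spring Apr-May, summer Jun-Aug, autumn Sep-Nov.
SEELEY = SiteConfig(
    site="seeley",
    season_map=_months(
        {
            "winter": (12, 1, 2, 3),
            "spring": (4, 5),
            "summer": (6, 7, 8),
            "autumn": (9, 10, 11),
        }
    ),
    latitude=47.23,
    elevation_m=1400.0,
)

#: High-elevation site: winter Nov-Apr, spring May-Jun, summer Jul-Aug, autumn Sep-Oct.
GARDINER = SiteConfig(
    site="gardiner",
    season_map=_months(
        {
            "winter": (11, 12, 1, 2, 3, 4),
            "spring": (5, 6),
            "summer": (7, 8),
            "autumn": (9, 10),
        }
    ),
    latitude=45.08,
    elevation_m=2550.0,
)

DEFAULT_SITES: dict[str, SiteConfig] = {"seeley": SEELEY, "gardiner": GARDINER}


def assign_season(date: _dt.date, site_config: SiteConfig) -> str:
    """Deterministic month-to-season lookup under a site's local calendar."""
    return site_config.season_map[date.month]


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily mean temperatures for one site.

    Dates must be strictly increasing; the degree-day accumulator additionally
    requires gap-free coverage inside each seasonal window it is asked to
    integrate (no imputation is attempted).
    """

    site: str
    dates: tuple[_dt.date, ...]
    tmean_c: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.tmean_c):
            raise ValidationError("dates and tmean_c must have equal length")
        for a, b in zip(self.dates, self.dates[1:]):
            if b <= a:
                raise ValidationError(f"dates not strictly increasing at {b}")


# ---------------------------------------------------------------------------
# Tabular I/O.  Comma-delimited UTF-8, "." decimal, ISO-8601 dates; missing
# behavioural fields are empty cells (zeros are legal data values).
# ---------------------------------------------------------------------------


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def observations_to_frame(records: Iterable[HareObservation]) -> pd.DataFrame:
    """Render validated records as the canonical observation table."""
    rows = []
    for rec in records:
        row: dict = {
            "hare_id": rec.hare_id,
            "site": rec.site,
            "date": rec.date.isoformat(),
            "sex": rec.sex,
            "whiteness": rec.whiteness,
            "snow1m": rec.snow1m,
            "snow10m": rec.snow10m,
            "concealment": rec.concealment,
            "fid_m": rec.fid_m,
            "fled": None if rec.fled is None else bool(rec.fled),
            "attempt_index": rec.attempt_index,
        }
        for i in range(8):
            row[f"slice_{i + 1}"] = None if rec.slices is None else rec.slices[i]
        rows.append(row)
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


def frame_to_observations(frame: pd.DataFrame) -> list[HareObservation]:
    """Parse and validate an observation table; row-level diagnostics on failure."""
    missing = sorted(set(OBSERVATION_COLUMNS) - set(frame.columns))
    if missing:
        raise SchemaError(f"observation table missing mandatory columns: {missing}")

    records: list[HareObservation] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        try:
            slice_vals = [_parse_optional_float(row[f"slice_{i}"]) for i in range(1, 9)]
            present = [v for v in slice_vals if v is not None]
            if present and len(present) != 8:
                raise ValidationError("pie slices must be all present or all absent")
            fled_raw = row["fled"]
            if fled_raw is None or (isinstance(fled_raw, float) and np.isnan(fled_raw)) or fled_raw == "":
                fled = None
            elif isinstance(fled_raw, (bool, np.bool_)):
                fled = bool(fled_raw)
            else:
                text = str(fled_raw).strip().lower()
                if text not in ("true", "false"):
                    raise ValidationError(f"fled must be true/false, got {fled_raw!r}")
                fled = text == "true"
            concealment = _parse_optional_float(row["concealment"])
            rec = HareObservation(
                hare_id=str(row["hare_id"]),
                site=str(row["site"]),
                date=_dt.date.fromisoformat(str(row["date"])),
                sex=str(row["sex"]),
                whiteness=float(row["whiteness"]),
                snow1m=float(row["snow1m"]),
                snow10m=float(row["snow10m"]),
                concealment=None if concealment is None else int(concealment),
                fid_m=_parse_optional_float(row["fid_m"]),
                fled=fled,
                attempt_index=int(row["attempt_index"]),
                slices=tuple(present) if present else None,
            )
            rec.validate()
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValidationError(
            "invalid observation rows:\n  " + "\n  ".join(errors)
        )

    # attempt_index must be strictly increasing per hare over dates
    by_hare: dict[str, list[HareObservation]] = {}
    for rec in records:
        by_hare.setdefault(rec.hare_id, []).append(rec)
    for hare_id, recs in by_hare.items():
        recs_sorted = sorted(recs, key=lambda r: (r.date, r.attempt_index))
        for a, b in zip(recs_sorted, recs_sorted[1:]):
            if b.attempt_index <= a.attempt_index:
                raise ValidationError(
                    f"attempt_index not strictly increasing for hare {hare_id!r} "
                    f"between {a.date} and {b.date}"
                )
    return records


def read_observations(path: str | Path) -> list[HareObservation]:
    """Read and validate a CSV observation table."""
    frame = pd.read_csv(path, dtype={"hare_id": str, "site": str, "date": str})
    return frame_to_observations(frame)


def write_observations(records: Iterable[HareObservation], path: str | Path) -> None:
    """Write records as CSV; lossless round-trip with :func:`read_observations`."""
    observations_to_frame(records).to_csv(path, index=False)


def read_temperatures(path: str | Path) -> dict[str, TemperatureSeries]:
    """Read a site/date/tmean_c CSV into per-site temperature series."""
    frame = pd.read_csv(path, dtype={"site": str, "date": str})
    missing = sorted(set(TEMPERATURE_COLUMNS) - set(frame.columns))
    if missing:
        raise SchemaError(f"temperature table missing mandatory columns: {missing}")
    out: dict[str, TemperatureSeries] = {}
    for site, grp in frame.groupby("site", sort=True):
        grp = grp.sort_values("date")
        out[str(site)] = TemperatureSeries(
            site=str(site),
            dates=tuple(_dt.date.fromisoformat(d) for d in grp["date"]),
            tmean_c=tuple(float(t) for t in grp["tmean_c"]),
        )
    return out


def write_temperatures(series: Iterable[TemperatureSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for d, t in zip(s.dates, s.tmean_c):
            rows.append({"site": s.site, "date": d.isoformat(), "tmean_c": t})
    pd.DataFrame(rows, columns=list(TEMPERATURE_COLUMNS)).to_csv(path, index=False)
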