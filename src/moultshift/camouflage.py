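"""Camouflage statistics: colour contrast, mismatch classes, degree days.

Colour contrast is the signed difference between a hare's % coat whiteness
and the % snow cover of its background at a given radius: positive contrast
is a white hare on a non-snowy background, negative a brown hare on snow.
A hare is considered *mismatched* when |contrast| >= 60% — the threshold at
which hares visibly stand out against their surroundings.

Degree days summarise the seasonal cooling (autumn) or warming (spring)
trend: the cumulative sum of daily mean temperature below 0°C over
September–December, or above 0°C over March–June.  Both accumulations are
reported as non-negative magnitudes so autumn and spring series are directly
comparable.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .observations import HareObservation, TemperatureSeries

__all__ = [
    "MISMATCH_THRESHOLD",
    "ContrastRecord",
    "DegreeDaySeries",
    "colour_contrast",
    "classify_mismatch",
    "degree_days",
    "weekly_average",
    "contrast_table",
]

#: |contrast| at and beyond which a hare is classed as mismatched.
MISMATCH_THRESHOLD: float = 60.0

#: Calendar windows (month numbers) over which degree days accumulate.
DEGREE_DAY_WINDOWS: dict[str, tuple[int, ...]] = {
    "autumn": (9, 10, 11, 12),
    "spring": (3, 4, 5, 6),
}

Season = Literal["autumn", "spring"]


@dataclass(frozen=True)
class ContrastRecord:
    """Contrast and mismatch classification of one sighting at both radii."""

    contrast1m: float
    contrast10m: float
    abs_contrast1m: float
    abs_contrast10m: float
    mismatch1m: str
    mismatch10m: str


@dataclass(frozen=True)
class DegreeDaySeries:
    """Cumulative degree days over one seasonal window at one site."""

    site: str
    season: Season
    year: int
    dates: tuple[_dt.date, ...]
    dd: tuple[float, ...]


def colour_contrast(whiteness: float, snow: float) -> float:
    """Signed % difference between coat whiteness and background snow cover."""
    if not (0.0 <= whiteness <= 100.0):
        raise ValueError(f"whiteness {whiteness!r} outside [0, 100]")
    if not (0.0 <= snow <= 100.0):
        raise ValueError(f"snow {snow!r} outside [0, 100]")
    return float(whiteness) - float(snow)


def classify_mismatch(contrast: float, threshold: float = MISMATCH_THRESHOLD) -> str:
    """Classify a signed contrast as ``positive``/``negative``/``none`` mismatch.

    Thresholds are inclusive: contrast >= +threshold is a white hare on a brown
    background, contrast <= -threshold a brown hare on snow.
    """
    if not (-100.0 <= contrast <= 100.0):
        raise ValueError(f"contrast {contrast!r} outside [-100, 100]")
    if not (0.0 < threshold <= 100.0):
        raise ValueError(f"threshold {threshold!r} outside (0, 100]")
    if contrast >= threshold:
        return "positive"
    if contrast <= -threshold:
        return "negative"
    return "none"


def contrast_table(records: Iterable[HareObservation],
                   threshold: float = MISMATCH_THRESHOLD) -> pd.DataFrame:
    """Per-sighting contrast/mismatch table at both radii."""
    rows = []
    for rec in records:
        c1 = colour_contrast(rec.whiteness, rec.snow1m)
        c10 = colour_contrast(rec.whiteness, rec.snow10m)
        rows.append(
            {
                "hare_id": rec.hare_id,
                "site": rec.site,
                "date": rec.date.isoformat(),
                "contrast1m": c1,
                "contrast10m": c10,
                "abs_contrast1m": abs(c1),
                "abs_contrast10m": abs(c10),
                "mismatch1m": classify_mismatch(c1, threshold),
                "mismatch10m": classify_mismatch(c10, threshold),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "hare_id", "site", "date",
            "contrast1m", "contrast10m",
            "abs_contrast1m", "abs_contrast10m",
            "mismatch1m", "mismatch10m",
        ],
    )


def degree_days(temps: TemperatureSeries, season: Season) -> list[DegreeDaySeries]:
    """Cumulative seasonal degree days per calendar year.

    Autumn accumulates the magnitude of sub-zero daily means over Sep-Dec;
    spring accumulates above-zero daily means over Mar-Jun.  The covered part
    of each window must be gap-free (consecutive calendar days); a gap raises
    rather than imputing.
    """
    if season not in DEGREE_DAY_WINDOWS:
        raise ValueError(f"season must be 'autumn' or 'spring', got {season!r}")
    months = DEGREE_DAY_WINDOWS[season]
    pairs = [
        (d, t) for d, t in zip(temps.dates, temps.tmean_c) if d.month in months
    ]
    out: list[DegreeDaySeries] = []
    for year in sorted({d.year for d, _ in pairs}):
        ypairs = [(d, t) for d, t in pairs if d.year == year]
        dates = [d for d, _ in ypairs]
        for a, b in zip(dates, dates[1:]):
            if (b - a).days != 1:
                raise ValueError(
                    f"gap in {season} {year} temperature window for site "
                    f"{temps.site!r} between {a} and {b}; degree days need a "
                    "gap-free window"
                )
        t = np.array([v for _, v in ypairs], dtype=float)
        if season == "autumn":
            daily = np.where(t < 0.0, -t, 0.0)
        else:
            daily = np.where(t > 0.0, t, 0.0)
        out.append(
            DegreeDaySeries(
                site=temps.site,
                season=season,
                year=year,
                dates=tuple(dates),
                dd=tuple(np.cumsum(daily)),
            )
        )
    return out


def weekly_average(records: Iterable[HareObservation], field: str) -> pd.DataFrame:
    """Mean of ``field`` per ISO week, per site and ISO year.

    Weeks with no observations are simply absent from the output (no fill).
    """
    rows = []
    for rec in records:
        value = getattr(rec, field)
        if value is None:
            continue
        iso = rec.date.isocalendar()
        rows.append(
            {
                "site": rec.site,
                "iso_year": iso.year,
                "iso_week": iso.week,
                "value": float(value),
            }
        )
    if not rows:
        raise ValueError("no records with a value for field " + repr(field))
    frame = pd.DataFrame(rows)
    grouped = (
        frame.groupby(["site", "iso_year", "iso_week"], as_index=False)["value"]
        .agg(["mean", "count"])
        .reset_index(drop=False)
    )
    grouped = grouped.rename(columns={"mean": f"mean_{field}", "count": "n"})
    return grouped[["site", "iso_year", "iso_week", f"mean_{field}", "n"]]
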