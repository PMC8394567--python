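"""GPS fix ingestion: parsing, daily averaging, migratory-year splitting and
net-squared-displacement series construction.

The analysis year ("migratory year") runs July 1 through June 30; the year
label is the calendar year of its July 1 start. Daily locations are arithmetic
means of that UTC day's fixes, and the displacement reference is the July 1
daily location.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geo import haversine_km

logger = logging.getLogger(__name__)

FIX_COLUMNS = ("animal_id", "timestamp", "lat", "lon")
DEFAULT_DIALECT: Mapping[str, str] = {c: c for c in FIX_COLUMNS}

YEAR_START_MONTH, YEAR_START_DAY = 7, 1


@dataclass
class FixTable:
    """Parsed GPS fixes plus row-level rejection diagnostics."""

    frame: pd.DataFrame
    rejected: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_gps_table(path, dialect: Optional[Mapping[str, str]] = None) -> FixTable:
    """Read a delimited fix table (CSV, or TSV when the suffix is .tsv/.txt).

    ``dialect`` maps the canonical names (animal_id, timestamp, lat, lon) to
    the file's column names. Unparseable rows are dropped, logged and counted;
    a missing mapped column raises ``ValueError``.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    sep = "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [v for v in dialect.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")

    frame = pd.DataFrame(
        {
            "animal_id": raw[dialect["animal_id"]].astype(str),
            "timestamp": pd.to_datetime(raw[dialect["timestamp"]], errors="coerce", utc=True, format="ISO8601"),
            "lat": pd.to_numeric(raw[dialect["lat"]], errors="coerce"),
            "lon": pd.to_numeric(raw[dialect["lon"]], errors="coerce"),
        }
    )
    bad = (
        frame["timestamp"].isna()
        | frame["lat"].isna()
        | frame["lon"].isna()
        | (frame["lat"].abs() > 90)
        | (frame["lon"].abs() > 180)
    )
    rejected = []
    for idx in frame.index[bad]:
        reason = "unparseable timestamp" if pd.isna(frame.at[idx, "timestamp"]) else "bad coordinate"
        rejected.append((int(idx), reason))
        logger.warning("row %d rejected: %s", idx, reason)
    frame = frame.loc[~bad].sort_values(["animal_id", "timestamp"], kind="mergesort")
    frame = frame.reset_index(drop=True)
    return FixTable(frame=frame, rejected=rejected)


def average_daily(fixes) -> pd.DataFrame:
    """Collapse fixes to one mean location per animal per UTC calendar day.

    Returns columns animal_id, date (``datetime.date``), lat, lon, n_fixes.
    """
    frame = fixes.frame if isinstance(fixes, FixTable) else fixes
    if frame.empty:
        return pd.DataFrame(columns=["animal_id", "date", "lat", "lon", "n_fixes"])
    ts = pd.to_datetime(frame["timestamp"], utc=True)
    out = (
        frame.assign(date=ts.dt.date)
        .groupby(["animal_id", "date"], sort=True)
        .agg(lat=("lat", "mean"), lon=("lon", "mean"), n_fixes=("lat", "size"))
        .reset_index()
    )
    return out


def migratory_year_bounds(year_label: int) -> tuple[dt.date, dt.date]:
    """(first, last) core day of the migratory year starting July 1."""
    return dt.date(year_label, YEAR_START_MONTH, YEAR_START_DAY), dt.date(
        year_label + 1, YEAR_START_MONTH, YEAR_START_DAY
    ) - dt.timedelta(days=1)


def year_label_of(date: dt.date) -> int:
    return date.year if (date.month, date.day) >= (YEAR_START_MONTH, YEAR_START_DAY) else date.year - 1


@dataclass
class AnnualTrack:
    """One animal's daily locations for one buffered migratory year."""

    animal_id: str
    year_label: int
    core: pd.DataFrame
    buffer_pre: pd.DataFrame
    buffer_post: pd.DataFrame
    complete: bool

    @property
    def days(self) -> pd.DataFrame:
        """Buffered daily table: pre-buffer, core, post-buffer concatenated."""
        return pd.concat([self.buffer_pre, self.core, self.buffer_post], ignore_index=True)


def _is_complete(core: pd.DataFrame, start: dt.date, end: dt.date, *,
                 min_coverage: float = 0.95, max_gap_days: int = 7) -> bool:
    # Complete iff July 1 present, >= 95% of core days observed, and no run of
    # missing days (edges included) longer than max_gap_days.
    span = (end - start).days + 1
    if core.empty or core["date"].iloc[0] != start:
        return False
    if len(core) < min_coverage * span:
        return False
    dates = [start - dt.timedelta(days=1), *core["date"], end + dt.timedelta(days=1)]
    for a, b in zip(dates, dates[1:]):
        if (b - a).days - 1 > max_gap_days:
            return False
    return True


def split_migratory_years(daily: pd.DataFrame, buffer_days: int = 14) -> list[AnnualTrack]:
    """Split a daily-location table into buffered annual tracks.

    The table may hold several animals; each covered migratory year yields one
    ``AnnualTrack`` whose ``complete`` flag applies the coverage rule (July 1
    present, >= 95% of days, no gap over 7 days). Buffers take up to
    ``buffer_days`` observed days on each side from neighbouring years.
    """
    tracks: list[AnnualTrack] = []
    if daily.empty:
        return tracks
    for animal_id, grp in daily.groupby("animal_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        if grp["date"].duplicated().any():
            raise ValueError(f"duplicate dates for animal {animal_id}")
        labels = sorted({year_label_of(d) for d in grp["date"]})
        for lab in labels:
            start, end = migratory_year_bounds(lab)
            pre_lo = start - dt.timedelta(days=buffer_days)
            post_hi = end + dt.timedelta(days=buffer_days)
            core = grp[(grp["date"] >= start) & (grp["date"] <= end)].reset_index(drop=True)
            pre = grp[(grp["date"] >= pre_lo) & (grp["date"] < start)].reset_index(drop=True)
            post = grp[(grp["date"] > end) & (grp["date"] <= post_hi)].reset_index(drop=True)
            if core.empty:
                continue
            tracks.append(
                AnnualTrack(
                    animal_id=str(animal_id),
                    year_label=lab,
                    core=core,
                    buffer_pre=pre,
                    buffer_post=post,
                    complete=_is_complete(core, start, end),
                )
            )
    return tracks


@dataclass
class NSDSeries:
    """Daily squared displacement (km**2) from the July 1 reference location.

    ``days`` has one row per observed day over buffers + core, with columns
    date, lat, lon, displacement_km, nsd_km2, in_core.
    """

    animal_id: str
    year_label: int
    reference_lat: float
    reference_lon: float
    days: pd.DataFrame

    @property
    def values(self) -> np.ndarray:
        return self.days["nsd_km2"].to_numpy(dtype=float)

    @property
    def core(self) -> pd.DataFrame:
        return self.days[self.days["in_core"]]

    @property
    def core_index(self) -> np.ndarray:
        return np.flatnonzero(self.days["in_core"].to_numpy())


def compute_nsd(track: AnnualTrack) -> NSDSeries:
    """Displacement and NSD for every observed buffered day of a complete track."""
    if not track.complete:
        raise ValueError("compute_nsd requires a complete annual track")
    start, end = migratory_year_bounds(track.year_label)
    days = track.days.reset_index(drop=True)
    ref = days[days["date"] == start]
    if ref.empty:
        raise ValueError("July 1 location missing; track should be incomplete")
    ref_lat = float(ref["lat"].iloc[0])
    ref_lon = float(ref["lon"].iloc[0])
    disp = haversine_km(ref_lat, ref_lon, days["lat"].to_numpy(), days["lon"].to_numpy())
    out = days[["date", "lat", "lon"]].copy()
    out["displacement_km"] = disp
    out["nsd_km2"] = disp**2
    out["in_core"] = [(start <= d <= end) for d in out["date"]]
    return NSDSeries(
        animal_id=track.animal_id,
        year_label=track.year_label,
        reference_lat=ref_lat,
        reference_lon=ref_lon,
        days=out,
    )
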