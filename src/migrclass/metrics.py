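"""Timing, duration and distance metrics for classified trajectories."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import Trip
from .geo import haversine_km
from .ingest import NSDSeries
from .ranges import RangeLabeling

TYPICAL_OUTBOUND_MONTHS = frozenset({9, 10, 11, 12})
TYPICAL_INBOUND_MONTHS = frozenset({4, 5, 6})


def trip_lengths(trips: Sequence[Trip]) -> tuple[list[int], int]:
    """Per-trip durations in days (complete trips only) and their sum."""
    per_trip = [
        (t.inbound_date - t.outbound_date).days for t in trips if t.complete
    ]
    return per_trip, sum(per_trip)


def range_distances(
    labeling: RangeLabeling, series: NSDSeries
) -> dict[int, float]:
    """Great-circle distance (km) from the summer-range centroid to every
    other range's centroid; centroids are day-weighted means of the daily
    locations over each range's segments."""
    days = series.days
    lat = days["lat"].to_numpy()
    lon = days["lon"].to_numpy()
    centroids: dict[int, tuple[float, float]] = {}
    sums: dict[int, list] = {}
    for seg in labeling.segments:
        acc = sums.setdefault(seg.range_id, [0.0, 0.0, 0])
        acc[0] += lat[seg.start : seg.end + 1].sum()
        acc[1] += lon[seg.start : seg.end + 1].sum()
        acc[2] += seg.end - seg.start + 1
    for rid, (slat, slon, n) in sums.items():
        centroids[rid] = (slat / n, slon / n)
    summer = centroids.get(labeling.summer_range_id)
    if summer is None:
        return {}
    return {
        rid: float(haversine_km(summer[0], summer[1], c[0], c[1]))
        for rid, c in centroids.items()
        if rid != labeling.summer_range_id
    }


def typical_timing(trip: Trip) -> bool:
    """True iff the single round trip departs in Sep–Dec and returns in Apr–Jun."""
    if not trip.complete:
        raise ValueError("typical_timing requires a complete trip")
    return (
        trip.outbound_date.month in TYPICAL_OUTBOUND_MONTHS
        and trip.inbound_date.month in TYPICAL_INBOUND_MONTHS
    )


def mean_displacement(series: NSDSeries) -> float:
    """Mean daily displacement (km) over the core year."""
    core = series.core
    if core.empty:
        return 0.0
    return float(core["displacement_km"].mean())


@dataclass
class TripMetrics:
    animal_id: str
    year_label: int
    departure_date: Optional[dt.date]
    return_date: Optional[dt.date]
    trip_lengths_days: list[int]
    combined_trip_length_days: int
    n_trip_ranges: int
    mean_range_distance_km: Optional[float]
    max_range_distance_km: Optional[float]
    typical_timing: Optional[bool]
    mean_displacement_km: float

    def to_row(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "year_label": self.year_label,
            "departure_date": self.departure_date,
            "return_date": self.return_date,
            "trip_length_days": (
                float(np.mean(self.trip_lengths_days)) if self.trip_lengths_days else np.nan
            ),
            "combined_trip_length_days": self.combined_trip_length_days,
            "n_trip_ranges": self.n_trip_ranges,
            "mean_range_distance_km": self.mean_range_distance_km,
            "max_range_distance_km": self.max_range_distance_km,
            "typical_timing": self.typical_timing,
            "mean_displacement_km": self.mean_displacement_km,
        }


def compute_metrics(
    labeling: RangeLabeling, trips: Sequence[Trip], series: NSDSeries
) -> TripMetrics:
    complete = [t for t in trips if t.complete]
    per_trip, combined = trip_lengths(trips)
    dists = range_distances(labeling, series)
    trip_ranges = sorted({r for t in complete for r in t.visited_range_ids})
    first = complete[0] if complete else (trips[0] if trips else None)
    return TripMetrics(
        animal_id=series.animal_id,
        year_label=series.year_label,
        departure_date=first.outbound_date if first else None,
        return_date=complete[0].inbound_date if complete else None,
        trip_lengths_days=per_trip,
        combined_trip_length_days=combined,
        n_trip_ranges=len(trip_ranges),
        mean_range_distance_km=float(np.mean(list(dists.values()))) if dists else None,
        max_range_distance_km=float(max(dists.values())) if dists else None,
        typical_timing=typical_timing(complete[0]) if len(complete) == 1 else None,
        mean_displacement_km=mean_displacement(series),
    )
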