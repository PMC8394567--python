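"""Strategy classification: decision tree over round trips and range shifts.

A round trip is an outbound shift leaving the summer range (the range
occupied on July 1, always id 1) paired with a later inbound shift returning
to it. Categories:

========================  ==================================================
dual_range_migrant        one round trip visiting exactly one other range
multi_range_migrant       one round trip visiting several distinct ranges
commuter                  several round trips, all to one identical range
poly_migrant              several round trips to different ranges
disperser                 outbound shift(s) but no return within the year
resident                  no shifts, displacement stays at home-range scale
gradual_mover             no shifts, but a sustained displacement excursion
========================  ==================================================
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

from .config import ClassifierConfig
from .ingest import NSDSeries
from .ranges import RangeLabeling

CATEGORIES = (
    "dual_range_migrant",
    "multi_range_migrant",
    "commuter",
    "poly_migrant",
    "disperser",
    "resident",
    "gradual_mover",
)


@dataclass
class Trip:
    outbound_date: dt.date
    inbound_date: Optional[dt.date]
    visited_range_ids: list[int]
    complete: bool


@dataclass
class StrategyLabel:
    category: str
    n_round_trips: int
    n_ranges_total: int
    flags: set[str] = field(default_factory=set)


def extract_trips(labeling: RangeLabeling) -> list[Trip]:
    """Scan shifts in time order and pair outbound/inbound movements.

    A shift 1 -> x opens a trip, y -> 1 closes it; shifts between non-summer
    ranges while away extend the visited list. A trailing open trip is
    returned with ``complete=False``.
    """
    summer = labeling.summer_range_id
    trips: list[Trip] = []
    open_trip: Optional[Trip] = None
    for shift in labeling.shifts:
        if open_trip is None:
            if shift.from_range == summer and shift.to_range != summer:
                open_trip = Trip(
                    outbound_date=shift.date,
                    inbound_date=None,
                    visited_range_ids=[shift.to_range],
                    complete=False,
                )
        else:
            if shift.to_range == summer:
                open_trip.inbound_date = shift.date
                open_trip.complete = True
                trips.append(open_trip)
                open_trip = None
            elif shift.to_range not in open_trip.visited_range_ids:
                open_trip.visited_range_ids.append(shift.to_range)
    if open_trip is not None:
        trips.append(open_trip)
    return trips


def gradual_mover_test(series: NSDSeries, config: Optional[ClassifierConfig] = None) -> bool:
    """True iff NSD exceeds the threshold on a long-enough run of consecutive
    observed days within the core year (a missing calendar day breaks the run)."""
    config = config or ClassifierConfig()
    core = series.core
    run = 0
    prev_date: Optional[dt.date] = None
    for date, nsd in zip(core["date"], core["nsd_km2"]):
        contiguous = prev_date is not None and (date - prev_date).days == 1
        if nsd > config.gradual_nsd_km2:
            run = run + 1 if (contiguous and run > 0) else 1
            if run >= config.gradual_run_days:
                return True
        else:
            run = 0
        prev_date = date
    return False


def classify(
    labeling: RangeLabeling,
    trips: list[Trip],
    series: Optional[NSDSeries] = None,
    config: Optional[ClassifierConfig] = None,
) -> StrategyLabel:
    """Map a labelled trajectory to exactly one of the seven categories."""
    complete = [t for t in trips if t.complete]
    flags: set[str] = set()
    if trips and not trips[-1].complete and complete:
        flags.add("incomplete_final_trip")

    n_trips = len(complete)
    if n_trips == 1:
        visited = complete[0].visited_range_ids
        category = "dual_range_migrant" if len(visited) == 1 else "multi_range_migrant"
    elif n_trips >= 2:
        destinations = {frozenset(t.visited_range_ids) for t in complete}
        single = len(destinations) == 1 and len(next(iter(destinations))) == 1
        category = "commuter" if single else "poly_migrant"
    elif labeling.shifts:
        category = "disperser"
    else:
        is_gradual = series is not None and gradual_mover_test(series, config)
        category = "gradual_mover" if is_gradual else "resident"

    return StrategyLabel(
        category=category,
        n_round_trips=n_trips,
        n_ranges_total=labeling.n_ranges,
        flags=flags,
    )
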