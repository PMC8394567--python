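"""Shared test helpers: independent oracles and small object builders."""

from __future__ import annotations

import datetime as dt
import itertools

import numpy as np
import pandas as pd

from migrclass.ingest import NSDSeries
from migrclass.ranges import RangeLabeling, RangeSegment, RangeShift


def direct_rss(values) -> float:
    """Residual sum of squares of a constant fit, computed the naive way."""
    values = np.asarray(values, dtype=float)
    return float(((values - values.mean()) ** 2).sum())


def brute_force_breaks(values, m: int, h: int):
    """Exhaustive minimum-RSS placement of m breakpoints with min length h.

    Enumerates every feasible breakpoint set in lexicographic order; the
    first minimum wins. Independent of the dynamic program under test.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if m == 0:
        return [], direct_rss(values)
    candidates = range(h - 1, n - h)
    best_rss, best_breaks = np.inf, None
    for combo in itertools.combinations(candidates, m):
        ok = all(b2 - b1 >= h for b1, b2 in zip(combo, combo[1:]))
        if not ok or (n - 1 - combo[-1]) < h:
            continue
        bounds = [-1, *combo, n - 1]
        rss = sum(direct_rss(values[a + 1 : b + 1]) for a, b in zip(bounds, bounds[1:]))
        if rss < best_rss - 1e-12:
            best_rss, best_breaks = rss, list(combo)
    return best_breaks, best_rss


def make_series(
    nsd_values,
    start_date: dt.date = dt.date(2016, 7, 1),
    animal_id: str = "a",
    year_label: int = 2016,
    in_core=None,
    dates=None,
    lat=None,
    lon=None,
) -> NSDSeries:
    """Build an NSDSeries directly from an NSD array (consecutive days)."""
    nsd = np.asarray(nsd_values, dtype=float)
    n = len(nsd)
    if dates is None:
        dates = [start_date + dt.timedelta(days=i) for i in range(n)]
    days = pd.DataFrame(
        {
            "date": dates,
            "lat": np.zeros(n) if lat is None else np.asarray(lat, dtype=float),
            "lon": np.zeros(n) if lon is None else np.asarray(lon, dtype=float),
            "displacement_km": np.sqrt(nsd),
            "nsd_km2": nsd,
            "in_core": np.ones(n, dtype=bool) if in_core is None else np.asarray(in_core, dtype=bool),
        }
    )
    return NSDSeries(
        animal_id=animal_id,
        year_label=year_label,
        reference_lat=0.0,
        reference_lon=0.0,
        days=days,
    )


def labeling_from_range_sequence(
    range_ids,
    seg_days: int = 30,
    start_date: dt.date = dt.date(2016, 7, 1),
) -> RangeLabeling:
    """A RangeLabeling whose consecutive segments carry the given range ids."""
    segments, shifts = [], []
    for k, rid in enumerate(range_ids):
        a, b = k * seg_days, (k + 1) * seg_days - 1
        segments.append(RangeSegment(start=a, end=b, range_id=rid))
        if k:
            shifts.append(
                RangeShift(
                    date=start_date + dt.timedelta(days=a),
                    from_range=range_ids[k - 1],
                    to_range=rid,
                    index=a,
                )
            )
    return RangeLabeling(segments=segments, shifts=shifts, n_ranges=len(set(range_ids)))
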