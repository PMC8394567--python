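"""Synthetic GPS trajectories with known ground truth for all seven
migration strategies.

Each animal-year is described by a ``TrajectorySpec``: a base location, a set
of range centres given as planar km offsets, and an itinerary of stays
(inclusive day indices relative to July 1). Consecutive stays at different
ranges are separated by ``transit_days`` during which the centre moves
linearly between range centres. Daily positions are the current centre plus
isotropic Gaussian noise; several fixes per day are emitted at evenly spaced
times. Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geo import KM_PER_DEG_LAT
from .ingest import migratory_year_bounds

DEFAULT_BASE_LAT = 40.0
DEFAULT_BASE_LON = -111.0


@dataclass(frozen=True)
class Stay:
    range_index: int  # 0-based index into range_offsets
    start_day: int  # inclusive, days since July 1
    end_day: int  # inclusive


@dataclass(frozen=True)
class Stopover:
    """A brief pause at a fixed offset, overriding the itinerary centre."""

    start_day: int
    end_day: int
    east_km: float
    north_km: float


@dataclass(frozen=True)
class TrajectorySpec:
    category: str
    year: int
    base_lat: float
    base_lon: float
    range_offsets: tuple  # ((east_km, north_km), ...)
    itinerary: tuple  # (Stay, ...)
    transit_days: int = 5
    within_range_sd_km: float = 0.5
    fixes_per_day: int = 4
    seed: int = 0
    drift_km: tuple = (0.0, 0.0)  # linear centre drift over the core year
    meander_km: float = 0.0  # to-and-fro along the drift axis (gradual movers)
    meander_period_days: float = 60.0
    stopovers: tuple = ()
    buffer_pre_days: int = 14
    buffer_post_days: int = 14

    def __post_init__(self):
        stays = self.itinerary
        for a, b in zip(stays, stays[1:]):
            if b.start_day - a.end_day - 1 != self.transit_days:
                raise ValueError("consecutive stays must be separated by transit_days")
            if b.range_index == a.range_index:
                raise ValueError("consecutive stays must use distinct ranges")

    @property
    def n_core_days(self) -> int:
        start, end = migratory_year_bounds(self.year)
        return (end - start).days + 1


@dataclass
class GroundTruth:
    true_category: str
    true_shift_dates: list[dt.date]
    true_range_of_day: dict  # date -> 1-based range id
    spec: TrajectorySpec


def _center_km(spec: TrajectorySpec, day: int) -> tuple[float, float]:
    """Planar (east, north) km offset of the movement centre on a given day."""
    for sp in spec.stopovers:
        if sp.start_day <= day <= sp.end_day:
            return sp.east_km, sp.north_km
    stays = spec.itinerary
    offsets = spec.range_offsets
    e = n = None
    if day <= stays[0].end_day:
        e, n = offsets[stays[0].range_index]
    elif day >= stays[-1].start_day:
        e, n = offsets[stays[-1].range_index]
    else:
        for a, b in zip(stays, stays[1:]):
            if day <= a.end_day:
                e, n = offsets[a.range_index]
                break
            if day < b.start_day:  # in transit
                frac = (day - a.end_day) / (spec.transit_days + 1)
                ea, na = offsets[a.range_index]
                eb, nb = offsets[b.range_index]
                e, n = ea + frac * (eb - ea), na + frac * (nb - na)
                break
            if day <= b.end_day:
                e, n = offsets[b.range_index]
                break
    de, dn = spec.drift_km
    frac_year = day / spec.n_core_days
    e, n = e + de * frac_year, n + dn * frac_year
    norm = np.hypot(de, dn)
    if spec.meander_km and norm > 0:
        # gradual movers do not drift on a perfect line; a slow to-and-fro
        # along the drift axis keeps daily displacement varying smoothly
        swing = spec.meander_km * np.sin(2 * np.pi * day / spec.meander_period_days)
        e += swing * de / norm
        n += swing * dn / norm
    return e, n


def _range_of_day(spec: TrajectorySpec, day: int) -> int:
    """1-based range id; transit days are attributed to the upcoming range."""
    stays = spec.itinerary
    if day <= stays[0].end_day:
        return stays[0].range_index + 1
    for stay in stays[1:]:
        if day <= stay.end_day:
            return stay.range_index + 1
    return stays[-1].range_index + 1


def simulate_fixes(spec: TrajectorySpec, animal_id: str = "sim") -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the fix table and ground truth for one animal-year."""
    rng = np.random.default_rng(spec.seed)
    jul1, _ = migratory_year_bounds(spec.year)
    day_lo = -spec.buffer_pre_days
    day_hi = spec.n_core_days - 1 + spec.buffer_post_days
    cos_lat = np.cos(np.radians(spec.base_lat))

    rows = []
    for day in range(day_lo, day_hi + 1):
        e0, n0 = _center_km(spec, day)
        date = jul1 + dt.timedelta(days=day)
        for k in range(spec.fixes_per_day):
            noise = rng.normal(0.0, spec.within_range_sd_km, size=2)
            e, n = e0 + noise[0], n0 + noise[1]
            ts = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc) + dt.timedelta(
                hours=24.0 * k / spec.fixes_per_day
            )
            rows.append(
                (
                    animal_id,
                    ts,
                    spec.base_lat + n / KM_PER_DEG_LAT,
                    spec.base_lon + e / (KM_PER_DEG_LAT * cos_lat),
                )
            )
    frame = pd.DataFrame(rows, columns=["animal_id", "timestamp", "lat", "lon"])

    shift_dates = [
        jul1 + dt.timedelta(days=a.end_day + 1)
        for a, b in zip(spec.itinerary, spec.itinerary[1:])
    ]
    range_of_day = {
        jul1 + dt.timedelta(days=d): _range_of_day(spec, d) for d in range(spec.n_core_days)
    }
    truth = GroundTruth(
        true_category=spec.category,
        true_shift_dates=shift_dates,
        true_range_of_day=range_of_day,
        spec=spec,
    )
    return frame, truth


def _day_of(year: int, month: int, day: int) -> int:
    """Day index (since July 1) of a calendar date inside the migratory year."""
    jul1, _ = migratory_year_bounds(year)
    y = year if month >= 7 else year + 1
    return (dt.date(y, month, day) - jul1).days


def template_spec(category: str, seed: int = 0, year: int = 2016, **overrides) -> TrajectorySpec:
    """A parameterised archetype of each strategy.

    Shift dates and separations echo typical large-herbivore scales: the
    dual-range template departs November 9 and returns April 26 to a range
    25 km away; the multi-range template chains ranges at 20 and 35 km; the
    gradual mover drifts 12 km over the year with no discrete shift.
    """
    d = lambda m, dd: _day_of(year, m, dd)  # noqa: E731
    last = (migratory_year_bounds(year)[1] - migratory_year_bounds(year)[0]).days
    t = int(overrides.get("transit_days", 5))
    base_extra: dict = {}

    def stays(*triples) -> tuple:
        return tuple(Stay(r, a, b) for r, a, b in triples)

    if category == "resident":
        offsets = ((0.0, 0.0),)
        itin = stays((0, 0, last))
        drift = (0.0, 0.0)
    elif category == "gradual_mover":
        offsets = ((0.0, 0.0),)
        itin = stays((0, 0, last))
        drift = (12.0, 0.0)
        base_extra = {"meander_km": 3.0, "meander_period_days": 45.0}
    elif category == "dual_range_migrant":
        offsets = ((0.0, 0.0), (25.0, 0.0))
        out_d, in_d = d(11, 9), d(4, 26)
        itin = stays((0, 0, out_d - 1), (1, out_d + t, in_d - 1), (0, in_d + t, last))
        drift = (0.0, 0.0)
    elif category == "multi_range_migrant":
        offsets = ((0.0, 0.0), (20.0, 0.0), (35.0, 0.0))
        s1, s2, s3 = d(10, 30), d(2, 1), d(5, 6)
        itin = stays(
            (0, 0, s1 - 1), (1, s1 + t, s2 - 1), (2, s2 + t, s3 - 1), (0, s3 + t, last)
        )
        drift = (0.0, 0.0)
    elif category == "commuter":
        offsets = ((0.0, 0.0), (12.0, 0.0))
        s1, s2, s3, s4 = d(9, 15), d(12, 15), d(2, 1), d(5, 1)
        itin = stays(
            (0, 0, s1 - 1),
            (1, s1 + t, s2 - 1),
            (0, s2 + t, s3 - 1),
            (1, s3 + t, s4 - 1),
            (0, s4 + t, last),
        )
        drift = (0.0, 0.0)
    elif category == "poly_migrant":
        offsets = ((0.0, 0.0), (15.0, 0.0), (0.0, 18.0))
        s1, s2, s3, s4 = d(9, 15), d(12, 15), d(2, 1), d(5, 1)
        itin = stays(
            (0, 0, s1 - 1),
            (1, s1 + t, s2 - 1),
            (0, s2 + t, s3 - 1),
            (2, s3 + t, s4 - 1),
            (0, s4 + t, last),
        )
        drift = (0.0, 0.0)
    elif category == "disperser":
        offsets = ((0.0, 0.0), (15.0, 0.0), (30.0, 0.0))
        s1, s2 = d(11, 1), d(3, 1)
        itin = stays((0, 0, s1 - 1), (1, s1 + t, s2 - 1), (2, s2 + t, last))
        drift = (0.0, 0.0)
    else:
        raise ValueError(f"unknown category: {category}")

    base = dict(
        category=category,
        year=year,
        base_lat=DEFAULT_BASE_LAT,
        base_lon=DEFAULT_BASE_LON,
        range_offsets=offsets,
        itinerary=itin,
        seed=seed,
        drift_km=drift,
        **base_extra,
    )
    base.update(overrides)
    return TrajectorySpec(**base)


def with_stopover(spec: TrajectorySpec, duration: int = 10, transit_index: int = 0) -> TrajectorySpec:
    """Insert a short pause at the midpoint of a transit leg.

    The pause is shorter than the minimum segment length, so a correct
    pipeline must not promote it to a range. The following stay is shortened
    by the overlap; true shift dates are unchanged.
    """
    a = spec.itinerary[transit_index]
    b = spec.itinerary[transit_index + 1]
    ea, na = spec.range_offsets[a.range_index]
    eb, nb = spec.range_offsets[b.range_index]
    start = a.end_day + 1 + spec.transit_days // 2
    stop = Stopover(
        start_day=start,
        end_day=start + duration - 1,
        east_km=(ea + eb) / 2.0,
        north_km=(na + nb) / 2.0,
    )
    return dataclasses.replace(spec, stopovers=spec.stopovers + (stop,))


def simulate_cohort(
    n_per_category: dict, base_seed: int = 0, year: int = 2016, **overrides
) -> tuple[pd.DataFrame, dict]:
    """Independent single-year animals, ``n_per_category[cat]`` per category.

    Returns the concatenated fix table and a dict animal_id -> GroundTruth.
    """
    frames, truths = [], {}
    seed_seq = np.random.SeedSequence(base_seed)
    for cat in sorted(n_per_category):
        for i in range(n_per_category[cat]):
            child = seed_seq.spawn(1)[0]
            spec = template_spec(cat, seed=int(child.generate_state(1)[0]), year=year, **overrides)
            animal_id = f"{cat}_{i:03d}"
            frame, truth = simulate_fixes(spec, animal_id=animal_id)
            frames.append(frame)
            truths[animal_id] = truth
    if not frames:
        return pd.DataFrame(columns=["animal_id", "timestamp", "lat", "lon"]), {}
    return pd.concat(frames, ignore_index=True), truths


def simulate_multiyear(
    plans: dict, base_seed: int = 0, start_year: int = 2016, **overrides
) -> tuple[pd.DataFrame, dict]:
    """Multi-year animals: ``plans[animal_id]`` is a list of categories, one
    per consecutive migratory year starting at ``start_year``.

    Interior year boundaries carry no synthetic buffer of their own — the
    neighbouring year's core days serve as the buffer, as with real collars.
    Returns the fix table and animal_id -> {year: GroundTruth}.
    """
    frames, truths = [], {}
    seed_seq = np.random.SeedSequence(base_seed)
    for animal_id in sorted(plans):
        cats = plans[animal_id]
        truths[animal_id] = {}
        for j, cat in enumerate(cats):
            child = seed_seq.spawn(1)[0]
            year = start_year + j
            spec = template_spec(
                cat,
                seed=int(child.generate_state(1)[0]),
                year=year,
                buffer_pre_days=14 if j == 0 else 0,
                buffer_post_days=14 if j == len(cats) - 1 else 0,
                **overrides,
            )
            frame, truth = simulate_fixes(spec, animal_id=animal_id)
            frames.append(frame)
            truths[animal_id][year] = truth
    if not frames:
        return pd.DataFrame(columns=["animal_id", "timestamp", "lat", "lon"]), {}
    out = pd.concat(frames, ignore_index=True).sort_values(["animal_id", "timestamp"])
    return out.reset_index(drop=True), truths


def drop_days(fixes: pd.DataFrame, rate: float, seed: int = 0) -> pd.DataFrame:
    """Remove all fixes of randomly chosen (animal, day) pairs — a missing-data
    stressor for robustness tests."""
    if fixes.empty or rate <= 0:
        return fixes.copy()
    rng = np.random.default_rng(seed)
    day = pd.to_datetime(fixes["timestamp"], utc=True).dt.date
    keys = pd.MultiIndex.from_arrays([fixes["animal_id"], day])
    uniq = keys.unique()
    drop = set(uniq[rng.random(len(uniq)) < rate])
    return fixes.loc[[k not in drop for k in keys]].reset_index(drop=True)
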