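"""Range identity from the overlap of segment-wise displacement distributions.

Two segments belong to the same range when their NSD value distributions
overlap by more than a threshold (default 5%). Overlap is evaluated between
all segment pairs, identity is the transitive closure (connected components),
and breakpoints between adjacent same-range segments are dropped — the
surviving boundaries are the range shifts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

GRID_POINTS = 1024
_MIN_BW = 1e-6


def _silverman_bw(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-1 / 5)


def overlap_coefficient(a: Sequence[float], b: Sequence[float], grid_points: int = GRID_POINTS) -> float:
    """Overlap of two samples' Gaussian kernel density estimates, in [0, 1].

    Bandwidths follow Silverman's rule per sample with a floor of
    max(0.01 * pooled sd, 1e-6) so zero-spread (resident) segments never
    degenerate; both densities are evaluated on one shared grid and the
    pointwise minimum is integrated by the trapezoidal rule.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("overlap_coefficient needs at least 2 values per sample")
    pooled_sd = float(np.std(np.concatenate([a, b]), ddof=1))
    floor = max(0.01 * pooled_sd, _MIN_BW)
    bw_a = max(_silverman_bw(a), floor)
    bw_b = max(_silverman_bw(b), floor)

    pad = 3.0 * max(bw_a, bw_b)
    lo = min(a.min(), b.min()) - pad
    hi = max(a.max(), b.max()) + pad
    grid = np.linspace(lo, hi, grid_points)

    def kde(x: np.ndarray, bw: float) -> np.ndarray:
        z = (grid[:, None] - x[None, :]) / bw
        return np.exp(-0.5 * z**2).sum(axis=1) / (len(x) * bw * np.sqrt(2 * np.pi))

    eta = float(np.trapezoid(np.minimum(kde(a, bw_a), kde(b, bw_b)), grid))
    return min(max(eta, 0.0), 1.0)


@dataclass
class RangeSegment:
    start: int
    end: int  # inclusive observed-series index
    range_id: int


@dataclass
class RangeShift:
    date: dt.date
    from_range: int
    to_range: int
    index: int  # observed-series index of the first day after the shift


@dataclass
class RangeLabeling:
    segments: list[RangeSegment]
    shifts: list[RangeShift]
    n_ranges: int
    summer_range_id: int = 1


def _components(n: int, edges: list[tuple[int, int]]) -> list[int]:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    return [find(i) for i in range(n)]


def build_range_labeling(
    spans: Sequence[tuple[int, int]],
    values: np.ndarray,
    dates: Sequence[dt.date],
    threshold: float = 0.05,
    sample_spans: Optional[Sequence[tuple[int, int]]] = None,
) -> RangeLabeling:
    """Assign range identities to segment spans of a displacement series.

    ``spans`` are inclusive (start, end) index pairs partitioning the core
    window of ``values``; ``dates`` maps indices to calendar days. Shift dates
    are the first day of the segment after each retained boundary.
    ``sample_spans``, when given, supply the (possibly wider, buffered)
    windows the density samples are drawn from.
    """
    values = np.asarray(values, dtype=float)
    spans = [tuple(s) for s in spans]
    k = len(spans)
    if k == 0:
        return RangeLabeling(segments=[], shifts=[], n_ranges=0)

    sample_spans = spans if sample_spans is None else [tuple(s) for s in sample_spans]
    samples = [values[a : b + 1] for a, b in sample_spans]
    edges = [
        (i, j)
        for i in range(k)
        for j in range(i + 1, k)
        if overlap_coefficient(samples[i], samples[j]) > threshold
    ]
    comp = _components(k, edges)

    # merge consecutive same-component spans, dropping the breakpoint between
    merged: list[list] = []  # [start, end, comp]
    for (a, b), c in zip(spans, comp):
        if merged and merged[-1][2] == c:
            merged[-1][1] = b
        else:
            merged.append([a, b, c])

    range_id_of: dict[int, int] = {}
    segments: list[RangeSegment] = []
    for a, b, c in merged:
        if c not in range_id_of:
            range_id_of[c] = len(range_id_of) + 1
        segments.append(RangeSegment(start=a, end=b, range_id=range_id_of[c]))

    shifts = [
        RangeShift(
            date=dates[nxt.start],
            from_range=prev.range_id,
            to_range=nxt.range_id,
            index=nxt.start,
        )
        for prev, nxt in zip(segments, segments[1:])
    ]
    return RangeLabeling(segments=segments, shifts=shifts, n_ranges=len(range_id_of))
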