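"""Breakpoint detection on a displacement series.

The series is modelled as piecewise constant in the mean. For every feasible
breakpoint count m the globally optimal placement (minimum residual sum of
squares, minimum segment length h) is found by dynamic programming over a
prefix-sum cost table; m itself is selected by minimum BIC with parameter
count 2m + 2 (m breakpoints, m + 1 means, one variance). Ties go to the
smaller m and then to the lexicographically earliest breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import SegmentationConfig


class CostTable:
    """O(1) residual-sum-of-squares lookup for constant fits on windows.

    cost(i, j) is the RSS of fitting a single mean to values[i..j] inclusive.
    """

    def __init__(self, values: Sequence[float], h: int):
        values = np.asarray(values, dtype=float)
        if h < 2:
            raise ValueError("h must be >= 2")
        if len(values) < h:
            raise ValueError(f"need at least h={h} values, got {len(values)}")
        self.values = values
        self.h = int(h)
        self.n = len(values)
        self._s1 = np.concatenate(([0.0], np.cumsum(values)))
        self._s2 = np.concatenate(([0.0], np.cumsum(values**2)))

    def cost(self, i: int, j: int) -> float:
        return float(self.cost_vector(i, np.asarray([j]))[0])

    def cost_vector(self, i: int, j: np.ndarray) -> np.ndarray:
        """RSS of values[i..j] for an array of end indices j (inclusive)."""
        length = j - i + 1
        s1 = self._s1[j + 1] - self._s1[i]
        s2 = self._s2[j + 1] - self._s2[i]
        # clip: float cancellation can drive tiny RSS slightly negative
        return np.maximum(s2 - s1 * s1 / length, 0.0)

    def mean(self, i: int, j: int) -> float:
        return float((self._s1[j + 1] - self._s1[i]) / (j - i + 1))


def cost_table(values: Sequence[float], h: int) -> CostTable:
    return CostTable(values, h)


def _suffix_dp(costs: CostTable, k_max: int) -> np.ndarray:
    """best[k][i] = min RSS splitting values[i:] into k segments of length >= h.

    Infeasible states are +inf. Shape (k_max + 1, n + 1).
    """
    n, h = costs.n, costs.h
    best = np.full((k_max + 1, n + 1), np.inf)
    for i in range(0, n - h + 1):
        best[1, i] = costs.cost(i, n - 1)
    for k in range(2, k_max + 1):
        # first segment [i..j], remainder needs (k-1) * h days
        for i in range(0, n - k * h + 1):
            j = np.arange(i + h - 1, n - (k - 1) * h)
            total = costs.cost_vector(i, j) + best[k - 1, j + 1]
            best[k, i] = total.min()
    return best


def _backtrack(costs: CostTable, best: np.ndarray, m: int) -> list[int]:
    """Reconstruct the earliest optimal breakpoint positions for m breaks."""
    n, h = costs.n, costs.h
    breaks: list[int] = []
    i = 0
    for k in range(m + 1, 1, -1):
        j = np.arange(i + h - 1, n - (k - 1) * h)
        total = costs.cost_vector(i, j) + best[k - 1, j + 1]
        j_star = int(j[int(np.argmin(total))])  # argmin returns first => earliest
        breaks.append(j_star)
        i = j_star + 1
    return breaks


def best_breaks_for_m(costs: CostTable, m: int) -> tuple[list[int], float]:
    """Globally optimal placement of exactly m breakpoints.

    Breakpoints are the last index of each segment but the final one.
    Raises ``ValueError`` when (m + 1) * h > n.
    """
    n, h = costs.n, costs.h
    if m < 0 or (m + 1) * h > n:
        raise ValueError(f"m={m} infeasible for n={n}, h={h}")
    if m == 0:
        return [], costs.cost(0, n - 1)
    best = _suffix_dp(costs, m + 1)
    return _backtrack(costs, best, m), float(best[m + 1, 0])


@dataclass
class Segment:
    start: int
    end: int  # inclusive
    mean_nsd: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Segmentation:
    breakpoints: list[int]
    segments: list[Segment]
    rss: float
    bic: float
    n: int
    bic_by_m: dict[int, float] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.breakpoints)


def _build_segments(costs: CostTable, breaks: Sequence[int]) -> list[Segment]:
    bounds = [-1, *breaks, costs.n - 1]
    return [
        Segment(start=a + 1, end=b, mean_nsd=costs.mean(a + 1, b))
        for a, b in zip(bounds, bounds[1:])
    ]


def bic_score(rss: float, n: int, m: int, rss_floor: float) -> float:
    return n * np.log(max(rss, rss_floor) / n) + (2 * m + 2) * np.log(n)


def select_segmentation(values: Sequence[float], config: Optional[SegmentationConfig] = None) -> Segmentation:
    """Segment a series, choosing the breakpoint count by minimum BIC.

    A series shorter than 2h cannot be split and yields the trivial
    single-segment result.
    """
    config = config or SegmentationConfig()
    values = np.asarray(values, dtype=float)
    n = len(values)
    h = config.min_segment_days
    rss_floor = n * config.rss_floor_per_obs

    if n < 2 * h:
        mean = float(values.mean())
        rss = float(((values - mean) ** 2).sum())
        return Segmentation(
            breakpoints=[],
            segments=[Segment(0, n - 1, mean)],
            rss=rss,
            bic=bic_score(rss, n, 0, rss_floor),
            n=n,
            bic_by_m={0: bic_score(rss, n, 0, rss_floor)},
        )

    m_max = config.resolve_max_breaks(n)
    costs = CostTable(values, h)
    best = _suffix_dp(costs, m_max + 1)

    bic_by_m: dict[int, float] = {}
    best_m, best_bic = 0, np.inf
    for m in range(m_max + 1):
        rss_m = costs.cost(0, n - 1) if m == 0 else float(best[m + 1, 0])
        if not np.isfinite(rss_m):
            continue
        bic = bic_score(rss_m, n, m, rss_floor)
        bic_by_m[m] = float(bic)
        if bic < best_bic:  # strict: ties keep smaller m
            best_m, best_bic = m, bic

    breaks = [] if best_m == 0 else _backtrack(costs, best, best_m)
    rss = costs.cost(0, n - 1) if best_m == 0 else float(best[best_m + 1, 0])
    return Segmentation(
        breakpoints=breaks,
        segments=_build_segments(costs, breaks),
        rss=rss,
        bic=float(best_bic),
        n=n,
        bic_by_m=bic_by_m,
    )


@dataclass(frozen=True)
class ClippedSegment:
    """A segment intersected with the core-year window.

    ``start``/``end`` are the clipped extent; ``src_start``/``src_end`` keep
    the original (buffered) extent so density samples can use every observed
    day of the segment, not just the clipped remnant.
    """

    start: int
    end: int  # inclusive
    src_start: int
    src_end: int


def clip_segments(segmentation: Segmentation, first: int, last: int) -> list[ClippedSegment]:
    """Intersect segments with the observed-index window [first, last].

    Segments lying wholly outside the window (i.e. inside a buffer) are
    dropped.
    """
    out: list[ClippedSegment] = []
    for seg in segmentation.segments:
        a, b = max(seg.start, first), min(seg.end, last)
        if a > b:
            continue
        out.append(ClippedSegment(start=a, end=b, src_start=seg.start, src_end=seg.end))
    return out
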