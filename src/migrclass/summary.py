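"""Cohort-level aggregation: category percentages, per-category metric means,
strategy-switching tables, and the year-to-year transition matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import CATEGORIES

_DEFAULT_METRICS = (
    "trip_length_days",
    "combined_trip_length_days",
    "n_trip_ranges",
    "mean_range_distance_km",
    "max_range_distance_km",
    "mean_displacement_km",
)


def summarize(labels: pd.DataFrame, metric_columns=None) -> pd.DataFrame:
    """Per-category counts, percentages and mean +/- SE of each metric.

    ``labels`` needs a ``category`` column; metric columns present in the
    frame are summarised with SE = sd(ddof=1) / sqrt(n).
    """
    if labels.empty:
        return pd.DataFrame(index=pd.Index(CATEGORIES, name="category"))
    metric_columns = [
        c for c in (metric_columns or _DEFAULT_METRICS) if c in labels.columns
    ]
    total = len(labels)
    rows = {}
    for cat in CATEGORIES:
        sub = labels[labels["category"] == cat]
        row = {"n": len(sub), "percent": 100.0 * len(sub) / total}
        for col in metric_columns:
            vals = pd.to_numeric(sub[col], errors="coerce").dropna()
            row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{col}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        rows[cat] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "category"
    return out


def _consecutive_runs(years: list[int]) -> list[list[int]]:
    """Maximal runs of consecutive year labels (a gap year breaks a run)."""
    runs: list[list[int]] = []
    for y in sorted(years):
        if runs and y == runs[-1][-1] + 1:
            runs[-1].append(y)
        else:
            runs.append([y])
    return runs


def strategy_switching(labels: pd.DataFrame) -> pd.DataFrame:
    """Distinct-strategy counts by number of consecutively monitored years.

    Each maximal run of >= 2 consecutive years of one animal contributes to
    the stratum of its run length; cells are the percentage of runs in that
    stratum using 1, 2, ... distinct strategies. Single-year animals are
    excluded.
    """
    by_key = {
        (str(r.animal_id), int(r.year_label)): r.category for r in labels.itertuples()
    }
    strata: dict[int, list[int]] = {}
    for animal in sorted({a for a, _ in by_key}):
        years = [y for a, y in by_key if a == animal]
        for run in _consecutive_runs(years):
            if len(run) < 2:
                continue
            n_strategies = len({by_key[(animal, y)] for y in run})
            strata.setdefault(len(run), []).append(n_strategies)
    if not strata:
        return pd.DataFrame()
    max_k = max(max(v) for v in strata.values())
    rows = {}
    for years_monitored in sorted(strata):
        counts = strata[years_monitored]
        row = {
            f"{k}_strategies": 100.0 * sum(c == k for c in counts) / len(counts)
            for k in range(1, max_k + 1)
        }
        row["n"] = len(counts)
        rows[years_monitored] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "years_monitored"
    return out


def transition_matrix(labels: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Counts and column-conditional percentages of year-to-year transitions.

    Columns are the category in year t, rows the category in year t + 1;
    pairs are formed only across adjacent migratory years of one animal.
    Returns (counts, percentages, overall switch percentage).
    """
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES), dtype=int)
    by_key = {
        (str(r.animal_id), int(r.year_label)): r.category for r in labels.itertuples()
    }
    n_pairs = n_switch = 0
    for (animal, year), cat in by_key.items():
        nxt = by_key.get((animal, year + 1))
        if nxt is None:
            continue
        counts.loc[nxt, cat] += 1
        n_pairs += 1
        n_switch += int(nxt != cat)
    col_totals = counts.sum(axis=0)
    percent = counts.astype(float)
    for cat in CATEGORIES:
        percent[cat] = (
            100.0 * counts[cat] / col_totals[cat] if col_totals[cat] else np.nan
        )
    switch_pct = 100.0 * n_switch / n_pairs if n_pairs else np.nan
    return counts, percent, switch_pct
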