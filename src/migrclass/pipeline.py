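"""End-to-end orchestration: fixes -> daily locations -> buffered annual NSD
series -> segmentation -> range labelling -> strategy label + metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import ingest, metrics, ranges, segmentation
from .classify import StrategyLabel, Trip, classify, extract_trips
from .config import PipelineConfig
from .ingest import AnnualTrack, NSDSeries
from .metrics import TripMetrics
from .ranges import RangeLabeling
from .segmentation import Segmentation

logger = logging.getLogger(__name__)


@dataclass
class AnnualResult:
    animal_id: str
    year_label: int
    series: NSDSeries
    segmentation: Segmentation
    labeling: RangeLabeling
    trips: list[Trip]
    label: StrategyLabel
    metrics: TripMetrics


def analyze_series(series: NSDSeries, config: Optional[PipelineConfig] = None) -> AnnualResult:
    """Classify one buffered annual NSD series.

    Segmentation runs on the buffered series; segments are then clipped to
    the core year (segments wholly inside a buffer are dropped) before range
    labelling, so year-edge movements absorbed by the buffer cannot spawn
    spurious ranges.
    """
    config = config or PipelineConfig()
    seg = segmentation.select_segmentation(series.values, config.segmentation)
    core_idx = series.core_index
    clipped = segmentation.clip_segments(seg, int(core_idx[0]), int(core_idx[-1]))
    labeling = ranges.build_range_labeling(
        [(c.start, c.end) for c in clipped],
        series.values,
        list(series.days["date"]),
        threshold=config.overlap_threshold,
        sample_spans=[(c.src_start, c.src_end) for c in clipped],
    )
    trips = extract_trips(labeling)
    label = classify(labeling, trips, series, config.classifier)
    trip_metrics = metrics.compute_metrics(labeling, trips, series)
    return AnnualResult(
        animal_id=series.animal_id,
        year_label=series.year_label,
        series=series,
        segmentation=seg,
        labeling=labeling,
        trips=trips,
        label=label,
        metrics=trip_metrics,
    )


def run_pipeline(fixes: pd.DataFrame, config: Optional[PipelineConfig] = None) -> list[AnnualResult]:
    """Classify every complete animal-year found in a fix table."""
    config = config or PipelineConfig()
    daily = ingest.average_daily(fixes)
    tracks = ingest.split_migratory_years(daily, buffer_days=config.buffer_days)
    results = []
    for track in tracks:
        if not track.complete:
            logger.info("skipping incomplete year %s/%s", track.animal_id, track.year_label)
            continue
        series = ingest.compute_nsd(track)
        results.append(analyze_series(series, config))
    return results


def results_to_frames(results: Sequence[AnnualResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(labels, metrics) data frames, one row per classified animal-year."""
    label_rows, metric_rows = [], []
    for r in results:
        label_rows.append(
            {
                "animal_id": r.animal_id,
                "year_label": r.year_label,
                "category": r.label.category,
                "n_round_trips": r.label.n_round_trips,
                "n_ranges_total": r.label.n_ranges_total,
                "flags": ";".join(sorted(r.label.flags)),
            }
        )
        metric_rows.append(r.metrics.to_row())
    cols = ["animal_id", "year_label", "category", "n_round_trips", "n_ranges_total", "flags"]
    labels = pd.DataFrame(label_rows, columns=cols)
    metric_cols = [
        "animal_id", "year_label", "departure_date", "return_date", "trip_length_days",
        "combined_trip_length_days", "n_trip_ranges", "mean_range_distance_km",
        "max_range_distance_km", "typical_timing", "mean_displacement_km",
    ]
    metric_frame = pd.DataFrame(metric_rows, columns=metric_cols)
    if not metric_frame.empty:
        metric_frame.insert(2, "category", labels["category"])
    return labels, metric_frame


def segmentation_records(results: Sequence[AnnualResult]) -> list[dict]:
    """JSON-ready per-animal-year segmentation and range-labelling export."""
    records = []
    for r in results:
        dates = list(r.series.days["date"])
        records.append(
            {
                "animal_id": r.animal_id,
                "year_label": r.year_label,
                "m": r.segmentation.m,
                "breakdates": [
                    dates[b + 1].isoformat() for b in r.segmentation.breakpoints
                ],
                "segment_means_km2": [s.mean_nsd for s in r.segmentation.segments],
                "rss": r.segmentation.rss,
                "bic": r.segmentation.bic,
                "ranges": [
                    {
                        "start": dates[s.start].isoformat(),
                        "end": dates[s.end].isoformat(),
                        "range_id": s.range_id,
                    }
                    for s in r.labeling.segments
                ],
                "shifts": [
                    {"date": s.date.isoformat(), "from": s.from_range, "to": s.to_range}
                    for s in r.labeling.shifts
                ],
            }
        )
    return records
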