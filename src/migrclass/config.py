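"""Pipeline configuration with every tunable threshold in one place."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


@dataclass(frozen=True)
class SegmentationConfig:
    """Controls breakpoint detection on a displacement series.

    ``min_segment_days`` is the minimum number of observed days per segment
    (guards against counting brief stopovers as ranges); ``max_breaks`` caps
    the number of breakpoints tried (default ``min(20, n // h - 1)``);
    ``rss_floor_per_obs`` stabilises the BIC on exactly constant series.
    """

    min_segment_days: int = 14
    max_breaks: Optional[int] = None
    rss_floor_per_obs: float = 1e-12

    def __post_init__(self):
        if self.min_segment_days < 2:
            raise ValueError("min_segment_days must be >= 2")
        if self.max_breaks is not None and self.max_breaks < 0:
            raise ValueError("max_breaks must be >= 0")

    def resolve_max_breaks(self, n: int) -> int:
        cap = max(n // self.min_segment_days - 1, 0)
        if self.max_breaks is None:
            return min(20, cap)
        return min(self.max_breaks, cap)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for the resident vs gradual-mover distinction.

    ``gradual_nsd_km2`` is a squared-displacement threshold in km**2 (25 km**2
    corresponds to a displacement of 5 km, on the scale of one home range);
    a run of at least ``gradual_run_days`` consecutive observed days above it
    marks a gradual mover.
    """

    gradual_nsd_km2: float = 25.0
    gradual_run_days: int = 14

    def __post_init__(self):
        if self.gradual_nsd_km2 <= 0 or self.gradual_run_days <= 0:
            raise ValueError("classifier thresholds must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end configuration: ingest buffers, segmentation, range overlap,
    and classification thresholds."""

    buffer_days: int = 14
    min_segment_days: int = 14
    max_breaks: Optional[int] = None
    overlap_threshold: float = 0.05
    gradual_nsd_km2: float = 25.0
    gradual_run_days: int = 14

    @property
    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(min_segment_days=self.min_segment_days, max_breaks=self.max_breaks)

    @property
    def classifier(self) -> ClassifierConfig:
        return ClassifierConfig(
            gradual_nsd_km2=self.gradual_nsd_km2, gradual_run_days=self.gradual_run_days
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)
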