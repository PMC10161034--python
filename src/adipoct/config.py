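"""Study configuration: dataclasses, YAML loading, and config echo."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .phantom import (
    CohortSpec,
    DriftModel,
    IntervalDaysSampler,
    NoiseCalibration,
    PhantomSpec,
    PositioningJitter,
)
from .core import VolumeGeometry
from .segmentation import SegmentationConfig
from .dosimetry import ABDOMEN_PELVIS_K
from .stats import DEFAULT_BIN_EDGES, DEFAULT_INTERVAL_CUTOFF_DAYS, DEFAULT_SMALL_N_MIN


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    interval_cutoff_days: float = DEFAULT_INTERVAL_CUTOFF_DAYS
    acceptable_accuracy_mode: str = "derived"  # derived | fixed
    fixed_values: dict[str, float] = field(
        default_factory=lambda: {"SAT": 94.5, "VAT": 85.2}
    )
    small_n_min: int = DEFAULT_SMALL_N_MIN
    fine_thickness: float = 1.25  # mm; arm carrying the fine dose bins
    fallback_thickness: float = 5.25  # mm; coarse reference arm
    holm: bool = False

    def __post_init__(self) -> None:
        if self.acceptable_accuracy_mode not in ("derived", "fixed"):
            raise ValueError("acceptable_accuracy_mode must be 'derived' or 'fixed'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class DosimetryConfig:
    k: float = ABDOMEN_PELVIS_K  # mSv / (mGy cm), abdomen-pelvis
    conversion_table_path: str | None = None
    scan_length_cm: float = 16.8
    use_ctdivol_dlp: bool = False  # effective dose from SSDE by default


@dataclass(frozen=True)
class StudyConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    dosimetry: DosimetryConfig = field(default_factory=DosimetryConfig)
    output_dir: str = "adipoct_out"
    master_seed: int = 0
    save_volumes: bool = False
    make_figures: bool = False

    def resolved_cohort(self) -> CohortSpec:
        """Cohort spec with the study-level master seed applied."""
        return dataclasses.replace(self.cohort, master_seed=self.master_seed)


_NESTED = {
    "cohort": CohortSpec,
    "segmentation": SegmentationConfig,
    "stats": StatsConfig,
    "dosimetry": DosimetryConfig,
    "phantom": PhantomSpec,
    "geometry": VolumeGeometry,
    "jitter": PositioningJitter,
    "drift": DriftModel,
    "interval_days": IntervalDaysSampler,
    "noise_cal": NoiseCalibration,
}


def _build(cls, data: dict[str, Any]):
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value)
        elif isinstance(value, list):
            kwargs[key] = tuple(math.inf if v in (".inf", "inf") else v for v in value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> StudyConfig:
    """Load a study configuration from YAML (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _build(StudyConfig, raw)


def config_to_dict(config) -> dict[str, Any]:
    """Fully-resolved config echo (JSON-serialisable)."""

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, float) and math.isinf(obj):
            return "inf"
        return obj

    return convert(config)
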