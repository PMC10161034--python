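"""Fat quantification statistics: total volume, volume per unit scan length,
and measurement accuracy, plus the tabular accuracy-record interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("SAT", "VAT")

#: Column schema of the accuracy-record CSV interchange table.
ACCURACY_COLUMNS = [
    "subject_id",
    "compartment",
    "source",
    "v_true",
    "v_measure",
    "accuracy",
    "days_between",
    "truncated",
    "ssde_5_25",
    "thickness",
    "denoised",
]


@dataclass(frozen=True)
class SliceAreas:
    """Ordered per-slice fat areas (mm^2) at a uniform slice interval (mm)."""

    areas: tuple[float, ...]
    slice_interval: float

    def __post_init__(self) -> None:
        areas = tuple(float(a) for a in self.areas)
        if len(areas) == 0:
            raise ValueError("at least one slice area is required")
        if any(a < 0 for a in areas):
            raise ValueError("slice areas must be non-negative")
        if self.slice_interval <= 0:
            raise ValueError("slice interval must be positive")
        object.__setattr__(self, "areas", areas)

    @property
    def n(self) -> int:
        return len(self.areas)


def fat_volume_total(slices: SliceAreas) -> float:
    """Total fat volume, mm^3: sum of per-slice area x slice interval."""
    return float(np.sum(slices.areas) * slices.slice_interval)


def fat_volume_per_unit_length(slices: SliceAreas) -> float:
    """Fat volume per unit scan length, mm^3/mm: the mean per-slice area.

    Independent of the slice interval and slice count for a fixed set of
    per-slice areas, which is why it is used in place of the total volume.
    """
    return float(np.mean(slices.areas))


def accuracy(v_true: float, v_measure: float) -> float:
    """Measurement accuracy in percent: (1 - |v_true - v_measure| / v_true) x 100.

    The absolute deviation makes over- and under-measurement symmetric; the
    result can be negative when the deviation exceeds the true value.
    """
    if v_true <= 0:
        raise ValueError("v_true must be strictly positive")
    return (1.0 - abs(v_true - v_measure) / v_true) * 100.0


@dataclass(frozen=True)
class AccuracyRecord:
    """One subject x compartment accuracy measurement."""

    subject_id: str
    compartment: str  # SAT | VAT
    source: str  # manual | auto
    v_true: float  # mm^3 per mm scan length
    v_measure: float
    accuracy: float  # percent
    days_between: float
    truncated: bool
    ssde_5_25: float  # mGy
    thickness: float  # mm
    denoised: bool

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        expected = accuracy(self.v_true, self.v_measure)
        if abs(expected - self.accuracy) > 1e-6:
            raise ValueError("accuracy field inconsistent with v_true/v_measure")


def make_record(
    subject_id: str,
    compartment: str,
    v_true: float,
    v_measure: float,
    *,
    source: str = "auto",
    days_between: float = 0.0,
    truncated: bool = False,
    ssde_5_25: float = float("nan"),
    thickness: float = float("nan"),
    denoised: bool = False,
) -> AccuracyRecord:
    """Build an :class:`AccuracyRecord` with the accuracy computed internally."""
    return AccuracyRecord(
        subject_id=subject_id,
        compartment=compartment,
        source=source,
        v_true=v_true,
        v_measure=v_measure,
        accuracy=accuracy(v_true, v_measure),
        days_between=days_between,
        truncated=truncated,
        ssde_5_25=ssde_5_25,
        thickness=thickness,
        denoised=denoised,
    )


def records_to_frame(records: Iterable[AccuracyRecord]) -> pd.DataFrame:
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=ACCURACY_COLUMNS)
    return df


def write_records(records: Sequence[AccuracyRecord], path: str | Path) -> Path:
    path = Path(path)
    # %.17g round-trips float64 exactly, so replaying the CSV reproduces the
    # statistics bit-for-bit
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")
    return path


def read_records(path: str | Path) -> list[AccuracyRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(ACCURACY_COLUMNS) - set(df.columns)
    if missing or len(df) == 0:
        raise ValueError(
            f"accuracy table schema mismatch: missing columns {sorted(missing)}"
            if missing
            else "accuracy table is empty"
        )
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AccuracyRecord(
                subject_id=str(row.subject_id),
                compartment=str(row.compartment),
                source=str(row.source),
                v_true=float(row.v_true),
                v_measure=float(row.v_measure),
                accuracy=float(row.accuracy),
                days_between=float(row.days_between),
                truncated=bool(row.truncated),
                ssde_5_25=float(row.ssde_5_25),
                thickness=float(row.thickness),
                denoised=bool(row.denoised),
            )
        )
    return out
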