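"""Dose arithmetic: SSDE, slice-thickness-normalised SSDE, effective dose,
and helical acquisition quantities.

The size correction uses the public AAPM Report 204 parameterisation for the
32-cm body phantom, indexed by the sum of the anterior-posterior and lateral
patient dimensions.  The packaged table is sampled from the report's
exponential fit ``f = a * exp(-b * d_eff)`` with ``d_eff = (AP + LAT) / 2``
(``a = 3.704369``, ``b = 0.03671937``) and is linearly interpolated; a user
table can be substituted from CSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np

REFERENCE_THICKNESS_MM = 5.25
ABDOMEN_PELVIS_K = 0.015  # mSv / (mGy * cm)

_DATA_PACKAGE = "adipoct.data"
_DEFAULT_TABLE = "ssde_body_sum_ap_lat.csv"


@dataclass(frozen=True)
class ConversionTable:
    """CTDIvol -> SSDE conversion factors vs AP+LAT dimension sum (cm)."""

    sums_cm: np.ndarray
    factors: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sums_cm, dtype=float)
        f = np.asarray(self.factors, dtype=float)
        if s.ndim != 1 or s.shape != f.shape or s.size < 2:
            raise ValueError("table needs matching 1-D sum and factor columns")
        if np.any(np.diff(s) <= 0):
            raise ValueError("dimension sums must be strictly increasing")
        if np.any(np.diff(f) >= 0):
            raise ValueError("conversion factors must be strictly decreasing")
        if np.any(f <= 0):
            raise ValueError("conversion factors must be positive")
        object.__setattr__(self, "sums_cm", s)
        object.__setattr__(self, "factors", f)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConversionTable":
        import pandas as pd

        data = pd.read_csv(path, comment="#")
        if not {"sum_cm", "factor"} <= set(data.columns):
            raise ValueError("conversion table CSV needs 'sum_cm' and 'factor' columns")
        return cls(sums_cm=data["sum_cm"].to_numpy(), factors=data["factor"].to_numpy())

    @classmethod
    def default(cls) -> "ConversionTable":
        ref = importlib.resources.files(_DATA_PACKAGE) / _DEFAULT_TABLE
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    def factor(self, sum_cm: float) -> float:
        """Linearly interpolated conversion factor; no extrapolation."""
        if not (self.sums_cm[0] <= sum_cm <= self.sums_cm[-1]):
            raise ValueError(
                f"AP+LAT sum {sum_cm:.1f} cm outside table range "
                f"[{self.sums_cm[0]:.0f}, {self.sums_cm[-1]:.0f}] cm"
            )
        return float(np.interp(sum_cm, self.sums_cm, self.factors))


_default_table_cache: ConversionTable | None = None


def default_table() -> ConversionTable:
    global _default_table_cache
    if _default_table_cache is None:
        _default_table_cache = ConversionTable.default()
    return _default_table_cache


def compute_ssde(
    ctdivol: float, ap_mm: float, lat_mm: float, table: ConversionTable | None = None
) -> float:
    """SSDE (mGy) from CTDIvol and patient AP/LAT dimensions in mm."""
    if ctdivol < 0:
        raise ValueError("ctdivol must be non-negative")
    if ap_mm <= 0 or lat_mm <= 0:
        raise ValueError("body dimensions must be positive")
    table = table or default_table()
    return ctdivol * table.factor((ap_mm + lat_mm) / 10.0)


def compute_ssde_5_25(ssde: float, thickness_mm: float) -> float:
    """Rescale SSDE to its 5.25-mm slice-thickness noise equivalent."""
    if ssde < 0:
        raise ValueError("ssde must be non-negative")
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    return ssde * thickness_mm / REFERENCE_THICKNESS_MM


def compute_effective_dose(
    dose_mgy: float, scan_length_cm: float, k: float = ABDOMEN_PELVIS_K
) -> float:
    """DLP-style effective dose (mSv) = dose x scan length x k.

    The dose argument is the SSDE of the scan by default in this package; a
    CTDIvol-based DLP is obtained by simply passing CTDIvol instead.
    """
    if dose_mgy < 0 or scan_length_cm < 0 or k < 0:
        raise ValueError("inputs must be non-negative")
    return dose_mgy * scan_length_cm * k


def compute_effective_mas(tube_current_ma: float, revolution_time_s: float, pitch: float) -> float:
    """Effective mAs = tube current x rotation time / pitch."""
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if tube_current_ma < 0 or revolution_time_s < 0:
        raise ValueError("inputs must be non-negative")
    return tube_current_ma * revolution_time_s / pitch


def compute_table_feed(total_collimation_mm: float, pitch: float) -> float:
    """Table feed per rotation (mm) = total collimation x pitch."""
    if total_collimation_mm <= 0 or pitch <= 0:
        raise ValueError("inputs must be positive")
    return total_collimation_mm * pitch


@dataclass(frozen=True)
class AcquisitionParams:
    """Helical acquisition settings (32-cm body phantom CTDIvol reference)."""

    tube_current_ma: float
    revolution_time_s: float
    pitch: float
    total_collimation_mm: float
    kvp: float
    ctdivol: float

    def __post_init__(self) -> None:
        for name in (
            "tube_current_ma",
            "revolution_time_s",
            "pitch",
            "total_collimation_mm",
            "kvp",
            "ctdivol",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def effective_mas(self) -> float:
        return compute_effective_mas(self.tube_current_ma, self.revolution_time_s, self.pitch)

    @property
    def table_feed_mm(self) -> float:
        return compute_table_feed(self.total_collimation_mm, self.pitch)


@dataclass(frozen=True)
class DoseRecord:
    """Per-scan dose summary with derived size-specific quantities."""

    ctdivol: float  # mGy
    ap_mm: float
    lat_mm: float
    ssde: float  # mGy
    thickness_mm: float
    ssde_5_25: float  # mGy

    @classmethod
    def from_ctdivol(
        cls,
        ctdivol: float,
        ap_mm: float,
        lat_mm: float,
        thickness_mm: float,
        table: ConversionTable | None = None,
    ) -> "DoseRecord":
        ssde = compute_ssde(ctdivol, ap_mm, lat_mm, table)
        return cls(
            ctdivol=ctdivol,
            ap_mm=ap_mm,
            lat_mm=lat_mm,
            ssde=ssde,
            thickness_mm=thickness_mm,
            ssde_5_25=compute_ssde_5_25(ssde, thickness_mm),
        )

    @classmethod
    def from_ssde_target(
        cls,
        ssde: float,
        ap_mm: float,
        lat_mm: float,
        thickness_mm: float,
        table: ConversionTable | None = None,
    ) -> "DoseRecord":
        """Back-compute the CTDIvol that realises a target SSDE for a body size."""
        if ssde <= 0:
            raise ValueError("target ssde must be positive")
        table = table or default_table()
        f = table.factor((ap_mm + lat_mm) / 10.0)
        return cls(
            ctdivol=ssde / f,
            ap_mm=ap_mm,
            lat_mm=lat_mm,
            ssde=ssde,
            thickness_mm=thickness_mm,
            ssde_5_25=compute_ssde_5_25(ssde, thickness_mm),
        )
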