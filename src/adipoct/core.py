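"""Core image containers: HU volumes and co-registered label masks.

Conventions used throughout the package:

* all physical lengths are millimetres, attenuation is Hounsfield units,
  dose is mGy;
* volume arrays are indexed ``(slice, row, column)`` with slice 0 the most
  superior slice;
* the in-plane origin sits at the image centre, ``x`` increases with the
  column index (patient left), ``y`` increases with the row index
  (posterior -> anterior is a bookkeeping choice only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0
HU_AIR = -1000.0


class TissueLabel(IntEnum):
    """Per-voxel ground-truth classes."""

    BACKGROUND = 0
    SAT = 1
    VAT = 2
    LEAN = 3
    OTHER = 4


@dataclass(frozen=True)
class VolumeGeometry:
    """Sampling grid of a reconstructed stack."""

    n_slices: int
    n_rows: int
    n_cols: int
    pixel_spacing: float  # mm, isotropic in-plane
    slice_thickness: float  # mm
    slice_interval: float  # mm
    fov_diameter: float  # mm

    def __post_init__(self) -> None:
        if min(self.n_slices, self.n_rows, self.n_cols) < 1:
            raise ValueError("geometry must have at least one voxel per axis")
        for name in ("pixel_spacing", "slice_thickness", "slice_interval", "fov_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_slices, self.n_rows, self.n_cols)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of in-plane pixel centres, mm."""
        x = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.pixel_spacing
        y = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.pixel_spacing
        return np.meshgrid(x, y)


@dataclass
class CTVolume:
    """A reconstructed CT slice stack in Hounsfield units."""

    voxels: np.ndarray  # (n_slices, n_rows, n_cols), HU
    pixel_spacing: float
    slice_thickness: float
    slice_interval: float
    fov_diameter: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array (slice, row, col)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        if self.voxels.min() < HU_MIN or self.voxels.max() > HU_MAX:
            raise ValueError(f"HU values must lie within [{HU_MIN}, {HU_MAX}]")
        for name in ("pixel_spacing", "slice_thickness", "slice_interval", "fov_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(
            n_slices=self.voxels.shape[0],
            n_rows=self.voxels.shape[1],
            n_cols=self.voxels.shape[2],
            pixel_spacing=self.pixel_spacing,
            slice_thickness=self.slice_thickness,
            slice_interval=self.slice_interval,
            fov_diameter=self.fov_diameter,
        )

    def with_voxels(self, voxels: np.ndarray, **overrides) -> "CTVolume":
        kwargs = dict(
            pixel_spacing=self.pixel_spacing,
            slice_thickness=self.slice_thickness,
            slice_interval=self.slice_interval,
            fov_diameter=self.fov_diameter,
        )
        kwargs.update(overrides)
        return CTVolume(voxels=voxels, **kwargs)


@dataclass
class LabelMask:
    """Ground-truth labels co-registered with a :class:`CTVolume`."""

    labels: np.ndarray  # (n_slices, n_rows, n_cols), TissueLabel values
    pixel_spacing: float
    slice_thickness: float
    slice_interval: float
    fov_diameter: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array (slice, row, col)")
        valid = {int(v) for v in TissueLabel}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown label values: {sorted(present - valid)}")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    def matches(self, volume: CTVolume) -> bool:
        return (
            self.labels.shape == volume.voxels.shape
            and self.pixel_spacing == volume.pixel_spacing
            and self.slice_interval == volume.slice_interval
        )

    def slice_areas(self, label: TissueLabel) -> np.ndarray:
        """Per-slice area of ``label`` in mm^2 (pixel count x spacing^2)."""
        counts = (self.labels == int(label)).sum(axis=(1, 2))
        return counts.astype(float) * self.pixel_spacing**2

    def with_labels(self, labels: np.ndarray) -> "LabelMask":
        return replace(self, labels=labels)


def check_paired(volume: CTVolume, mask: LabelMask) -> None:
    if not mask.matches(volume):
        raise ValueError("volume and mask geometry differ")
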