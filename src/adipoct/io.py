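"""Volume/mask persistence and cohort manifests.

The primary container is a compressed ``.npz`` array file with a JSON
sidecar carrying the geometry metadata.  Single-frame DICOM series export is
available when ``pydicom`` is installed (optional extra); the container
format round-trips losslessly and is the one the pipeline uses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CTVolume, LabelMask

MANIFEST_COLUMNS = [
    "subject_id",
    "scan_role",
    "day_offset",
    "ssde_mGy",
    "ssde_5_25_mGy",
    "thickness_mm",
    "truncated",
    "volume_path",
    "mask_path",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_volume(path: str | Path, volume: CTVolume, mask: LabelMask | None = None) -> Path:
    """Write a volume (and optional mask) as ``.npz`` + JSON geometry sidecar."""
    path = Path(path).with_suffix(".npz")
    arrays = {"voxels": volume.voxels}
    if mask is not None:
        arrays["labels"] = mask.labels
    np.savez_compressed(path, **arrays)
    meta = {
        "pixel_spacing_mm": volume.pixel_spacing,
        "slice_thickness_mm": volume.slice_thickness,
        "slice_interval_mm": volume.slice_interval,
        "fov_diameter_mm": volume.fov_diameter,
        "n_slices": volume.n_slices,
        "has_labels": mask is not None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def load_volume(path: str | Path) -> tuple[CTVolume, LabelMask | None]:
    path = Path(path).with_suffix(".npz")
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path) as data:
        common = dict(
            pixel_spacing=meta["pixel_spacing_mm"],
            slice_thickness=meta["slice_thickness_mm"],
            slice_interval=meta["slice_interval_mm"],
            fov_diameter=meta["fov_diameter_mm"],
        )
        volume = CTVolume(voxels=data["voxels"], **common)
        mask = LabelMask(labels=data["labels"], **common) if meta["has_labels"] else None
    return volume, mask


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest schema mismatch: missing {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Optional DICOM export (CT Image Storage, one file per slice)
# ---------------------------------------------------------------------------


def write_dicom_series(directory: str | Path, volume: CTVolume, series_desc: str = "adipoct") -> list[Path]:
    """Write the stack as single-frame CT DICOM files (requires pydicom)."""
    try:
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("DICOM export requires the optional 'pydicom' dependency") from exc

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    intercept, slope = -1024.0, 1.0
    stored = np.round((volume.voxels - intercept) / slope).astype(np.uint16)
    for k in range(volume.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesDescription = series_desc
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, -k * volume.slice_interval]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [volume.pixel_spacing, volume.pixel_spacing]
        ds.SliceThickness = volume.slice_thickness
        ds.SpacingBetweenSlices = volume.slice_interval
        ds.Rows, ds.Columns = stored.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = intercept
        ds.RescaleSlope = slope
        ds.PixelData = stored[k].tobytes()
        path = directory / f"slice{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_dicom_series(directory: str | Path) -> CTVolume:
    """Read a single-frame CT series back into a volume (requires pydicom)."""
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("DICOM import requires the optional 'pydicom' dependency") from exc

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda d: int(d.InstanceNumber))
    slices = [
        d.pixel_array.astype(np.float32) * float(d.RescaleSlope) + float(d.RescaleIntercept)
        for d in datasets
    ]
    first = datasets[0]
    return CTVolume(
        voxels=np.stack(slices),
        pixel_spacing=float(first.PixelSpacing[0]),
        slice_thickness=float(first.SliceThickness),
        slice_interval=float(getattr(first, "SpacingBetweenSlices", first.SliceThickness)),
        fov_diameter=float(first.PixelSpacing[0]) * int(first.Columns),
    )
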