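"""Volume and report I/O.

Volumes are read from NIfTI files (.nii/.nii.gz) or DICOM series
directories.  Arrays are indexed (x, y, z), 0-based; spacing in mm comes
from the file header.  Masks are written back as NIfTI on the grid of the
input volume.  Reports go out as JSON (full structure, config echo
included) and CSV (flat rows, stable column order).
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np

from .grid import BinaryMask, ScalarVolume

__all__ = ["read_volume", "write_volume", "write_mask", "write_report"]


def read_volume(path: str | os.PathLike) -> ScalarVolume:
    """Read a NIfTI file or a DICOM series directory into a ScalarVolume."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume: {p}")
    if p.is_dir():
        return _read_dicom_series(p)
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume in {p}, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ScalarVolume(data, spacing=tuple(float(z) for z in zooms),
                        origin=origin)


def _read_dicom_series(directory: Path) -> ScalarVolume:
    """Read a single-frame DICOM series; slices sorted by position."""
    import pydicom

    slices = []
    for f in sorted(directory.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image files in {directory}")

    def sort_key(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        # pixel_array is (row, col) = (y, x); transpose to (x, y)
        planes.append((arr * slope + intercept).T)
    data = np.stack(planes, axis=2)
    first = slices[0]
    dy, dx = (float(v) for v in getattr(first, "PixelSpacing", (1.0, 1.0)))
    if len(slices) > 1 and hasattr(first, "ImagePositionPatient"):
        dz = abs(float(slices[1].ImagePositionPatient[2])
                 - float(first.ImagePositionPatient[2]))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    if dz == 0:
        dz = float(getattr(first, "SliceThickness", 1.0)) or 1.0
    origin = tuple(float(v) for v in getattr(
        first, "ImagePositionPatient", (0.0, 0.0, 0.0)))
    return ScalarVolume(data, spacing=(dx, dy, dz), origin=origin)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: ScalarVolume, path: str | os.PathLike) -> None:
    p = Path(path)
    if not p.parent.exists():
        raise FileNotFoundError(f"parent directory missing: {p.parent}")
    img = nib.Nifti1Image(volume.voxels.astype(np.float32),
                          _affine(volume.spacing, volume.origin))
    nib.save(img, str(p))


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a {0,1} NIfTI mask on the grid of its parent volume."""
    p = Path(path)
    if not p.parent.exists():
        raise FileNotFoundError(f"parent directory missing: {p.parent}")
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8),
                          _affine(mask.spacing, mask.origin))
    nib.save(img, str(p))


def write_report(report: dict[str, Any], path: str | os.PathLike,
                 csv_rows: list[dict[str, Any]] | None = None,
                 csv_columns: list[str] | None = None) -> None:
    """Write a JSON report; optionally a sibling CSV with stable columns.

    The CSV lands next to the JSON with a ``.csv`` suffix.
    """
    p = Path(path)
    if not p.parent.exists():
        raise FileNotFoundError(f"parent directory missing: {p.parent}")
    with open(p, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")
    if csv_rows is not None:
        import pandas as pd

        df = pd.DataFrame(csv_rows)
        if csv_columns:
            df = df.reindex(columns=csv_columns)
        df.to_csv(p.with_suffix(".csv"), index=False)
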