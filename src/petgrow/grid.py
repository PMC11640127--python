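"""Voxel-lattice containers: scalar activity volumes and binary masks.

Arrays are indexed ``(x, y, z)``; spacing is given in mm per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScalarVolume", "BinaryMask"]


@dataclass
class ScalarVolume:
    """3D activity lattice (SUV or Bq/mL) with mm voxel spacing."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def voxel_volume_ccm(self) -> float:
        return self.voxel_volume_mm3 / 1000.0


@dataclass
class BinaryMask:
    """{0,1} lattice on the grid of a parent :class:`ScalarVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_ccm(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def volume_ccm(self) -> float:
        return self.count * self.voxel_volume_ccm
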