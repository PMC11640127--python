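"""Texture features used as region-growing stop criteria.

Three features summarise the activity distribution inside a candidate
region of a PET volume:

* **Kurtosis (KU)** — normalized fourth central moment of the voxel
  activities, Pearson convention (a normal distribution gives 3).
  Population (1/N) moments are used throughout.
* **Local Entropy (LE)** — Shannon entropy, in bits by default, of the
  normalized gray-level co-occurrence matrix (GLCM) of the region.
* **Long-Zone Emphasis (LZE)** — size-squared-weighted mean zone size of
  the gray-level size-zone matrix (GLSZM); large for homogeneous regions
  that form big connected zones of equal gray level.

KU is computed on raw activities; LE and LZE require the activities to be
discretized to ``G`` gray levels first (fixed bin count, bounds normally
taken from the seed-centered search volume so that features are comparable
across growth iterations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, ScalarVolume

__all__ = [
    "RegionSample",
    "GrayLevelImage",
    "CooccurrenceMatrix",
    "SizeZoneMatrix",
    "TextureFeatures",
    "UNIQUE_3D_DIRECTIONS",
    "discretize",
    "compute_glcm",
    "compute_glszm",
    "kurtosis",
    "local_entropy",
    "long_zone_emphasis",
    "region_features",
]


def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    """The 13 unique 3D direction vectors at Chebyshev distance 1.

    One representative per antipodal pair of the 26 neighbors; with
    symmetric pair counting these cover all 26 directions.
    """
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) > (0, 0, 0):
                    dirs.append((dx, dy, dz))
    return tuple(dirs)


#: Default GLCM offsets: 13 unique distance-1 directions, aggregated into
#: one symmetric matrix (common 3D radiomics practice).
UNIQUE_3D_DIRECTIONS: tuple[tuple[int, int, int], ...] = _unique_directions()


@dataclass
class RegionSample:
    """First-order summary of the activities in a region.

    Parameters are the quantities entering the kurtosis formula: the voxel
    values, their count N, mean, and *population* standard deviation.
    """

    values: np.ndarray
    count: int
    mean: float
    stdv: float

    @classmethod
    def from_values(cls, values: Sequence[float] | np.ndarray) -> "RegionSample":
        v = np.asarray(values, dtype=np.float64).ravel()
        if v.size < 1:
            raise ValueError("empty region")
        return cls(values=v, count=int(v.size), mean=float(v.mean()),
                   stdv=float(v.std(ddof=0)))


@dataclass
class GrayLevelImage:
    """Discretized region: integer level in [1..G] per region voxel.

    ``levels`` is a full-grid integer array with 0 outside the region.
    ``bounds`` records the (lo, hi) activity window used for binning.
    """

    levels: np.ndarray
    G: int
    bounds: tuple[float, float]

    @property
    def region(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


@dataclass
class CooccurrenceMatrix:
    """Normalized G×G gray-level co-occurrence matrix (GLCM).

    ``entries[i-1, j-1]`` is the probability of observing levels (i, j) at
    the given voxel offsets; symmetric counting means each ordered pair is
    counted in both orders before normalization.
    """

    entries: np.ndarray
    G: int
    offsets: tuple[tuple[int, int, int], ...]
    symmetric: bool = True


@dataclass
class SizeZoneMatrix:
    """G×S_max gray-level size-zone matrix (GLSZM).

    ``entries[i-1, s-1]`` counts the maximal connected zones of gray level
    i having exactly s voxels, under the stated connectivity.
    """

    entries: np.ndarray
    G: int
    connectivity: int = 26

    @property
    def total_zones(self) -> int:
        return int(self.entries.sum())

    @property
    def total_voxels(self) -> int:
        sizes = np.arange(1, self.entries.shape[1] + 1)
        return int((self.entries * sizes[None, :]).sum())


@dataclass
class TextureFeatures:
    """The three stop-criterion feature values for one region."""

    ku: float
    le: float
    lze: float

    def value(self, name: str) -> float:
        return {"ku": self.ku, "le": self.le, "lze": self.lze}[name.lower()]


def discretize(
    volume: ScalarVolume,
    region: BinaryMask | np.ndarray,
    G: int,
    bounds: tuple[float, float] | None = None,
) -> GrayLevelImage:
    """Bin region activities into ``G`` fixed-width gray levels.

    The level of a voxel with activity x is
    ``min(G, 1 + floor(G * (x - lo) / (hi - lo)))`` with (lo, hi) taken
    from ``bounds`` if given, else the min/max over the region.  A
    degenerate window (lo == hi) maps every voxel to level 1.  Values
    outside an explicit window are clipped into [1, G].
    """
    mask = region.voxels if isinstance(region, BinaryMask) else np.asarray(region, bool)
    if mask.shape != volume.shape:
        raise ValueError("region shape does not match volume")
    if not mask.any():
        raise ValueError("empty region")
    if G < 2:
        raise ValueError("G must be >= 2")
    vals = volume.voxels[mask]
    if bounds is None:
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = float(bounds[0]), float(bounds[1])
        if lo > hi:
            raise ValueError("bounds must satisfy lo <= hi")
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
    else:
        lev = 1 + np.floor(G * (vals - lo) / (hi - lo))
        levels[mask] = np.clip(lev, 1, G).astype(np.int32)
    return GrayLevelImage(levels=levels, G=int(G), bounds=(lo, hi))


def compute_glcm(
    gray: GrayLevelImage,
    offsets: Sequence[tuple[int, int, int]] | None = None,
) -> CooccurrenceMatrix:
    """Build the symmetric normalized GLCM of a discretized region.

    For every offset, every ordered voxel pair with both endpoints inside
    the region is counted; counts are symmetrized (each pair contributes in
    both orders) and normalized to sum to 1.
    """
    if offsets is None:
        offsets = UNIQUE_3D_DIRECTIONS
    offsets = tuple(tuple(int(c) for c in o) for o in offsets)
    if not offsets:
        raise ValueError("offsets must be non-empty")
    L = gray.levels
    if not (L > 0).any():
        raise ValueError("empty region")
    G = gray.G
    counts = np.zeros((G, G), dtype=np.float64)
    shape = L.shape
    for off in offsets:
        src = tuple(
            slice(max(0, -d), min(s, s - d)) for d, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, d), min(s, s + d)) for d, s in zip(off, shape)
        )
        a = L[src]
        b = L[dst]
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        idx = (a[ok].astype(np.int64) - 1) * G + (b[ok].astype(np.int64) - 1)
        counts += np.bincount(idx, minlength=G * G).reshape(G, G)
    counts = counts + counts.T  # symmetric counting
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurring pairs")
    return CooccurrenceMatrix(entries=counts / total, G=G, offsets=offsets,
                              symmetric=True)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def compute_glszm(gray: GrayLevelImage, connectivity: int = 26) -> SizeZoneMatrix:
    """Build the GLSZM: zone counts by gray level and zone size.

    A zone is a maximal connected set of equal-level voxels (default
    26-connectivity).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    L = gray.levels
    if not (L > 0).any():
        raise ValueError("empty region")
    structure = _STRUCTURES[connectivity]
    G = gray.G
    per_level: dict[int, np.ndarray] = {}
    s_max = 1
    for lev in np.unique(L[L > 0]):
        labeled, n = ndimage.label(L == lev, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        per_level[int(lev)] = sizes
        s_max = max(s_max, int(sizes.max()))
    entries = np.zeros((G, s_max), dtype=np.int64)
    for lev, sizes in per_level.items():
        for s in sizes:
            entries[lev - 1, int(s) - 1] += 1
    return SizeZoneMatrix(entries=entries, G=G, connectivity=connectivity)


def kurtosis(sample: RegionSample | Sequence[float] | np.ndarray) -> float:
    """Pearson (non-excess) kurtosis of the region activities.

    ``(1/N) * sum(((x_i - mean) / stdv)^4)`` with population moments; a
    normal distribution gives 3.  Requires at least 4 voxels and non-zero
    spread.
    """
    if not isinstance(sample, RegionSample):
        sample = RegionSample.from_values(sample)
    if sample.count < 4:
        raise ValueError("too few voxels")
    if sample.stdv == 0:
        raise ValueError("degenerate region (constant uptake)")
    z = (sample.values - sample.mean) / sample.stdv
    return float(np.mean(z ** 4))


def local_entropy(m: CooccurrenceMatrix, base: float = 2.0) -> float:
    """Shannon entropy of the co-occurrence distribution (bits by default).

    ``-sum(p * log(p))`` over non-zero cells, with 0·log 0 := 0.  Raises if
    the matrix is not normalized.
    """
    p = np.asarray(m.entries, dtype=np.float64)
    total = p.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-8):
        raise ValueError("co-occurrence matrix is not normalized")
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(base))).sum())


def long_zone_emphasis(m: SizeZoneMatrix) -> float:
    """Size-squared-weighted mean zone size, ``sum(m_ij j^2) / sum(m_ij)``.

    Equals 1 when every zone is a single voxel, and n^2 for a single zone
    of n voxels.
    """
    entries = np.asarray(m.entries, dtype=np.float64)
    total = entries.sum()
    if total == 0:
        raise ValueError("empty size-zone matrix")
    sizes = np.arange(1, entries.shape[1] + 1, dtype=np.float64)
    return float((entries * sizes[None, :] ** 2).sum() / total)


def region_features(
    volume: ScalarVolume,
    region: BinaryMask | np.ndarray,
    G: int = 64,
    offsets: Sequence[tuple[int, int, int]] | None = None,
    connectivity: int = 26,
    bounds: tuple[float, float] | None = None,
) -> TextureFeatures:
    """Compute KU, LE and LZE for one region on a shared discretization."""
    mask = region.voxels if isinstance(region, BinaryMask) else np.asarray(region, bool)
    try:
        ku = kurtosis(volume.voxels[mask])
    except ValueError as e:
        raise ValueError(f"KU failed: {e}") from e
    gray = discretize(volume, mask, G=G, bounds=bounds)
    try:
        le = local_entropy(compute_glcm(gray, offsets=offsets))
    except ValueError as e:
        raise ValueError(f"LE failed: {e}") from e
    try:
        lze = long_zone_emphasis(compute_glszm(gray, connectivity=connectivity))
    except ValueError as e:
        raise ValueError(f"LZE failed: {e}") from e
    return TextureFeatures(ku=ku, le=le, lze=lze)
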