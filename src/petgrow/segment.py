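"""Seeded lesion segmentation on PET volumes.

Two delineation methods share the same seed-and-search-volume contract:

* :func:`region_grow_segment` — texture-feature region growing.  Starting
  from a small cube around the user-provided seed, the region grows by
  intensity-ordered flooding: the brightest 26-connected boundary voxel is
  absorbed first, so the region tracks superlevel sets of the local uptake
  (clipped to the search volume).  One *iteration* is a ~10% increase in
  region size; after every iteration the configured texture feature (KU,
  LE or LZE) is evaluated on the grown region, and growth stops at the
  first iteration whose feature value crosses the configured threshold.
  The region of the *previous* iteration is returned — the crossing region
  has already absorbed background.
* :func:`threshold_segment` — the conventional baseline: the 26-connected
  component around the seed of all voxels at or above a fixed fraction
  (default 40%) of the maximum uptake in the search volume.

Both report the segmented volume in ccm and the maximal lesion diameter
in mm.  Stop thresholds for the texture features are not universal
constants; :func:`calibrate_stop_threshold` derives them from phantoms
with known truth masks by exhaustive Dice-maximizing grid search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .grid import BinaryMask, ScalarVolume
from . import texture

__all__ = [
    "GrowthConfig",
    "SegmentationResult",
    "CalibrationResult",
    "region_grow_segment",
    "threshold_segment",
    "measure_mask",
    "calibrate_stop_threshold",
    "dice",
]

_FEATURES = ("ku", "le", "lze")
_DIRECTIONS = ("rising", "falling")

_STRUCT26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class GrowthConfig:
    """Parameters of the texture-feature region-growing algorithm.

    feature
        Stop-criterion feature: ``"ku"``, ``"le"`` or ``"lze"``.
    stop_threshold, direction
        Growth stops at the first iteration whose feature value is >= the
        threshold (``"rising"``) or <= it (``"falling"``).
    init_halfwidth
        Half-width in voxels of the seed-centered initial cube (1 gives
        the default 3×3×3 region).
    growth_factor
        Relative region growth per iteration (1.1 = one feature
        evaluation per ~10% volume increase); voxels are absorbed in
        decreasing-intensity order within and across iterations.
    search_halfwidth_mm
        Half-width of the cubic search volume around the seed; bounds
        runaway growth and defines the discretization window.
    G, offsets, connectivity
        Forwarded to the texture module.
    bounds_mode
        ``"search"`` (default): gray-level bounds taken once from the
        search volume so features are comparable across iterations;
        ``"region"``: re-binned per iteration from the current region.
    """

    feature: str = "le"
    stop_threshold: float = 0.0
    direction: str = "rising"
    init_halfwidth: int = 1
    growth_factor: float = 1.1
    max_iterations: int = 60
    search_halfwidth_mm: float = 100.0
    G: int = 64
    offsets: tuple[tuple[int, int, int], ...] | None = None
    connectivity: int = 26
    bounds_mode: str = "search"

    def __post_init__(self) -> None:
        self.feature = self.feature.lower()
        if self.feature not in _FEATURES:
            raise ValueError(f"feature must be one of {_FEATURES}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.init_halfwidth < 1:
            raise ValueError("init_halfwidth must be >= 1")
        if self.growth_factor <= 1.0:
            raise ValueError("growth_factor must be > 1")
        if self.search_halfwidth_mm <= 0:
            raise ValueError("search_halfwidth_mm must be positive")
        if self.bounds_mode not in ("search", "region"):
            raise ValueError("bounds_mode must be 'search' or 'region'")


@dataclass
class SegmentationResult:
    """Mask plus measurements and the growth record of one segmentation."""

    mask: BinaryMask
    volume_ccm: float
    max_diameter_mm: float
    iterations: int
    trajectory: list[float]
    stop_reason: str
    method: str = ""

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "volume_ccm": self.volume_ccm,
            "max_diameter_mm": self.max_diameter_mm,
            "iterations": self.iterations,
            "trajectory": list(self.trajectory),
            "stop_reason": self.stop_reason,
            "voxel_count": self.mask.count,
        }


@dataclass
class CalibrationResult:
    stop_threshold: float
    direction: str
    mean_dice: float
    feature: str = ""


def dice(a: np.ndarray | BinaryMask, b: np.ndarray | BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 0 when both masks are empty."""
    av = a.voxels if isinstance(a, BinaryMask) else np.asarray(a, bool)
    bv = b.voxels if isinstance(b, BinaryMask) else np.asarray(b, bool)
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((av & bv).sum()) / denom


def _search_box(volume: ScalarVolume, seed: tuple[int, int, int],
                halfwidth_mm: float) -> tuple[slice, slice, slice]:
    slices = []
    for axis in range(3):
        hw = int(np.floor(halfwidth_mm / volume.spacing[axis]))
        lo = max(0, seed[axis] - hw)
        hi = min(volume.shape[axis], seed[axis] + hw + 1)
        slices.append(slice(lo, hi))
    return tuple(slices)


def _check_seed(volume: ScalarVolume, seed: Sequence[int]) -> tuple[int, int, int]:
    seed = tuple(int(c) for c in seed)
    if len(seed) != 3 or any(
        c < 0 or c >= s for c, s in zip(seed, volume.shape)
    ):
        raise ValueError("seed outside volume")
    return seed


def _evaluate_feature(volume: ScalarVolume, region: np.ndarray,
                      config: GrowthConfig,
                      bounds: tuple[float, float] | None) -> float:
    """Evaluate only the configured feature (cheaper than all three)."""
    if config.feature == "ku":
        return texture.kurtosis(volume.voxels[region])
    gray = texture.discretize(volume, region, G=config.G, bounds=bounds)
    if config.feature == "le":
        return texture.local_entropy(texture.compute_glcm(gray, config.offsets))
    return texture.long_zone_emphasis(
        texture.compute_glszm(gray, connectivity=config.connectivity)
    )


_NEIGHBORS26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _grow_iterations(volume: ScalarVolume, seed: tuple[int, int, int],
                     config: GrowthConfig):
    """Yield (region, feature) per iteration; raise on a degenerate seed.

    The first yielded region is the seed-centered initial cube.  Growth
    then floods in decreasing-intensity order: a max-heap holds the
    26-connected boundary voxels and the brightest is absorbed first, with
    deterministic index-order tie-breaking.  One iteration corresponds to
    a ``growth_factor``-fold region size increase; the configured feature
    is evaluated on the region after each iteration.  Iteration ends when
    the search volume is exhausted or ``max_iterations`` is reached.
    Yielded masks are full-grid and nested (each a strict superset of the
    previous one).
    """
    import heapq

    box = _search_box(volume, seed, config.search_halfwidth_mm)
    sub = np.ascontiguousarray(volume.voxels[box])  # crop: all growth is in-box
    cropped = ScalarVolume(sub, spacing=volume.spacing)
    shape = sub.shape
    if config.bounds_mode == "search":
        bounds = (float(sub.min()), float(sub.max()))
    else:
        bounds = None
    seed_c = tuple(seed[a] - box[a].start for a in range(3))

    region = np.zeros(shape, dtype=bool)
    init = tuple(
        slice(max(0, seed_c[a] - config.init_halfwidth),
              min(shape[a], seed_c[a] + config.init_halfwidth + 1))
        for a in range(3)
    )
    region[init] = True
    size = int(region.sum())
    if size < 4:
        raise ValueError("uninformative seed region")
    init_vals = sub[region]
    if float(init_vals.max()) == float(init_vals.min()):
        raise ValueError("uninformative seed region (constant uptake)")

    def full_mask() -> np.ndarray:
        m = np.zeros(volume.shape, dtype=bool)
        m[box] = region
        return m

    def evaluate() -> float:
        try:
            return _evaluate_feature(cropped, region, config, bounds)
        except ValueError as e:
            raise ValueError(
                f"feature undefined on region of {size} voxels ({e})") from e

    try:
        f = evaluate()
    except ValueError as e:
        raise ValueError(f"uninformative seed region ({e})") from e
    yield full_mask(), f

    heap: list[tuple[float, int, int, int]] = []
    queued = region.copy()

    def push_neighbors(x: int, y: int, z: int) -> None:
        for dx, dy, dz in _NEIGHBORS26:
            nx, ny, nz = x + dx, y + dy, z + dz
            if (0 <= nx < shape[0] and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2] and not queued[nx, ny, nz]):
                queued[nx, ny, nz] = True
                heapq.heappush(heap, (-sub[nx, ny, nz], nx, ny, nz))

    for x, y, z in np.argwhere(region):
        push_neighbors(int(x), int(y), int(z))

    iterations = 1
    while iterations < config.max_iterations and heap:
        last_size = size
        target = max(size + 1, int(np.ceil(size * config.growth_factor)))
        while size < target and heap:
            _, x, y, z = heapq.heappop(heap)
            region[x, y, z] = True
            size += 1
            push_neighbors(x, y, z)
        if size == last_size:
            return  # search volume exhausted
        iterations += 1
        yield full_mask(), evaluate()


def _crossed(f: float, config: GrowthConfig) -> bool:
    if config.direction == "rising":
        return f >= config.stop_threshold
    return f <= config.stop_threshold


def region_grow_segment(volume: ScalarVolume, seed: Sequence[int],
                        config: GrowthConfig) -> SegmentationResult:
    """Segment one lesion by texture-feature region growing.

    ``seed`` is a 0-based (x, y, z) voxel index, typically the visual
    center of the lesion.  Deterministic: identical inputs give an
    identical mask and trajectory.
    """
    seed = _check_seed(volume, seed)
    if volume.voxels[seed] <= 0:
        raise ValueError("seed uptake must be positive")

    rising = config.direction == "rising"
    trajectory: list[float] = []
    prev: np.ndarray | None = None
    last: np.ndarray | None = None
    best: np.ndarray | None = None  # closest approach to the threshold
    best_f = -np.inf if rising else np.inf
    stop_reason = "search_bound"
    for region, f in _grow_iterations(volume, seed, config):
        trajectory.append(f)
        if _crossed(f, config):
            # return the region before the crossing; at the very first
            # iteration there is no previous region, so the init region
            # itself is returned.
            last = prev if prev is not None else region
            stop_reason = "threshold_crossed"
            break
        prev = region
        last = region
        if (f > best_f) if rising else (f < best_f):
            best_f, best = f, region
        if len(trajectory) >= config.max_iterations:
            stop_reason = "max_iterations"
            break
    if stop_reason != "threshold_crossed":
        # the threshold was never crossed: the best available estimate is
        # the iteration whose feature value came closest to it, not the
        # runaway final region.
        if best is not None:
            last = best
        warnings.warn(
            f"stop threshold never crossed ({stop_reason})", stacklevel=2
        )
    mask = BinaryMask(last, spacing=volume.spacing, origin=volume.origin)
    vol_ccm, diam_mm = measure_mask(mask)
    return SegmentationResult(
        mask=mask, volume_ccm=vol_ccm, max_diameter_mm=diam_mm,
        iterations=len(trajectory), trajectory=trajectory,
        stop_reason=stop_reason, method=config.feature,
    )


def threshold_segment(volume: ScalarVolume, seed: Sequence[int],
                      fraction: float = 0.40,
                      search_halfwidth_mm: float = 100.0) -> SegmentationResult:
    """Variable-threshold baseline: fraction of the local maximum uptake.

    The threshold is ``fraction`` × the maximum uptake inside the
    seed-centered search volume (not the whole scan, so multiple lesions
    per scan stay independent); the mask is the 26-connected component of
    supra-threshold voxels containing the seed.
    """
    seed = _check_seed(volume, seed)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    box = _search_box(volume, seed, search_halfwidth_mm)
    inside = np.zeros(volume.shape, dtype=bool)
    inside[box] = True
    vmax = float(volume.voxels[box].max())
    thr = fraction * vmax
    candidate = (volume.voxels >= thr) & inside
    labeled, _ = ndimage.label(candidate, structure=_STRUCT26)
    lab = labeled[seed]
    if lab == 0:
        raise ValueError("seed disconnected from lesion")
    mask = BinaryMask(labeled == lab, spacing=volume.spacing,
                      origin=volume.origin)
    vol_ccm, diam_mm = measure_mask(mask)
    return SegmentationResult(
        mask=mask, volume_ccm=vol_ccm, max_diameter_mm=diam_mm,
        iterations=0, trajectory=[], stop_reason="threshold_crossed",
        method="threshold40" if fraction == 0.40 else f"threshold{fraction:g}",
    )


def measure_mask(mask: BinaryMask) -> tuple[float, float]:
    """Volume in ccm and exact maximal diameter in mm of a mask.

    The diameter is the maximum pairwise Euclidean distance between voxel
    centers; for large masks the convex hull prunes the pair scan without
    changing the result.
    """
    coords = np.argwhere(mask.voxels)
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    vol_ccm = coords.shape[0] * mask.voxel_volume_ccm
    pts = coords * np.asarray(mask.spacing, dtype=np.float64)
    if pts.shape[0] == 1:
        return vol_ccm, 0.0
    if pts.shape[0] > 400:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (flat/collinear) mask: scan all pairs
    return vol_ccm, float(pdist(pts).max())


def calibrate_stop_threshold(
    phantoms: Iterable[tuple[ScalarVolume, BinaryMask, Sequence[int]]],
    feature: str,
    grid: Sequence[float] | None = None,
    config: GrowthConfig | None = None,
    grid_size: int = 25,
) -> CalibrationResult:
    """Pick the (threshold, direction) maximizing mean Dice on phantoms.

    Growth is purely geometric, so the iteration trajectory of each
    phantom is computed once and every candidate (threshold, direction)
    pair is scored against it.  With ``grid=None`` the candidate
    thresholds are ``grid_size`` values evenly spanning the observed
    feature range across all trajectories.  Ties are broken toward the
    smaller threshold, then the rising direction.
    """
    base = config if config is not None else GrowthConfig(feature=feature)
    base = replace(base, feature=feature.lower(),
                   stop_threshold=float("nan"))
    records = []  # (feats, masks, truth)
    for volume, truth, seed in phantoms:
        seed = _check_seed(volume, seed)
        masks: list[np.ndarray] = []
        feats: list[float] = []
        try:
            for region, f in _grow_iterations(volume, seed, base):
                masks.append(region)
                feats.append(f)
        except ValueError:
            continue
        if masks:
            records.append((np.asarray(feats), masks, truth.voxels))
    if not records:
        raise ValueError("calibration failed")

    if grid is None:
        all_f = np.concatenate([r[0] for r in records])
        grid = np.linspace(all_f.min(), all_f.max(), grid_size)
    grid = sorted(float(t) for t in grid)
    if not grid:
        raise ValueError("calibration failed: empty grid")

    best: CalibrationResult | None = None
    for thr in grid:
        for direction in _DIRECTIONS:
            dices = []
            for feats, masks, truth_vox in records:
                cross = feats >= thr if direction == "rising" else feats <= thr
                idx = int(np.argmax(cross)) if cross.any() else None
                if idx is None:
                    # never crossed: closest approach, as in region_grow_segment
                    ext = int(np.argmax(feats)) if direction == "rising" \
                        else int(np.argmin(feats))
                    region = masks[ext]
                elif idx == 0:
                    region = masks[0]
                else:
                    region = masks[idx - 1]
                dices.append(dice(region, truth_vox))
            mean_dice = float(np.mean(dices))
            if best is None or mean_dice > best.mean_dice:
                best = CalibrationResult(stop_threshold=thr,
                                         direction=direction,
                                         mean_dice=mean_dice,
                                         feature=base.feature)
    assert best is not None
    return best
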