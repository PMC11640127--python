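"""Digital PET phantoms with known ground truth.

Phantoms emulate a clinical whole-body FDG acquisition at desk scale:
ellipsoidal hot lesions on a warm background, rasterized with sub-voxel
occupancy on a 128×128 matrix with 5 mm slices (4×4×5 mm voxels), blurred
with an isotropic Gaussian point-spread function (default 7 mm FWHM:
a 5 mm post-reconstruction filter combined with scanner intrinsic
resolution) and degraded with seeded Gaussian noise whose variance scales
Poisson-like with activity.

Each phantom carries analytic truth: the exact ellipsoid volume, a truth
mask at 50% voxel occupancy, and an interior seed voxel — so segmentation
accuracy can be scored where a pathological gold standard is unavailable.

Two packaged suites drive calibration and evaluation:

* ``calibration`` — six spheres, diameters 16–50 mm;
* ``evaluation`` — ten ellipsoids spanning roughly 1–100 ccm, including
  three lesions below 3 ccm and two above 45 ccm, so size-subgroup
  analyses at the 3 and 45 ccm cutoffs are exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, ScalarVolume

__all__ = [
    "Lesion",
    "PhantomSpec",
    "PhantomOutput",
    "rasterize",
    "apply_psf",
    "add_noise",
    "make_phantom",
    "make_suite",
    "CALIBRATION_SEED_BASE",
    "EVALUATION_SEED_BASE",
]

#: Packaged suite seeds (disjoint between suites).
CALIBRATION_SEED_BASE = 20_100
EVALUATION_SEED_BASE = 30_500

GAUSS_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # 1 / (2 sqrt(2 ln 2))


@dataclass
class Lesion:
    """Analytic ellipsoid: center (mm), semi-axes (mm), activity."""

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    activity: float

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semiaxes_mm):
            raise ValueError("semi-axes must be positive")

    @property
    def volume_ccm(self) -> float:
        a, b, c = self.semiaxes_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


@dataclass
class PhantomSpec:
    """Geometry plus imaging model of one digital phantom."""

    shape: tuple[int, int, int] = (128, 128, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 5.0)
    background_activity: float = 1.0
    lesions: list[Lesion] = field(default_factory=list)
    psf_fwhm_mm: float = 7.0
    noise_fraction: float = 0.05
    rng_seed: int = 0


@dataclass
class PhantomOutput:
    """Simulated volume plus per-lesion ground truth."""

    volume: ScalarVolume
    truth_masks: list[BinaryMask]
    truth_volumes_ccm: list[float]
    seeds: list[tuple[int, int, int]]
    spec: PhantomSpec


def _occupancy(spec: PhantomSpec, lesion: Lesion, subdiv: int = 4) -> tuple[tuple[slice, ...], np.ndarray]:
    """Fractional ellipsoid occupancy per voxel over the lesion bounding box.

    Each voxel is subdivided subdiv³ ways and the fraction of sub-voxel
    centers inside the analytic ellipsoid is returned.
    """
    spacing = np.asarray(spec.spacing)
    center = np.asarray(lesion.center_mm)
    semi = np.asarray(lesion.semiaxes_mm)
    lo_idx = np.floor((center - semi) / spacing - 1).astype(int)
    hi_idx = np.ceil((center + semi) / spacing + 1).astype(int)
    if np.any(lo_idx < 0) or np.any(hi_idx > np.asarray(spec.shape)):
        raise ValueError("lesion outside grid")
    box = tuple(slice(int(l), int(h)) for l, h in zip(lo_idx, hi_idx))
    axes = [
        (np.arange(s.start, s.stop) + 0.5) * sp
        for s, sp in zip(box, spacing)
    ]
    # sub-voxel center offsets within one voxel, per axis
    sub = [(np.arange(subdiv) + 0.5) / subdiv - 0.5 for _ in range(3)]
    occ = np.zeros(tuple(s.stop - s.start for s in box))
    for ox in sub[0] * spacing[0]:
        u = ((axes[0] + ox - center[0]) / semi[0]) ** 2
        for oy in sub[1] * spacing[1]:
            v = ((axes[1] + oy - center[1]) / semi[1]) ** 2
            uv = u[:, None] + v[None, :]
            for oz in sub[2] * spacing[2]:
                w = ((axes[2] + oz - center[2]) / semi[2]) ** 2
                occ += (uv[:, :, None] + w[None, None, :]) <= 1.0
    return box, occ / subdiv ** 3


def rasterize(spec: PhantomSpec, subdiv: int = 4) -> tuple[ScalarVolume, list[BinaryMask]]:
    """Noise-free, blur-free activity volume plus 50%-occupancy truth masks.

    Voxel activity is background + Σ (lesion − background) · occupancy,
    with occupancy from sub-voxel sampling of the analytic ellipsoid.
    """
    vox = np.full(spec.shape, float(spec.background_activity))
    masks = []
    for lesion in spec.lesions:
        box, occ = _occupancy(spec, lesion, subdiv=subdiv)
        vox[box] += (lesion.activity - spec.background_activity) * occ
        m = np.zeros(spec.shape, dtype=bool)
        m[box] = occ >= 0.5
        masks.append(BinaryMask(m, spacing=spec.spacing))
    return ScalarVolume(vox, spacing=spec.spacing), masks


def apply_psf(volume: ScalarVolume, fwhm_mm: float) -> ScalarVolume:
    """Isotropic Gaussian blur: the partial-volume effect surrogate.

    σ = FWHM / 2.3548, converted to voxel units per axis; total activity
    is conserved away from the grid boundary.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return ScalarVolume(volume.voxels.copy(), spacing=volume.spacing,
                            origin=volume.origin)
    sigma_vox = [fwhm_mm * GAUSS_FWHM_TO_SIGMA / s for s in volume.spacing]
    blurred = ndimage.gaussian_filter(volume.voxels, sigma=sigma_vox,
                                      mode="nearest")
    return ScalarVolume(blurred, spacing=volume.spacing, origin=volume.origin)


def add_noise(volume: ScalarVolume, noise_fraction: float,
              rng_seed: int) -> ScalarVolume:
    """Seeded Gaussian noise with Poisson-like variance scaling.

    Per-voxel sd = noise_fraction · sqrt(value · max value); the noisy
    image is clipped at zero (PET activities are non-negative).
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be non-negative")
    if noise_fraction == 0:
        return ScalarVolume(volume.voxels.copy(), spacing=volume.spacing,
                            origin=volume.origin)
    rng = np.random.default_rng(rng_seed)
    vmax = float(volume.voxels.max())
    sd = noise_fraction * np.sqrt(np.clip(volume.voxels, 0, None) * vmax)
    noisy = np.clip(volume.voxels + rng.normal(size=volume.shape) * sd, 0, None)
    return ScalarVolume(noisy, spacing=volume.spacing, origin=volume.origin)


def make_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Rasterize → blur → noise, with truth carried through untouched."""
    clean, masks = rasterize(spec)
    blurred = apply_psf(clean, spec.psf_fwhm_mm)
    noisy = add_noise(blurred, spec.noise_fraction, spec.rng_seed)
    seeds = []
    for lesion, mask in zip(spec.lesions, masks):
        seed = tuple(
            int(round(c / s - 0.5))
            for c, s in zip(lesion.center_mm, spec.spacing)
        )
        if not mask.voxels[seed]:  # pragma: no cover - center is interior
            seed = tuple(int(i) for i in np.argwhere(mask.voxels)[0])
        seeds.append(seed)
    return PhantomOutput(
        volume=noisy,
        truth_masks=masks,
        truth_volumes_ccm=[l.volume_ccm for l in spec.lesions],
        seeds=seeds,
        spec=spec,
    )


#: Sphere diameters (mm) of the calibration suite.
CALIBRATION_DIAMETERS_MM = (16.0, 22.0, 28.0, 34.0, 42.0, 50.0)

#: Ellipsoid semi-axes (mm) of the evaluation suite, in increasing volume:
#: three lesions below 3 ccm, five between 3 and 45 ccm, two above 45 ccm.
EVALUATION_SEMIAXES_MM = (
    (6.5, 6.0, 6.0),     # 0.98 ccm
    (8.0, 7.0, 6.5),     # 1.52 ccm
    (9.5, 8.5, 8.0),     # 2.71 ccm
    (12.0, 10.0, 9.0),   # 4.52 ccm
    (14.0, 12.0, 11.0),  # 7.74 ccm
    (17.0, 14.0, 13.0),  # 12.96 ccm
    (20.0, 17.0, 15.0),  # 21.36 ccm
    (24.0, 20.0, 18.0),  # 36.19 ccm
    (28.0, 24.0, 22.0),  # 61.92 ccm
    (32.0, 28.0, 25.0),  # 93.83 ccm
)

#: Source-to-background ratio of both suites.
SUITE_SBR = 4.0


def make_suite(name: str, seed_base: int | None = None) -> list[PhantomOutput]:
    """Build a packaged phantom suite, one lesion per phantom.

    ``calibration``: 6 spheres (16–50 mm diameter).  ``evaluation``: 10
    ellipsoids spanning ~1–100 ccm.  Both use SBR 4:1, 7 mm FWHM PSF and
    5% noise with disjoint per-phantom seeds; results are bit-reproducible
    for a fixed ``seed_base``.
    """
    if name == "calibration":
        geoms = [(d / 2.0, d / 2.0, d / 2.0) for d in CALIBRATION_DIAMETERS_MM]
        base = CALIBRATION_SEED_BASE if seed_base is None else seed_base
    elif name == "evaluation":
        geoms = [tuple(s) for s in EVALUATION_SEMIAXES_MM]
        base = EVALUATION_SEED_BASE if seed_base is None else seed_base
    else:
        raise ValueError("suite name must be 'calibration' or 'evaluation'")
    outputs = []
    for i, semiaxes in enumerate(geoms):
        spec = PhantomSpec(
            lesions=[
                Lesion(
                    # at the center of voxel (64, 64, 24): the seed voxel
                    # center coincides with the analytic lesion center
                    center_mm=(258.0, 258.0, 122.5),
                    semiaxes_mm=semiaxes,
                    activity=SUITE_SBR,  # background is 1.0
                )
            ],
            rng_seed=int(base) + i,
        )
        outputs.append(make_phantom(spec))
    return outputs
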