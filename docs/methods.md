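# Methods

This note records the models implemented in `petgrow`, the defaults and
why they were chosen, what the phantom generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Texture features

All three stop-criterion features are computed on the voxels of the
current region only.

**Discretization.** LE and LZE require gray levels. Activities are
binned into `G = 64` fixed-width levels,
`level(x) = min(G, 1 + ⌊G·(x − lo)/(hi − lo)⌋)`, clipped into `[1, G]`
when explicit bounds are given. During region growing the bounds `(lo,
hi)` are taken **once** from the seed-centered search volume, not from
the current region: per-iteration re-binning would rescale the feature at
every step and make the stop trajectory incomparable across iterations.
A constant region maps to level 1.

**KU** is the population (1/N) standardized fourth moment — the Pearson
convention, so a normal activity distribution gives 3. It is undefined
(error) for fewer than 4 voxels or zero spread.

**LE** is the Shannon entropy, base 2 by default (bits, base
configurable), of the gray-level co-occurrence matrix: 13 unique
distance-1 3D directions, each voxel pair counted in both orders
(symmetric), aggregated into a single matrix and normalized to sum 1.
`0·log 0 := 0`. LE ranges over `[0, 2·log₂ G]`; it is 0 iff the
co-occurrence distribution is a point mass.

**LZE** is `Σ m_ij·j² / Σ m_ij` over the gray-level size-zone matrix
with 26-connected zones; 1 iff every zone is a single voxel, `n²` for a
single n-voxel zone.

## Region growing

The seed is a 0-based voxel index, conceptually the user's click at the
lesion center. The initial region is the seed-centered 3×3×3 cube. A
constant initial patch is rejected ("uninformative seed region") — the
features carry no information there.

**Growth order.** The region grows by intensity-ordered flooding: a
max-heap holds the 26-connected boundary voxels, and the brightest is
absorbed first (ties broken by voxel index, so growth is fully
deterministic). The intermediate regions therefore track superlevel sets
of the local uptake, which is what a hot-lesion segmentation should
interpolate through. A simpler alternative — dilating by a full
26-connected shell per iteration — was implemented first and rejected:
starting from a cube it produces only cube-shaped regions whose volumes
are quantized to (2k+1)³ voxels, a 2–3× jump per iteration at lesion
scale, so no stop rule can land near a target volume and recovered
volumes missed truth by 40–80% on spherical test lesions.

**Iterations and stopping.** One iteration is a `growth_factor = 1.1`
(~10%) increase in region size; after each, the configured feature is
evaluated on the full region. Growth stops at the first iteration whose
feature value crosses the stop threshold in the configured direction
(rising: `f ≥ T`; falling: `f ≤ T`), and the **previous** iteration's
region is returned — the crossing region has already absorbed background,
and returning it would build in systematic over-segmentation beyond the
~10% step size. The per-iteration feature values are returned as the
trajectory. If the threshold is never crossed (`max_iterations = 60`
reached, or the search volume exhausted), the region whose feature came
closest to the threshold is returned with a warning and
`stop_reason` set accordingly: the closest approach is the best available
estimate under the stop-criterion model, and it keeps failures bounded
(returning the runaway final region would report a search-volume-sized
mask for a small lesion).

**Search volume.** Growth and the discretization window are confined to
a cube of half-width `search_halfwidth_mm = 100` around the seed. This
bounds runaway growth in low-contrast cases and makes multi-lesion scans
separable; it is also why the 40% baseline takes its maximum there
rather than over the whole scan.

## Stop-threshold calibration

Stop thresholds depend on the gray-level count, the discretization
window, the acquisition and the noise level, so they are configuration,
not constants. `calibrate_stop_threshold` exploits the fact that the
growth *path* is independent of the threshold: per phantom it records the
full iteration trajectory once, then scores every candidate (threshold,
direction) pair by the Dice overlap of the region it would select against
the truth mask, and returns the pair maximizing mean Dice (ties toward
the smaller threshold, then rising). The default candidate grid is 25
thresholds evenly spanning the observed feature range. The shipped
defaults (`petgrow.defaults`) come from one run on the packaged 6-sphere
calibration suite; on it, LE achieves mean Dice 0.89, KU 0.79 and LZE
0.62 — the same ordering (LE most reliable, LZE weakest) reported for
this family of stop criteria on clinical lesions.

## Threshold baseline

`threshold_segment` takes the maximum uptake inside the search volume,
thresholds at 40% of it, and keeps the 26-connected supra-threshold
component containing the seed. Two properties matter for interpreting
results at the phantom's 4:1 lesion-to-background ratio:

- The blurred lesion edge sits at ~50% of the lesion/background contrast,
  i.e. at value `(4+1)/2 = 2.5` (background 1). 40% of a maximum of ~4 is
  ~1.6 < 2.5, so the mask necessarily extends **beyond** the true
  boundary: the baseline overestimates at this contrast (by +16% to +68%
  on the evaluation suite, worst for small lesions). The clinically
  reported tendency of 40%-threshold volumes to be *smaller* than
  texture-grown volumes holds at contrasts above ~5:1, where 40% of the
  maximum exceeds the edge value; at 4:1 the relation provably inverts,
  and the corresponding directional check in the acceptance tests
  documents this (it fails under these conditions, by design of the
  conditions, not of the code).
- For the smallest lesions the partial-volume effect pulls the maximum so
  low that 40% of it lands within ~1.3 noise-sd of the background mean —
  site occupancy near the 26-connectivity percolation threshold — and the
  component degenerates into a background spiderweb. This failure mode is
  real and is left observable.

## Measurements

Mask volume is voxel count × voxel volume (ccm). The maximal diameter is
the exact maximum pairwise Euclidean distance between voxel centers in
mm; above 400 voxels the convex hull prunes candidate pairs without
changing the result (with a plain all-pairs fallback for degenerate,
e.g. coplanar, masks).

## Agreement statistics

- Pathology reference: fresh-specimen axes `(a, b, c)` cm give
  `V = (π/6)abc` ccm and maximal diameter `10·max(a,b,c)` mm. Values are
  reported unrounded.
- Relative Bland–Altman: `d = 100·(test − gold)/pair mean`, bias =
  mean(d), limits of agreement = bias ± 1.96·sd(d) (sample sd). The
  pair-mean denominator is the standard choice for relative differences;
  a gold-denominated variant is available behind a flag and is used for
  the reported mean relative difference.
- RMS COV treats each (gold, test) pair as duplicate measurements of one
  lesion: `sd_i = |test − gold|/√2`, `cv_i = sd_i / pair mean`, COV =
  `100·√(mean cv_i²)`. It is symmetric in the pair and scale-invariant.
- Forkman's F-test for equality of two coefficients of variation uses
  the McKay-transformed statistic
  `F = [c₁²/(1 + c₁²(n₁−1)/n₁)] / [c₂²/(1 + c₂²(n₂−1)/n₂)]` referred to
  `F(n₁−1, n₂−1)`; the two-sided p doubles the smaller tail. Its type-I
  error is verified by seeded simulation (0.052 at nominal 0.05,
  n = 20 per sample, 2000 replicates).
- Subgroup reports repeat the battery for lesions whose pathological
  volume exceeds each cutoff (default 3 and 45 ccm); subgroups with
  fewer than 2 lesions are flagged unavailable rather than reported.

## Phantom generator

Each phantom is an analytic ellipsoid lesion on a uniform warm background
in a 128×128×48 grid at 4×4×5 mm (a typical whole-body PET matrix with
5 mm slices), rasterized with 4×4×4 sub-voxel occupancy sampling, blurred
with an isotropic Gaussian PSF of 7 mm FWHM (a 5 mm post-reconstruction
filter combined with scanner intrinsic resolution), and degraded with
seeded Gaussian noise of per-voxel sd `0.05·√(value·max)` (Poisson-like
variance scaling), clipped at zero. Lesions are centered on a voxel
center so the seed voxel coincides with the analytic center. Truth is
carried analytically: exact ellipsoid volume, a 50%-occupancy truth mask,
and an interior seed.

Packaged suites: *calibration* = six spheres of 16–50 mm diameter;
*evaluation* = ten ellipsoids from ~1 to ~94 ccm, three below 3 ccm and
two above 45 ccm so both size-subgroup cutoffs are exercisable; both at
4:1 lesion-to-background ratio with disjoint per-phantom seeds.

What the phantom does **not** emulate: sinogram-level physics (scatter,
randoms, reconstruction artifacts and their correlated noise), lesion
heterogeneity (lesions are uniform ellipsoids), irregular shapes,
necrotic cores, and physiological background structure. Passing the
phantom study therefore shows that the algorithm recovers volumes of
blurred, noisy, homogeneous lesions at known contrast — it does not by
itself establish clinical accuracy, where heterogeneous uptake and
higher, variable contrasts dominate.

Voxelization note: at 4×4×5 mm the 50%-occupancy truth mask volume
deviates from the analytic volume by a few voxels (up to ~16% for a
2 ccm lesion, ~1–3% above 20 ccm) and converges under spacing
refinement; segmentation accuracy is therefore scored against the
analytic volume, with the mask used for Dice.

## Problem sizes and runtime

The packaged study — 16 phantoms, three calibrations, ten evaluation
segmentations with two methods, and a 2000-replicate Forkman null
simulation — completes in roughly half a minute on one CPU; the full
test suite takes a similar time. These sizes were chosen to make the
subgroup structure (all / >3 ccm / >45 ccm) well-populated at desk scale.

## Known limitations

- Lesions below ~3 ccm (a few dozen voxels) are at the edge of what
  region-level texture can support: feature peaks scale with lesion size,
  so a threshold calibrated on 16–50 mm spheres may never be crossed for
  a ~1 ccm lesion, which then returns its closest-approach region with a
  warning. Texture-based stop criteria should not be the tool of choice
  in that regime.
- The calibrated stop threshold is tied to the calibration conditions
  (G, bounds mode, search volume, PSF, noise, contrast). Recalibrate for
  a different scanner model or phantom set.
- One lesion per seed; overlapping or confluent lesions are out of
  scope, as are DICOM-RT export and any GUI.
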