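# petgrow

Texture-feature region-growing tumor delineation for 3D PET, with a
40%-of-maximum threshold baseline, an agreement-statistics battery for
validation against pathology references, and a digital phantom generator
with known ground truth.

## The problem

Delineating the metabolically active tumor volume in FDG-PET is a core
step of radiotherapy planning and response assessment, but finite scanner
resolution (the partial-volume effect), image noise, and lesion
heterogeneity make simple intensity thresholds unreliable. `petgrow`
implements a seeded region-growing algorithm whose *stop criterion* is a
radiomics texture feature of the growing region rather than an intensity
rule, for users (medical physicists, imaging researchers) who want a
reproducible, scriptable implementation of that approach together with
the statistical machinery to validate it.

## The model

A user supplies one seed voxel per lesion. Starting from a 3×3×3 cube
around the seed, the region grows by intensity-ordered flooding (the
brightest 26-connected boundary voxel is absorbed first). After every
iteration (~10% region growth) one of three texture features is evaluated
on the region:

- **Kurtosis** — `KU = (1/N) Σᵢ ((xᵢ − X̄)/σ)⁴`, the standardized fourth
  moment of the region activities (population moments; 3 for a normal
  distribution);
- **Local Entropy** — `LE = −Σᵢⱼ M1ᵢⱼ log₂ M1ᵢⱼ`, the Shannon entropy of
  the normalized gray-level co-occurrence matrix `M1` (13 unique 3D
  directions, symmetric, G = 64 gray levels);
- **Long-Zone Emphasis** — `LZE = Σᵢⱼ M4ᵢⱼ j² / Σᵢⱼ M4ᵢⱼ`, the
  size-squared-weighted mean zone size of the gray-level size-zone matrix
  `M4` (26-connected zones).

Growth stops at the first iteration whose feature value crosses a
configured threshold, and the region of the *previous* iteration is the
segmentation. Stop thresholds are not universal constants: they are
derived by a Dice-maximizing grid search on phantoms with known truth
(`calibrate_stop_threshold`), and the shipped defaults were calibrated on
the packaged 6-sphere suite. A conventional baseline segments the
26-connected component above 40% of the local maximum uptake
(`threshold_segment`).

For validation, pathology specimens measured in three axes `a, b, c` are
modeled as ellipsoids (`V = (π/6)·a·b·c`, maximal diameter
`10·max(a,b,c)` mm), and paired gold/test measurements are scored with
Pearson r, relative Bland–Altman bias and limits of agreement, the
root-mean-square coefficient of variation for duplicate measurements, and
Forkman's F-test for equality of two COVs, with lesion-size subgroups at
3 and 45 ccm.

## Worked example

`python examples/segment_phantom_lesion.py` builds a blurred, noisy
ellipsoid lesion (semi-axes 17×14×13 mm, 4:1 lesion-to-background ratio,
7 mm PSF) and segments it from its center voxel:

```
analytic truth volume: 12.96 ccm
LE region growing:     11.20 ccm, max diameter 29.1 mm (18 iterations, stop: threshold_crossed)
40% of max threshold:  16.48 ccm, max diameter 34.5 mm
```

The Local-Entropy stop recovers the 12.96 ccm truth to within −14%
(return-previous-iteration makes it conservative), while the 40%
threshold overshoots (+27%) because at this 4:1 contrast 40% of the
maximum lies below the blurred lesion edge. The other examples
demonstrate the texture features (`texture_features_demo.py`), threshold
calibration (`calibrate_stop_thresholds.py`, which prints the shipped
defaults, e.g. LE threshold 9.29 rising with mean Dice 0.894), and the
agreement battery (`agreement_statistics.py`).

## Command line

```sh
petgrow phantom  --suite evaluation --outdir suite/          # phantoms + truth + manifest
petgrow segment  --input scan.nii --seed 64,64,24 --method le --out result.json
petgrow calibrate --suite suite/ --feature le --out cal.json
petgrow validate --pairs lesions.csv --cutoffs 3,45 --out agreement.json
```

Seeds are 0-based voxel indices in x,y,z order. Every output embeds its
configuration; identical command lines produce byte-identical outputs.

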