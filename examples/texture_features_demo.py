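"""Compute the three stop-criterion texture features for one region.

Builds a small blurred, noisy sphere phantom, takes a cubic region around
the lesion center, and prints Kurtosis (KU), Local Entropy (LE) and
Long-Zone Emphasis (LZE) for that region.
"""

import numpy as np

from petgrow import Lesion, PhantomSpec, make_phantom, region_features

spec = PhantomSpec(
    shape=(48, 48, 24), spacing=(4.0, 4.0, 5.0),
    lesions=[Lesion(center_mm=(98.0, 98.0, 62.5),
                    semiaxes_mm=(12.0, 11.0, 10.0), activity=4.0)],
    rng_seed=1,
)
phantom = make_phantom(spec)
seed = phantom.seeds[0]

region = np.zeros(phantom.volume.shape, dtype=bool)
region[seed[0] - 3:seed[0] + 4,
       seed[1] - 3:seed[1] + 4,
       seed[2] - 3:seed[2] + 4] = True

feats = region_features(phantom.volume, region, G=64)
print(f"region of {int(region.sum())} voxels around the lesion center")
print(f"  KU  = {feats.ku:.3f}   (4th standardized moment; 3 for a normal "
      "activity distribution)")
print(f"  LE  = {feats.le:.3f} bits  (entropy of the gray-level "
      "co-occurrence matrix; higher = more heterogeneous)")
print(f"  LZE = {feats.lze:.1f}  (size-squared-weighted mean zone size; "
      "large for big homogeneous zones)")
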