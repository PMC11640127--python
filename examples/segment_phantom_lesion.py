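"""Segment one phantom lesion with texture growing and the 40% baseline.

Builds a blurred, noisy ellipsoid lesion of known volume, segments it with
the calibrated Local-Entropy region-growing configuration and with the
conventional 40%-of-maximum threshold, and prints both results next to
the analytic truth.
"""

from petgrow import (GrowthConfig, Lesion, PhantomSpec, make_phantom,
                     region_grow_segment, threshold_segment)
from petgrow.defaults import CALIBRATED_STOP

spec = PhantomSpec(
    lesions=[Lesion(center_mm=(258.0, 258.0, 122.5),
                    semiaxes_mm=(17.0, 14.0, 13.0), activity=4.0)],
    rng_seed=21,
)
phantom = make_phantom(spec)
seed = phantom.seeds[0]
truth_ccm = phantom.truth_volumes_ccm[0]

thr, direction, _ = CALIBRATED_STOP["le"]
cfg = GrowthConfig(feature="le", stop_threshold=thr, direction=direction)
grown = region_grow_segment(phantom.volume, seed, cfg)
base = threshold_segment(phantom.volume, seed)

print(f"analytic truth volume: {truth_ccm:.2f} ccm")
print(f"LE region growing:     {grown.volume_ccm:.2f} ccm, "
      f"max diameter {grown.max_diameter_mm:.1f} mm "
      f"({grown.iterations} iterations, stop: {grown.stop_reason})")
print(f"40% of max threshold:  {base.volume_ccm:.2f} ccm, "
      f"max diameter {base.max_diameter_mm:.1f} mm")
print("The LE trajectory rises as the growing region starts absorbing the "
      "blurred lesion rim and background; growth stops when it crosses the "
      "calibrated threshold, and the previous iteration is returned.")
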