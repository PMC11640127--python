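"""Shipped default configuration.

Stop thresholds for the texture features are not universal constants —
they depend on gray-level count, discretization window and acquisition.
The values below were frozen from one run of
:func:`petgrow.segment.calibrate_stop_threshold` on the packaged 6-sphere
calibration suite (SBR 4:1, 7 mm FWHM PSF, 5% noise, packaged seeds) with
the default growth configuration; rerun ``petgrow calibrate`` to derive
thresholds for a different scanner model or phantom set.
"""

from __future__ import annotations

DEFAULT_G = 64
DEFAULT_SEARCH_HALFWIDTH_MM = 100.0
DEFAULT_FRACTION = 0.40

#: feature -> (stop_threshold, direction, mean Dice achieved in calibration)
CALIBRATED_STOP = {
    "ku": (1.3968033132689592, "falling", 0.7893430547465385),
    "le": (9.289573993614784, "rising", 0.894012173957119),
    "lze": (3.264716177462888, "falling", 0.6161313032649703),
}
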