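"""Quantify fluorescein leakage for one eye: the full imaging pipeline.

Align the 5-min frame onto the 1-min reference, remove the background with
a 50 px rolling ball, crop 384x384 at the fovea, auto-threshold and
binarize each frame, subtract the binary 1-min image from the 5-min one,
and report the mean gray value of the leakage map over the parafoveal
(120 px) and perifoveal (240 px) windows.
"""

from faleak import QuantifyConfig, quantify_eye
from faleak.synthetic import (
    generate_fa_pair,
    refractory_scenario,
    responsive_scenario,
)

for label, scenario in (("responsive-style eye", responsive_scenario),
                        ("refractory-style eye", refractory_scenario)):
    params = scenario(seed=1, inter_frame_shift=(3.0, 2.0))
    pair, _ = generate_fa_pair(params)
    result = quantify_eye(pair, config=QuantifyConfig(align=True))
    tf = result.transform
    print(f"{label}:")
    print(f"  estimated motion: rot {tf.rotation_deg:+.2f} deg, "
          f"shift ({tf.translation[0]:+.1f}, {tf.translation[1]:+.1f}) px "
          f"(true: +0.00 deg, (+3.0, +2.0) px)")
    print(f"  thresholds 1min/5min: {result.threshold_1min}/{result.threshold_5min}")
    print(f"  parafoveal MGV {result.parafoveal_mgv:.1f}   "
          f"perifoveal MGV {result.perifoveal_mgv:.1f}")

print("Higher mean gray value = a larger fraction of the macular window")
print("newly hyperfluorescent at 5 min, i.e. more severe leakage.")
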