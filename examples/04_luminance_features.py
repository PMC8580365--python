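"""Brightness -> luminance conversion and flashlight calibration.

Pixel brightness BV = 0.299R + 0.587G + 0.114B is rescaled (255 -> 5 by
default) and converted to luminance with the iPhone X camera constants
(K=12.4, s=25 ms, t=1/2000 s), so lumen = 2**BV / 0.0927.  Healthy lenses
sit near 95 lumen, diseased ones near 140.
"""

import dataclasses

import numpy as np

from lumicat import classify, luminance, phantom, preprocess

profile = luminance.get_profile("iPhoneX")
print(f"conversion constant c = {profile.denominator:.4f}  (lumen = 2**BV / c)")

for condition, target in [("healthy", 94.7), ("mature", 140.2)]:
    base = phantom.solve_base_brightness(94.7, 3100.0)
    spec = phantom.PhantomSpec(condition=condition, base_lens_brightness=base, seed=3)
    if condition != "healthy":
        spec = dataclasses.replace(spec, opacity=phantom.solve_opacity(spec, target))
    image, truth = phantom.generate_eye_image(spec)
    masked = preprocess.median_filter(preprocess.mask_image(image, truth.lens_mask))
    lmap = luminance.luminance_map(masked, profile)
    fv = classify.extract_features(lmap, masked)
    print(
        f"{condition:8s} mean luminance {fv.mean_lum:6.1f} lumen "
        f"(sd {fv.sd_lum:5.1f}) | mean R {fv.mean_r:5.1f}"
    )

# flashlight calibration makes maps from different phones comparable
lit = luminance.luminance_map(masked, profile)
lit = dataclasses.replace(lit, lumen=lit.lumen * profile.flashlight_lumens / 100.0)
cal = luminance.calibrate_flashlight(lit, profile)
print(
    f"flash-lit map rescaled by 100/{profile.flashlight_lumens:.0f}: "
    f"mean {cal.lumen[cal.mask].mean():.1f} lumen after calibration"
)
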