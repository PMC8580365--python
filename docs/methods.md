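# Methods

## The detection model

A cataract elevates the brightness of the crystalline lens in a flash-lit
anterior eye photograph. `lumicat` reduces every ROI pixel to its
brightness `BV = 0.299R + 0.587G + 0.114B` (the ITU-601 luma weighting) and
maps it to a photometric luminance with the acquiring camera's constants:

    luminance = K · 2^BV' / ((s/t) · 0.023),

with light-meter constant `K` (unitless), ISO-speed parameter `s`
(milliseconds, taken literally from the camera specification despite the
odd unit), exposure time `t` (seconds) and a rescaled brightness `BV'`.
For the iPhone X constants (K = 12.4, s = 25 ms, t = 1/2000 s) the
denominator is 0.092742; the commonly quoted rounded form is 2^BV/0.0929
(0.17% away, treated as rounding). The conversion is evaluated in the log2
domain, so even an unscaled 0–255 exponent cannot overflow.

**Brightness rescaling (`bv_scale`).** An 8-bit BV in the exponent would
produce astronomically large values, while observed lens luminances sit
near 100 lumen — implying an effective exponent of 3–4. Three modes are
exposed: `literal` (BV as is), `unit` (BV/255) and the default `scaled`
(β·BV/255 with β = 5), chosen so mid-bright lens pixels (BV ≈ 160–190) map
to the 95–140 lumen range of the reported class statistics. Every report
echoes the mode in effect.

**Exact chroma invariance.** Brightness is computed as
`(299R + 587G + 114B)/1000` with integer numerators, which is the weighted
sum evaluated exactly for 8-bit channels. Consequently any channel
perturbation `(a, b, c)` with `299a + 587b + 114c = 0` — for example
`(+19, −19, +48)` — changes hue but leaves the brightness raster, and with
it the entire luminance map, bit-identical. This is the mechanism behind
the feature's robustness to sensor chroma, and it is asserted exactly in
the tests rather than approximately.

**Flashlight calibration.** The three supported phone profiles carry
measured flashlight outputs (iPhone 6: 112 lm, iPhone X: 136 lm, iPhone 11
Pro: 154 lm). `calibrate_flashlight` rescales a luminance map by
`target/flashlight_lumens` (target 100 lm), the software counterpart of
physically tuning every flashlight to the same output before acquisition.
Because the phantom generator renders scenes as if flashlights were already
tuned, the default pipeline applies no rescaling; the operation guards
against double application. Only the iPhone X optics constants are
published, so the other profiles reuse them and differ in flashlight output
and sensor chroma.

## Classification

Features are computed over the masked lens pixels only: mean and SD of
luminance, plus per-channel means. The default feature pair is
(mean luminance, mean red); a luminance-only mode exists. The classifier
is a soft-margin SVM with Gaussian kernel on standardized features
(defaults C = 1, gamma = 1/(n_features · feature variance)); hyperparameters
are unspecified in the source method, so the standard defaults are used and
logged. Splits and cross-validation are stratified (70/30 and 10-fold) —
stratification prevents degenerate folds at n = 100. `k = n` falls back to
unstratified leave-one-out, since singleton folds cannot be stratified.

Metrics: sensitivity TP/(TP+FN), accuracy (TP+TN)/total, and two
specificity variants — the standard TN/(TN+FP) as the headline and the
TN/(TN+FN) form printed in the original report, always flagged as
non-standard. Zero-denominator ratios are reported as undefined, never 0.

Pixel-level disease maps use an equal-prior two-Gaussian rule: a pixel is
diseased when its luminance is strictly closer to the diseased class mean
in class-SD units; ties break toward healthy. The mean-RGB baseline
mirrors the rule with Euclidean distances to class mean colors.

The environment-impact statistic is the symmetric percentage difference
`|max − min| / mean(max, min) · 100` between the extreme levels of one
acquisition factor.

## The phantom generator

The generator replaces a physical eye model: gray-rendered sclera (level
205), iris annulus (level 60) and lens disc (≈ level 160), with Gaussian
texture (SD 2.5 levels). Cataract patterns are analytic weights w ∈ [0,1]
over the lens disc, painted as a brightness elevation
`opacity · (255 − base) · w`:

- nuclear: centered radial Gaussian falloff (scale 0.6 lens radii);
- cortical: 8 angular-Gaussian spokes entering from the rim (onset at
  0.3 radii), phase set by the seed;
- posterior subcapsular: sharp-edged central plaque (radius 0.55);
- mature: uniform full-lens opacity;
- capsular: rim annulus (inner edge 0.68).

Ground truth marks pixels with w > 0.5; it is pixel-exact, always inside
the lens disc, and empty exactly for healthy eyes.

**Luminance calibration.** The pattern shapes and absolute opacities of a
physical eye model are not published, so the generator is calibrated
instead to the reported class luminance distributions: per image a target
mean lens luminance is drawn (healthy N(94.7, 4.1), diseased
N(140.2, 19.4) lumen) and the base brightness (healthy) or the opacity
(diseased, by bisection on the analytic forward model) is solved so the
masked mean luminance hits the target. Targets outside the achievable
range of a pattern are clipped, and diseased targets are floored 8 lumen
above the healthy base, which slightly compresses the diseased class
toward ≈ 136 lumen mean in practice.

**Environment model.** `apply_environment` applies, in order: an ambient
intensity scale, a spatial rescale by `20 cm / distance`, a fixed affine
foreshortening per 45° camera angle (cos 45° along the tilt axis plus a
small offset), and per-channel chroma gains; the benchmark (3100 lumens,
20 cm, center angle, unit gains) is the identity. Ambient coupling is a
weak power law `(ambient/3100)^0.12`: a close-range flash plus
auto-exposure means the ambient level moves image brightness far less than
proportionally, and this exponent reproduces an ambient impact on mean
luminance of roughly one third between the 1600 and 6100 lumen extremes —
the dominant-factor regime observed in practice. A proportional coupling
would swing brightness 0.5–2×, which is incompatible with a healthy-class
luminance SD of 4 lumen. The dataset generator additionally
pre-compensates the known ambient factor in the painting stage
(auto-exposure emulation), so class statistics hold across the full
acquisition grid; the sweep generator disables that compensation to expose
the raw sensitivity.

Sensor chroma is modeled as brightness-preserving gain triples
(0.299·g_r + 0.587·g_g + 0.114·g_b = 1): fixed per phone profile, plus
per-level white-balance jitter (g_r, g_b ~ U(0.85, 1.15)) in the
angle/distance/light sweeps, representing shot-to-shot white balance.
These move mean-RGB features by several percent while leaving luminance
unchanged up to 8-bit rounding — the ordering the robustness tests assert.

Noise: a seeded fraction of salt-and-pepper pixels plus saturated glare
discs (radius 2–4 px) on the iris annulus, clear of the lens ROI.
Randomness uses three documented substreams per spec seed (texture →
salt/pepper → glare), so partial pipelines are bit-reproducible; identical
specs give bit-identical images.

**What the phantoms do not model:** anterior-chamber geometry and corneal
refraction, specular texture of real opacities, pupil constriction,
eyelashes/eyelid occlusion, JPEG artifacts, and realistic color (scenes
are gray up to chroma gains). Passing tests therefore demonstrate the
correctness and internal robustness of the measurement chain, not clinical
performance on human eyes.

## Segmentation

The watershed stage follows the classic marker-controlled recipe: Sobel
gradient magnitude (reflected borders), opening and closing by
morphological reconstruction (geodesic reconstruction under/over the
original, 8-connected), regional maxima of the smoothed image as
foreground markers, the Otsu-dark region as background markers, and a
4-connected priority-flood watershed on the gradient with ridge pixels
labeled 0. The structuring element is a disc of radius max(3, r/20),
scaling with the lens radius r so smoothing strength tracks the 10–50 cm
distance range. Elementary dilation/erosion are implemented directly over
offset sets (union/intersection of translates); plain opening/closing pad
by the SE extent so the compositions behave as on an infinite domain
(binary pad: background; grayscale pad: reflection). Segmentation serves
visualization and per-region statistics; classification features are
computed over the whole ROI.

Numerical conventions: coordinates are 0-based row-major; a circle mask
includes pixels whose center lies within the radius; masks travel with
images and background carries the sentinel 0; the median filter (default
3×3, configurable odd size) reflects at image edges; Otsu on a constant
raster returns a single class rather than an error; watershed ties on
plateaus resolve by insertion order, making results deterministic.

## Problem sizes and limitations

Default experiments use 128×128 phantoms with a 26 px lens radius, 100
images per dataset and 10 replicates per sweep level — sizes chosen so the
whole test suite and the acceptance script run in seconds while keeping
≥ 300 pixels in the smallest (50 cm) lens. Known limitations: the
luminance scale is only meaningful relative to the chosen `bv_scale` mode;
the published camera constants cover one phone model; the classifier
separates healthy from diseased only (no cataract typing or grading); and
the reported robustness ordering concerns the engineered chroma/geometry
factors of the phantom, not all real-world acquisition effects.
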