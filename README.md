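# lumicat

Luminance-based cataract screening from smartphone eye images.

Cataract — clouding of the crystalline lens — shows up in an anterior eye
photograph as elevated lens brightness. Color-based detectors are fragile:
their RGB features drift with the phone's sensor chroma, white balance,
viewing angle and distance. `lumicat` implements the luminance-based
alternative: every pixel is reduced to its brightness

```
BV = 0.299·R + 0.587·G + 0.114·B
```

and converted to a photometric luminance with the acquiring camera's
constants (light-meter constant *K*, ISO-speed parameter *s*, exposure time
*t*):

```
luminance [lumen] = K · 2^BV / ((s/t) · 0.023)       (iPhone X: 2^BV / 0.0927)
```

Because luminance depends on the channels only through the weighted sum,
any chroma change that preserves that sum leaves the feature untouched —
the formal core of the method's robustness across phones. Classification
of healthy vs. diseased lenses uses the masked mean luminance of the lens
region (plus the mean red channel) with a Gaussian-kernel SVM, a stratified
70/30 split and 10-fold cross-validation.

The package is a library with six building blocks:

| module | what it does |
| --- | --- |
| `lumicat.phantom` | synthetic eye images with ground-truth opacity masks for five cataract types (nuclear, cortical, posterior subcapsular, mature, capsular) under controlled ambient light, distance, angle and sensor chroma |
| `lumicat.preprocess` | circular lens ROI (manual or Hough-detected), rotation, median-filter denoising |
| `lumicat.segment` | Sobel gradient, morphological operators over explicit offset sets, opening/closing by reconstruction, Otsu background markers, marker-controlled watershed |
| `lumicat.luminance` | brightness sum, BV rescaling, camera-profile luminance conversion, flashlight calibration |
| `lumicat.classify` | feature extraction, SVM training/CV, pixel-level disease maps, metrics, percentage-difference impact statistic, t-tests, mean-RGB baseline |
| `lumicat.pipeline` / `lumicat.cli` | end-to-end orchestration and a thin `lumicat` command-line tool |

## Worked example

`examples/` holds one short script per capability. The classification
pipeline (`python examples/05_classification.py`) simulates 100 phantoms
(50 healthy / 50 diseased, diseased split evenly over the five types),
extracts luminance features, and trains/evaluates the SVM:

```
training class luminance: healthy 92.9 +/- 3.6 lumen | diseased 136.4 +/- 15.4 lumen
held-out (30 images): accuracy 100.0% | sensitivity 100.0% | specificity 100.0% (TN/(TN+FN) variant 100.0%)
10-fold CV on the 70 training images: 97.1 +/- 5.7%
Welch test healthy vs diseased mean luminance: t=16.1, p=1.88e-18
```

The class luminance statistics are the quantity the phantom generator is
calibrated to (healthy ≈ 95 lumen, diseased ≈ 140 lumen); the tiny p-value
reflects the ~3-SD separation of those distributions. Held-out accuracy
varies by a few points with the seed and averages in the mid-to-high 90s.

The robustness sweep (`python examples/06_environment_sweep.py`) varies one
acquisition factor at a time and reports the percentage difference of each
feature between the extreme factor levels:

```
factor      luminance   mean RGB
angle           0.96%      8.54%
distance        2.88%      6.77%
phone           0.23%      3.21%
light          34.82%     21.92%
```

Luminance features are an order of magnitude more stable than mean-RGB
under angle, distance and sensor changes; ambient light moves true scene
brightness and therefore affects both.

A dataset can also be produced and consumed from the shell:

```
lumicat simulate --n-healthy 50 --n-diseased 50 --seed 42 --out data/
lumicat train --manifest data/ --seed 42 --out report.json
lumicat sweep --factor distance
```

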