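"""Feature extraction, Gaussian-kernel SVM classification and evaluation.

The diagnostic feature set is the masked mean luminance of the lens plus the
mean red channel (a luminance-only mode exists).  Classification uses a
soft-margin SVM with RBF kernel on standardized features, a stratified 70/30
train/test split and stratified 10-fold cross-validation.  Evaluation
reports sensitivity TP/(TP+FN), accuracy (TP+TN)/total and two specificity
variants: the standard TN/(TN+FP) and the TN/(TN+FN) form printed in the
source method, flagged as such.  Pixel-level disease maps use an
equal-prior two-Gaussian rule on luminance; the mean-RGB baseline mirrors it
in color space for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureVector",
    "ConfusionCounts",
    "MetricsReport",
    "CvReport",
    "ClassStats",
    "SvmModel",
    "EmptyMaskError",
    "extract_features",
    "split_dataset",
    "train_svm",
    "kfold_cv",
    "classify_pixels",
    "rgb_classify_pixels",
    "metrics",
    "percentage_difference",
    "t_test",
    "rgb_baseline_features",
    "environment_sweep",
]


class EmptyMaskError(ValueError):
    """Feature extraction was asked to run on an empty ROI mask."""


@dataclass(frozen=True)
class FeatureVector:
    """Per-image features over the masked lens pixels."""

    mean_lum: float
    sd_lum: float
    mean_r: float
    mean_g: float
    mean_b: float

    @property
    def mean_rgb(self) -> float:
        return (self.mean_r + self.mean_g + self.mean_b) / 3.0


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts; positive = diseased."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Percent metrics; ``None`` marks an undefined (0/0) ratio.

    ``specificity_standard`` = TN/(TN+FP) is the headline number;
    ``specificity_paper`` = TN/(TN+FN) reproduces the printed variant and is
    reported alongside with this flag.
    """

    sensitivity: Optional[float]
    specificity_standard: Optional[float]
    specificity_paper: Optional[float]
    accuracy: Optional[float]

    def as_dict(self) -> dict:
        return {
            "sensitivity_pct": self.sensitivity,
            "specificity_standard_pct": self.specificity_standard,
            "specificity_paper_pct": self.specificity_paper,
            "accuracy_pct": self.accuracy,
            "specificity_paper_is_nonstandard": True,
        }


@dataclass(frozen=True)
class CvReport:
    """Per-fold accuracies with their mean and SD, in percent."""

    fold_accuracies: tuple
    mean: float
    sd: float

    @property
    def k(self) -> int:
        return len(self.fold_accuracies)


@dataclass(frozen=True)
class ClassStats:
    """Per-class luminance mean/SD used by the pixel-level rule."""

    healthy_mean: float
    healthy_sd: float
    diseased_mean: float
    diseased_sd: float


def extract_features(lmap, image) -> FeatureVector:
    """Masked means and SDs of luminance and channel values.

    ``lmap`` is a :class:`~lumicat.luminance.LuminanceMap`, ``image`` the
    matching :class:`~lumicat.preprocess.MaskedImage`.
    """
    mask = np.asarray(lmap.mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot extract features from an empty mask")
    lum = np.asarray(lmap.lumen, dtype=np.float64)[mask]
    raster = np.asarray(image.image, dtype=np.float64)
    return FeatureVector(
        mean_lum=float(lum.mean()),
        sd_lum=float(lum.std()),
        mean_r=float(raster[..., 0][mask].mean()),
        mean_g=float(raster[..., 1][mask].mean()),
        mean_b=float(raster[..., 2][mask].mean()),
    )


def split_dataset(
    manifest: pd.DataFrame,
    train_frac: float = 0.7,
    seed: int = 0,
    label_col: str = "label",
) -> np.ndarray:
    """Stratified train/test assignment ('train'/'test' per manifest row)."""
    labels = manifest[label_col].to_numpy()
    n = len(labels)
    if train_frac >= 1.0:
        warnings.warn("train_frac >= 1: all samples assigned to training")
        return np.full(n, "train", dtype=object)
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples to split")
    idx_train, idx_test = train_test_split(
        np.arange(n),
        train_size=train_frac,
        stratify=labels,
        random_state=int(seed) % (2**32),
        shuffle=True,
    )
    out = np.full(n, "test", dtype=object)
    out[idx_train] = "train"
    return out


@dataclass
class SvmModel:
    """Standardizing RBF-SVM wrapper with its training configuration."""

    scaler: StandardScaler
    svc: SVC
    feature_names: tuple
    classes: tuple

    def decision_function(self, X) -> np.ndarray:
        return self.svc.decision_function(self.scaler.transform(np.asarray(X)))

    def predict(self, X) -> np.ndarray:
        return self.svc.predict(self.scaler.transform(np.asarray(X)))

    @property
    def support_vectors(self) -> np.ndarray:
        """Support vectors mapped back to the original feature space."""
        return self.scaler.inverse_transform(self.svc.support_vectors_)


def train_svm(
    features,
    labels,
    gamma="scale",
    C: float = 1.0,
    seed: int = 0,
    feature_names: Sequence[str] = ("mean_lum", "mean_r"),
) -> SvmModel:
    """Fit a Gaussian-kernel SVM on standardized features.

    ``gamma='scale'`` is 1/(n_features * feature variance) after
    standardization.  Raises on single-class input.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training needs both classes present")
    scaler = StandardScaler().fit(X)
    svc = SVC(kernel="rbf", C=C, gamma=gamma, random_state=int(seed) % (2**32))
    svc.fit(scaler.transform(X), y)
    return SvmModel(
        scaler=scaler,
        svc=svc,
        feature_names=tuple(feature_names),
        classes=tuple(classes),
    )


def kfold_cv(
    features,
    labels,
    k: int = 10,
    seed: int = 0,
    gamma="scale",
    C: float = 1.0,
) -> CvReport:
    """Stratified k-fold cross-validated accuracy of the SVM.

    Each fold standardizes and fits on its own training part.  ``k == n``
    falls back to unstratified leave-one-out (stratification is impossible
    with singleton folds); otherwise every class must have at least k
    samples.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    accs = []
    if k == n:
        folds = ((np.delete(np.arange(n), i), np.array([i])) for i in range(n))
    else:
        counts = pd.Series(y).value_counts()
        if (counts < k).any():
            raise ValueError("every class needs at least k samples for k-fold CV")
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(seed) % (2**32)
        )
        folds = skf.split(X, y)
    for tr, te in folds:
        model = train_svm(X[tr], y[tr], gamma=gamma, C=C, seed=seed)
        accs.append(float(np.mean(model.predict(X[te]) == y[te])) * 100.0)
    accs = tuple(accs)
    return CvReport(
        fold_accuracies=accs,
        mean=float(np.mean(accs)),
        sd=float(np.std(accs)),
    )


def _z_distance(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    if sd > 0:
        return np.abs(values - mean) / sd
    return np.where(values == mean, 0.0, np.inf)


def classify_pixels(lmap, class_stats: ClassStats) -> np.ndarray:
    """Per-pixel disease map from an equal-prior two-Gaussian luminance rule.

    A pixel is flagged diseased when its luminance is strictly closer to the
    diseased class mean in class-SD units; ties break toward healthy
    (conservative).  Returns a boolean raster restricted to the map's mask.
    """
    if (
        class_stats.healthy_sd == 0
        and class_stats.diseased_sd == 0
        and class_stats.healthy_mean == class_stats.diseased_mean
    ):
        raise ValueError("degenerate class statistics")
    lum = np.asarray(lmap.lumen, dtype=np.float64)
    z_h = _z_distance(lum, class_stats.healthy_mean, class_stats.healthy_sd)
    z_d = _z_distance(lum, class_stats.diseased_mean, class_stats.diseased_sd)
    return (z_d < z_h) & np.asarray(lmap.mask, dtype=bool)


def rgb_classify_pixels(
    image,
    healthy_rgb: Sequence[float],
    diseased_rgb: Sequence[float],
    healthy_sd: float = 1.0,
    diseased_sd: float = 1.0,
) -> np.ndarray:
    """Color-space mirror of :func:`classify_pixels` for the mean-RGB baseline.

    Euclidean distance to each class mean RGB vector, scaled by a per-class
    SD; ties break toward healthy.
    """
    raster = np.asarray(image.image, dtype=np.float64)
    mask = np.asarray(image.mask, dtype=bool)
    d_h = np.linalg.norm(raster - np.asarray(healthy_rgb), axis=-1)
    d_d = np.linalg.norm(raster - np.asarray(diseased_rgb), axis=-1)
    z_h = d_h / healthy_sd if healthy_sd > 0 else np.where(d_h == 0, 0.0, np.inf)
    z_d = d_d / diseased_sd if diseased_sd > 0 else np.where(d_d == 0, 0.0, np.inf)
    return (z_d < z_h) & mask


def _ratio_pct(num: int, den: int) -> Optional[float]:
    if den == 0:
        return None
    return 100.0 * num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, both specificity variants and accuracy, in percent.

    Zero-denominator ratios are reported as ``None`` (undefined), never 0.
    """
    if counts.total == 0:
        raise ValueError("metrics need at least one evaluated sample")
    return MetricsReport(
        sensitivity=_ratio_pct(counts.tp, counts.tp + counts.fn),
        specificity_standard=_ratio_pct(counts.tn, counts.tn + counts.fp),
        specificity_paper=_ratio_pct(counts.tn, counts.tn + counts.fn),
        accuracy=_ratio_pct(counts.tp + counts.tn, counts.total),
    )


def percentage_difference(x_max: float, x_min: float) -> float:
    """|x_max - x_min| divided by their mean, times 100 (symmetric)."""
    mean = (x_max + x_min) / 2.0
    if mean == 0:
        raise ZeroDivisionError("percentage difference undefined for zero mean")
    return abs(x_max - x_min) / abs(mean) * 100.0


def t_test(a, b, paired: bool = False) -> tuple[float, float]:
    """Two-sided t test: paired (one-sample on differences) or Welch.

    Identical paired samples return (0, 1) rather than a 0/0 statistic.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test needs equal-length samples")
        if len(a) < 2:
            raise ValueError("paired test needs n >= 2")
        if np.all(a == b):
            return 0.0, 1.0
        res = stats.ttest_rel(a, b)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each sample needs n >= 2")
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def rgb_baseline_features(image) -> np.ndarray:
    """Masked per-channel means (R, G, B), the color-baseline feature set."""
    mask = np.asarray(image.mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot extract features from an empty mask")
    raster = np.asarray(image.image, dtype=np.float64)
    return np.array([raster[..., ch][mask].mean() for ch in range(3)])


def environment_sweep(
    features: pd.DataFrame,
    factor: str,
    feature_cols: Sequence[str] = ("mean_lum", "mean_rgb"),
) -> dict:
    """Impact of one environmental factor on each feature.

    ``features`` holds one row per image with the factor level and the
    feature columns.  Per level the mean and SD of each feature are
    tabulated; the impact is the percentage difference between the levels
    with the largest and smallest mean.  Returns ``{"levels": DataFrame,
    "impact_pct": {feature: float}}``; a single-level factor has impact 0.
    """
    if factor not in features.columns:
        raise KeyError(f"factor column {factor!r} absent from the feature table")
    for col in feature_cols:
        if col not in features.columns:
            raise KeyError(f"feature column {col!r} absent from the feature table")
    grouped = features.groupby(factor, sort=True)
    table = grouped[list(feature_cols)].agg(["mean", "std"])
    impacts = {}
    for col in feature_cols:
        level_means = grouped[col].mean()
        if len(level_means) < 2:
            impacts[col] = 0.0
        else:
            impacts[col] = percentage_difference(
                float(level_means.max()), float(level_means.min())
            )
    return {"levels": table, "impact_pct": impacts}
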