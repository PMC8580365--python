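"""Lens ROI extraction, rotation and median-filter denoising.

The lens (cornea) region of interest is a circular disc given as
(center_row, center_col, radius) in 0-based pixel coordinates; a pixel
belongs to the disc when its center lies at distance <= radius.  Pixels
outside the ROI carry the background sentinel 0 and the binary mask travels
with the image so downstream statistics can exclude background exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .luminance import brightness_map

__all__ = [
    "CircleRoi",
    "MaskedImage",
    "EmptyRoiError",
    "CircleDetectionError",
    "circle_mask",
    "crop_circle",
    "mask_image",
    "detect_lens_circle",
    "rotate_image",
    "median_filter",
]


class EmptyRoiError(ValueError):
    """The requested circular ROI contains no image pixel."""


class CircleDetectionError(RuntimeError):
    """Automatic lens-circle detection failed; supply an ROI manually."""


@dataclass(frozen=True)
class CircleRoi:
    """Circular lens region: center (row, col) and radius, in pixels."""

    center_row: float
    center_col: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("CircleRoi.radius must be positive")


@dataclass
class MaskedImage:
    """8-bit RGB raster plus the binary ROI mask (True inside the ROI)."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("MaskedImage.image must be H x W x 3")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask shape must match image")


def circle_mask(shape, roi: CircleRoi) -> np.ndarray:
    """Boolean disc mask for ``roi`` clipped to an image of ``shape``."""
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    d2 = (rows - roi.center_row) ** 2 + (cols - roi.center_col) ** 2
    return d2 <= roi.radius**2


def mask_image(image: np.ndarray, mask: np.ndarray) -> MaskedImage:
    """Apply an arbitrary boolean mask, zeroing everything outside it."""
    mask = np.asarray(mask, dtype=bool)
    out = np.where(mask[..., None], image, 0).astype(np.uint8)
    return MaskedImage(out, mask)


def crop_circle(image: np.ndarray, roi: CircleRoi) -> MaskedImage:
    """Extract the circular lens ROI; outside pixels are zeroed.

    The disc may be clipped by the image border; a disc entirely outside the
    image raises :class:`EmptyRoiError`.
    """
    image = np.asarray(image)
    mask = circle_mask(image.shape[:2], roi)
    if not mask.any():
        raise EmptyRoiError("circular ROI lies entirely outside the image")
    return mask_image(image, mask)


def detect_lens_circle(
    image: np.ndarray,
    radius_bounds: tuple[int, int] | None = None,
    sigma: float = 2.0,
    min_accumulator: float = 0.25,
) -> CircleRoi:
    """Circular-Hough fit of the lens circle, for use when no ROI is given.

    Edge pixels come from a Canny detector on the brightness raster; the
    Hough accumulator is scanned over a radius range and the candidate whose
    interior is brightest relative to its surrounding ring is returned (the
    lens is brighter than the iris annulus around it).  A manual ROI always
    overrides this.
    """
    image = np.asarray(image)
    gray = brightness_map(image)
    h, w = gray.shape
    if radius_bounds is None:
        radius_bounds = (max(4, min(h, w) // 12), min(h, w) // 2)
    edges = canny(gray / 255.0, sigma=sigma)
    if not edges.any():
        raise CircleDetectionError("no edges found; cannot fit a circle")
    radii = np.arange(radius_bounds[0], radius_bounds[1] + 1)
    accum = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(
        accum, radii, total_num_peaks=8, normalize=True
    )
    if len(accums) == 0 or accums[0] < min_accumulator:
        raise CircleDetectionError(
            "no circle found above the accumulator threshold"
        )
    best, best_score = None, -np.inf
    rows, cols = np.ogrid[:h, :w]
    for a, x, y, r in zip(accums, cx, cy, rad):
        if a < min_accumulator:
            continue
        d2 = (rows - y) ** 2 + (cols - x) ** 2
        inner = d2 <= (0.9 * r) ** 2
        ring = (d2 > r**2) & (d2 <= (1.4 * r) ** 2)
        if not inner.any() or not ring.any():
            continue
        score = gray[inner].mean() - gray[ring].mean()
        if score > best_score:
            best_score = score
            best = CircleRoi(float(y), float(x), float(r))
    if best is None:
        raise CircleDetectionError("no usable circle candidate")
    return best


def rotate_image(image: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate about the image center with nearest-neighbor resampling.

    The canvas is preserved; corners rotated in from outside are set to 0.
    Rotation is counter-clockwise for positive angles, about the geometric
    center ((H-1)/2, (W-1)/2).
    """
    image = np.asarray(image)
    if degrees % 360 == 0:
        return image.copy()
    h, w = image.shape[:2]
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    theta = np.deg2rad(degrees)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    out_r, out_c = np.indices((h, w), dtype=np.float64)
    dr, dc = out_r - cr, out_c - cc
    # inverse map: rotate output coordinates by -theta
    src_r = cos_t * dr + sin_t * dc + cr
    src_c = -sin_t * dr + cos_t * dc + cc
    ri = np.rint(src_r).astype(np.int64)
    ci = np.rint(src_c).astype(np.int64)
    valid = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
    out = np.zeros_like(image)
    out[valid] = image[ri[valid], ci[valid]]
    return out


def median_filter(masked: MaskedImage, kernel: int = 3) -> MaskedImage:
    """Per-channel median smoothing inside the ROI.

    Classic salt-and-pepper/glare remover.  ``kernel`` must be odd and >= 3;
    image edges are handled by reflection; the mask is unchanged and pixels
    outside it stay at the background sentinel.
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 3")
    img = np.asarray(masked.image)
    out = np.empty_like(img)
    for ch in range(3):
        out[..., ch] = ndi.median_filter(
            img[..., ch], size=kernel, mode="reflect"
        )
    out = np.where(masked.mask[..., None], out, 0).astype(np.uint8)
    return MaskedImage(out, masked.mask.copy())
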