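"""Marker-controlled watershed segmentation of the lens ROI.

Stage order (the pipeline default): Sobel gradient magnitude -> opening and
closing by morphological reconstruction -> regional-maxima foreground
markers plus Otsu-thresholded background markers -> priority-flood watershed
on the gradient, ridges labeled 0.

The elementary morphological operators are written over explicit offset
sets: a structuring element B is a set of (drow, dcol) displacements,
dilation is the union of translates A_b over b in B and erosion the
intersection of translates A_{-b}.  Grayscale variants use per-pixel
max/min semantics with the usual padding (-inf for dilation, +inf for
erosion).  Geodesic reconstruction and the watershed flood itself are
delegated to scikit-image.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

__all__ = [
    "se_offsets",
    "disc_se",
    "gradient_magnitude",
    "dilate",
    "erode",
    "opening",
    "closing",
    "open_by_reconstruction",
    "close_by_reconstruction",
    "threshold_background",
    "regional_maxima",
    "watershed_segment",
    "overlay_segmentation",
    "segment_roi",
]

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)


def se_offsets(se) -> list[tuple[int, int]]:
    """Normalize a structuring element to a list of (drow, dcol) offsets.

    Accepts an iterable of offsets or a boolean array whose origin is its
    center element.
    """
    arr = np.asarray(se)
    if arr.ndim == 2 and arr.dtype != object and arr.shape[1] != 2:
        cr, cc = (arr.shape[0] - 1) // 2, (arr.shape[1] - 1) // 2
        offs = [
            (r - cr, c - cc)
            for r in range(arr.shape[0])
            for c in range(arr.shape[1])
            if arr[r, c]
        ]
    elif arr.ndim == 2 and arr.shape[1] == 2 and np.issubdtype(arr.dtype, np.integer):
        offs = [tuple(map(int, row)) for row in arr]
    else:
        offs = [(int(dr), int(dc)) for dr, dc in se]
    if not offs:
        raise ValueError("structuring element must be non-empty")
    return offs


def disc_se(radius: int) -> list[tuple[int, int]]:
    """Offsets of a disc structuring element of the given pixel radius."""
    r = int(radius)
    return [
        (dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if dr * dr + dc * dc <= r * r
    ]


def gradient_magnitude(gray: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude sqrt(gx**2 + gy**2), reflected borders."""
    from scipy import ndimage as ndi

    f = np.asarray(gray, dtype=np.float64)
    gx = ndi.correlate(f, _SOBEL_X, mode="reflect")
    gy = ndi.correlate(f, _SOBEL_X.T, mode="reflect")
    return np.hypot(gx, gy)


def _shift(a: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """Translate raster ``a`` by (dr, dc), filling exposed cells."""
    out = np.full_like(a, fill)
    h, w = a.shape
    rs_src = slice(max(0, -dr), min(h, h - dr))
    cs_src = slice(max(0, -dc), min(w, w - dc))
    rs_dst = slice(max(0, dr), min(h, h + dr))
    cs_dst = slice(max(0, dc), min(w, w + dc))
    out[rs_dst, cs_dst] = a[rs_src, cs_src]
    return out


def dilate(a: np.ndarray, se) -> np.ndarray:
    """Dilation: union of translates A_b over b in B (max for grayscale)."""
    a = np.asarray(a)
    offs = se_offsets(se)
    if a.dtype == bool:
        out = np.zeros_like(a)
        for dr, dc in offs:
            out |= _shift(a, dr, dc, False)
        return out
    f = a.astype(np.float64)
    out = np.full_like(f, -np.inf)
    for dr, dc in offs:
        np.maximum(out, _shift(f, dr, dc, -np.inf), out=out)
    out[~np.isfinite(out)] = f.min()
    return out


def erode(a: np.ndarray, se) -> np.ndarray:
    """Erosion: intersection of translates A_{-b} (min for grayscale)."""
    a = np.asarray(a)
    offs = se_offsets(se)
    if a.dtype == bool:
        out = np.ones_like(a)
        for dr, dc in offs:
            out &= _shift(a, -dr, -dc, False)
        return out
    f = a.astype(np.float64)
    out = np.full_like(f, np.inf)
    for dr, dc in offs:
        np.minimum(out, _shift(f, -dr, -dc, np.inf), out=out)
    out[~np.isfinite(out)] = f.max()
    return out


def _padded(a: np.ndarray, offs):
    """Pad by the SE extent so compositions behave as on an infinite domain."""
    m = max(max(abs(dr), abs(dc)) for dr, dc in offs)
    m = max(m, 1)
    if a.dtype == bool:
        return np.pad(a, m, mode="constant", constant_values=False), m
    return np.pad(a, m, mode="reflect"), m


def opening(a: np.ndarray, se) -> np.ndarray:
    """Opening = dilation of the erosion; removes objects smaller than B."""
    a = np.asarray(a)
    offs = se_offsets(se)
    big, m = _padded(a, offs)
    return dilate(erode(big, offs), offs)[m:-m, m:-m]


def closing(a: np.ndarray, se) -> np.ndarray:
    """Closing = erosion of the dilation; fills holes smaller than B."""
    a = np.asarray(a)
    offs = se_offsets(se)
    big, m = _padded(a, offs)
    return erode(dilate(big, offs), offs)[m:-m, m:-m]


_CONN8 = np.ones((3, 3), dtype=bool)


def open_by_reconstruction(gray: np.ndarray, se) -> np.ndarray:
    """Erosion followed by geodesic reconstruction by dilation under the input.

    Levels peaks narrower than the structuring element while restoring the
    exact shape of surviving structures; output is sandwiched between the
    plain opening and the original, pointwise.
    """
    f = np.asarray(gray, dtype=np.float64)
    marker = erode(f, se)
    return reconstruction(marker, f, method="dilation", footprint=_CONN8)


def close_by_reconstruction(gray: np.ndarray, se) -> np.ndarray:
    """Dilation followed by geodesic reconstruction by erosion over the input."""
    f = np.asarray(gray, dtype=np.float64)
    marker = dilate(f, se)
    return reconstruction(marker, f, method="erosion", footprint=_CONN8)


def threshold_background(
    gray: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Otsu threshold on masked pixels; returns the dark background marker.

    A constant input yields a single class (an empty marker raster), not an
    error.
    """
    f = np.asarray(gray, dtype=np.float64)
    if mask is None:
        mask = np.ones(f.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    vals = f[mask]
    if vals.size == 0:
        raise ValueError("threshold_background needs a non-empty mask")
    if np.all(vals == vals.flat[0]):
        return np.zeros(f.shape, dtype=bool)
    th = threshold_otsu(vals)
    return (f < th) & mask


def regional_maxima(gray: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """8-connected regional maxima, optionally restricted to a mask."""
    out = local_maxima(np.asarray(gray, dtype=np.float64), connectivity=2)
    if mask is not None:
        out = out & np.asarray(mask, dtype=bool)
    return out


def watershed_segment(
    gradient: np.ndarray,
    fg_markers: np.ndarray,
    bg_markers: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Priority-flood watershed on a gradient raster seeded by markers.

    Foreground marker components (8-connected) become regions 2, 3, ...;
    background markers, if given, form region 1.  Ridge pixels and pixels
    outside the mask are labeled 0.  Flood regions are grown 4-connected;
    the output partitions the mask.
    """
    grad = np.asarray(gradient, dtype=np.float64)
    fg = np.asarray(fg_markers, dtype=bool)
    if not fg.any():
        raise ValueError("watershed needs at least one foreground marker")
    markers = np.zeros(grad.shape, dtype=np.int32)
    next_label = 1
    if bg_markers is not None:
        bg = np.asarray(bg_markers, dtype=bool)
        if (bg & fg).any():
            raise ValueError("foreground and background markers must be disjoint")
        markers[bg] = 1
        next_label = 2
    fg_cc = cc_label(fg, connectivity=2)
    markers[fg > 0] = fg_cc[fg > 0] + (next_label - 1)
    labels = watershed(
        grad, markers, mask=mask, connectivity=1, watershed_line=True
    )
    return labels.astype(np.int32)


def overlay_segmentation(
    image: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    color: tuple[int, int, int] = (255, 64, 64),
) -> np.ndarray:
    """Recolor watershed ridge pixels over the original image.

    Ridges are label-0 pixels inside ``mask``.  With no mask given, only
    label-0 pixels touching a labeled region are recolored, so an empty
    label raster returns the image untouched.
    """
    image = np.asarray(image)
    labels = np.asarray(labels)
    if labels.shape != image.shape[:2]:
        raise ValueError("labels shape must match image")
    out = image.copy()
    if mask is None:
        if labels.max() <= 0:
            return out
        near = dilate(labels > 0, disc_se(1))
        ridge = (labels == 0) & near
    else:
        ridge = (labels == 0) & np.asarray(mask, dtype=bool)
    out[ridge] = np.asarray(color, dtype=np.uint8)
    return out


def segment_roi(
    masked,
    se_radius: int | None = None,
    use_reconstruction: bool = True,
):
    """Full marker-controlled watershed of a preprocessed lens ROI.

    Returns ``(labels, overlay)``.  The structuring element is a disc whose
    radius scales with the lens size, max(3, r/20), so smoothing strength
    tracks the 10-50 cm acquisition distances.
    """
    from .luminance import brightness_map

    gray = brightness_map(masked.image)
    mask = masked.mask
    if se_radius is None:
        roi_r = np.sqrt(mask.sum() / np.pi)
        se_radius = max(3, int(round(roi_r / 20)))
    se = disc_se(se_radius)
    grad = gradient_magnitude(gray)
    if use_reconstruction:
        smooth = close_by_reconstruction(open_by_reconstruction(gray, se), se)
    else:
        smooth = closing(opening(gray, se), se)
    fg = regional_maxima(smooth, mask)
    bg = threshold_background(smooth, mask) & ~fg
    labels = watershed_segment(grad, fg, bg, mask=mask)
    overlay = overlay_segmentation(masked.image, labels, mask=mask)
    return labels, overlay
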