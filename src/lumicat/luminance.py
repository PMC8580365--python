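"""Brightness and luminance photometry for smartphone eye images.

Pixel brightness is the ITU-601-style weighted channel sum

    BV = 0.299*R + 0.587*G + 0.114*B,

and luminance follows the APEX-style camera conversion

    luminance [lumen] = K * 2**BV / ((s / t) * 0.023),

where K is the light-meter constant, s the ISO-speed parameter and t the
exposure time of the acquiring camera.  Because 2**BV with an 8-bit BV is
astronomically large while reported lens luminances sit near 100 lumen, the
raw 0-255 brightness is rescaled before exponentiation (``bv_scale``); the
default maps 255 -> 5.0 so mid-bright lens pixels land in the reported
luminance range.  All camera constants live in :class:`CameraProfile`.

Brightness is evaluated as ``(299*R + 587*G + 114*B) / 1000``.  For integer
channel values the numerator is exact in float64, so any channel perturbation
``(a, b, c)`` with ``299a + 587b + 114c = 0`` (for example ``(19, -19, 48)``)
leaves the brightness map bit-identical — the formal core of the method's
robustness to sensor chroma.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "BV_WEIGHTS",
    "CameraProfile",
    "BUILTIN_PROFILES",
    "get_profile",
    "LuminanceMap",
    "AlreadyCalibratedError",
    "brightness_value",
    "brightness_map",
    "bv_scale",
    "luminance_from_bv",
    "luminance_map",
    "calibrate_flashlight",
    "flash_bv_offset",
    "bv_for_luminance",
]

#: Channel weights of the brightness sum (R, G, B).
BV_WEIGHTS = (0.299, 0.587, 0.114)

BV_MODES = ("literal", "unit", "scaled")
DEFAULT_BV_MODE = "scaled"
DEFAULT_BETA = 5.0


@dataclass(frozen=True)
class CameraProfile:
    """Photometric constants of one phone model.

    Parameters
    ----------
    K : light-meter constant (unitless).
    s_ms : ISO-speed parameter in milliseconds (taken literally from the
        camera specification, despite the odd unit).
    t_s : exposure time in seconds.
    flashlight_lumens : measured LED flashlight output.
    """

    profile_id: str
    K: float = 12.4
    s_ms: float = 25.0
    t_s: float = 1.0 / 2000.0
    flashlight_lumens: float = 136.0

    def __post_init__(self) -> None:
        for name in ("K", "s_ms", "t_s", "flashlight_lumens"):
            if not getattr(self, name) > 0:
                raise ValueError(f"CameraProfile.{name} must be positive")

    @property
    def denominator(self) -> float:
        """Constant c such that luminance = 2**BV / c for this camera."""
        return (self.s_ms / 1000.0 / self.t_s) * 0.023 / self.K


#: Profiles of the three phone models used in the study.  Only the iPhone X
#: optics constants are published; the other models reuse them and differ in
#: measured flashlight output (112 / 136 / 154 lumens).
BUILTIN_PROFILES = {
    "iPhone6": CameraProfile("iPhone6", flashlight_lumens=112.0),
    "iPhoneX": CameraProfile("iPhoneX", flashlight_lumens=136.0),
    "iPhone11Pro": CameraProfile("iPhone11Pro", flashlight_lumens=154.0),
}


def get_profile(profile_id: str) -> CameraProfile:
    """Look up a built-in camera profile by name."""
    try:
        return BUILTIN_PROFILES[profile_id]
    except KeyError:
        raise KeyError(
            f"unknown camera profile {profile_id!r}; "
            f"built-ins: {sorted(BUILTIN_PROFILES)}"
        ) from None


@dataclass
class LuminanceMap:
    """Per-pixel luminance raster restricted to a region of interest.

    ``lumen`` and ``bv`` are float64 H x W rasters; values outside ``mask``
    are zero and carry no meaning.  ``bv`` stores the raw 0-255 brightness.
    """

    lumen: np.ndarray
    bv: np.ndarray
    mask: np.ndarray
    profile_id: str
    bv_mode: str = DEFAULT_BV_MODE
    beta: float = DEFAULT_BETA
    calibrated: bool = False
    calibration_target: Optional[float] = None

    def masked_lumen(self) -> np.ndarray:
        """1-D array of luminance values inside the mask."""
        return self.lumen[self.mask]


class AlreadyCalibratedError(RuntimeError):
    """Raised when flashlight calibration would be applied twice."""


def _validate_channels(*channels) -> None:
    for ch in channels:
        arr = np.asarray(ch)
        if np.any(arr < 0) or np.any(arr > 255):
            raise ValueError("channel values must lie in [0, 255]")


def brightness_value(r, g, b):
    """Brightness of a pixel from its 8-bit R, G, B channel values.

    Accepts scalars or arrays; returns float64.  Exact (correctly rounded)
    for integer channel values.
    """
    _validate_channels(r, g, b)
    r = np.asarray(r, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    out = (299.0 * r + 587.0 * g + 114.0 * b) / 1000.0
    if out.ndim == 0:
        return float(out)
    return out


def brightness_map(image: np.ndarray) -> np.ndarray:
    """Brightness raster of an H x W x 3 RGB image (float64 H x W)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return brightness_value(image[..., 0], image[..., 1], image[..., 2])


def bv_scale(bv_raw, mode: str = DEFAULT_BV_MODE, beta: float = DEFAULT_BETA):
    """Rescale raw 0-255 brightness to the exponent used by the luminance map.

    modes: ``literal`` -> bv_raw, ``unit`` -> bv_raw/255,
    ``scaled`` -> beta*bv_raw/255 (default, beta=5).
    """
    if mode not in BV_MODES:
        raise ValueError(f"unknown bv mode {mode!r}; choose from {BV_MODES}")
    bv_raw = np.asarray(bv_raw, dtype=np.float64)
    if mode == "literal":
        out = bv_raw
    elif mode == "unit":
        out = bv_raw / 255.0
    else:
        out = beta * bv_raw / 255.0
    if out.ndim == 0:
        return float(out)
    return out


def luminance_from_bv(bv, profile: CameraProfile):
    """Luminance in lumens from an (already rescaled) brightness value.

    Computed in the log2 domain, ``lumen = 2**(bv - log2 c)`` with
    ``c = (s/t)*0.023/K``, so the literal bv mode cannot overflow.
    Luminance doubles for every unit increase of bv.
    """
    bv = np.asarray(bv, dtype=np.float64)
    out = np.exp2(bv - np.log2(profile.denominator))
    if out.ndim == 0:
        return float(out)
    return out


def bv_for_luminance(
    lumen,
    profile: CameraProfile,
    mode: str = DEFAULT_BV_MODE,
    beta: float = DEFAULT_BETA,
):
    """Raw 0-255 brightness that maps to a given luminance (inverse map)."""
    lumen = np.asarray(lumen, dtype=np.float64)
    if np.any(lumen <= 0):
        raise ValueError("luminance must be positive")
    bv_scaled = np.log2(lumen) + np.log2(profile.denominator)
    if mode == "literal":
        out = bv_scaled
    elif mode == "unit":
        out = bv_scaled * 255.0
    elif mode == "scaled":
        out = bv_scaled * 255.0 / beta
    else:
        raise ValueError(f"unknown bv mode {mode!r}; choose from {BV_MODES}")
    if out.ndim == 0:
        return float(out)
    return out


def luminance_map(
    image,
    profile: CameraProfile,
    mode: str = DEFAULT_BV_MODE,
    beta: float = DEFAULT_BETA,
) -> LuminanceMap:
    """Per-pixel brightness -> luminance conversion inside the ROI mask.

    ``image`` is a :class:`~lumicat.preprocess.MaskedImage` (or any object
    with ``image`` and ``mask`` attributes).  Luminance depends on the
    channels only through the brightness sum, so any hue change preserving
    that sum leaves the map unchanged.
    """
    raster = np.asarray(image.image)
    mask = np.asarray(image.mask, dtype=bool)
    bv_raw = brightness_map(raster)
    lum = luminance_from_bv(bv_scale(bv_raw, mode, beta), profile)
    bv_out = np.where(mask, bv_raw, 0.0)
    lum_out = np.where(mask, lum, 0.0)
    return LuminanceMap(
        lumen=lum_out,
        bv=bv_out,
        mask=mask,
        profile_id=profile.profile_id,
        bv_mode=mode,
        beta=beta,
    )


def calibrate_flashlight(
    lmap: LuminanceMap, profile: CameraProfile, target: float = 100.0
) -> LuminanceMap:
    """Normalize a luminance map to a common flashlight output.

    Multiplies the luminance raster by ``target / profile.flashlight_lumens``
    so maps acquired under different flashlights become comparable (the
    software counterpart of physically tuning every flashlight to 100 lumen).
    Refuses to run twice on the same map.
    """
    if target <= 0:
        raise ValueError("calibration target must be positive")
    if lmap.calibrated:
        raise AlreadyCalibratedError(
            "luminance map is already flashlight-calibrated"
        )
    scale = target / profile.flashlight_lumens
    return dataclasses.replace(
        lmap,
        lumen=lmap.lumen * scale,
        calibrated=True,
        calibration_target=target,
    )


def flash_bv_offset(
    profile: CameraProfile,
    mode: str = DEFAULT_BV_MODE,
    beta: float = DEFAULT_BETA,
    reference_lumens: float = 100.0,
) -> float:
    """Raw-brightness offset equivalent to a flashlight brighter than reference.

    A scene lit by a flashlight of ``profile.flashlight_lumens`` instead of
    ``reference_lumens`` has its luminance multiplied by their ratio, i.e. its
    (rescaled) brightness shifted by ``log2(ratio)``.  Returned on the raw
    0-255 brightness scale for the given bv mode.
    """
    shift = float(np.log2(profile.flashlight_lumens / reference_lumens))
    if mode == "literal":
        return shift
    if mode == "unit":
        return shift * 255.0
    if mode == "scaled":
        return shift * 255.0 / beta
    raise ValueError(f"unknown bv mode {mode!r}; choose from {BV_MODES}")
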