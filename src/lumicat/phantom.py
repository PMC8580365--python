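"""Synthetic eye phantoms with ground-truth opacity masks.

Replaces the physical eye model of the original acquisition protocol: each
phantom is a gray-rendered eye (sclera background, dark iris annulus, bright
lens disc) with one of five cataract patterns painted inside the lens as a
brightness elevation, plus controlled environmental factors (ambient light,
camera distance, camera angle, per-phone chroma gains) and acquisition noise
(salt-and-pepper pixels, glare spots).

Cataract patterns, by where the opacity sits in a real lens:

- ``nuclear``              centered radial-falloff cloud (cloudy nucleus)
- ``cortical``             wedge spokes entering from the lens rim
- ``posterior_subcapsular``compact central plaque with a sharp edge
- ``mature``               whole lens uniformly opaque
- ``capsular``             annulus along the lens rim

Painting is luminance-calibrated: the dataset generator draws a target mean
lens luminance per image from the reported class distributions (healthy
94.7 +/- 4.1 lumen, diseased 140.2 +/- 19.4 lumen) and solves the base
brightness (healthy) or opacity (diseased) so that the post-environment
masked mean luminance hits the target.  The ambient factor is compensated in
the painting stage the way a camera's auto-exposure would; the raw ambient
sensitivity is exposed by the sweep generator, which disables compensation.

Randomness: one seed per spec, split into three documented substreams
(texture -> salt/pepper noise -> glare), so partial pipelines remain
bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .luminance import (
    BUILTIN_PROFILES,
    bv_for_luminance,
    bv_scale,
    get_profile,
    luminance_from_bv,
)

__all__ = [
    "CONDITIONS",
    "DISEASED_TYPES",
    "ANGLES",
    "REFERENCE_ENVIRONMENT",
    "AMBIENT_EXPONENT",
    "HEALTHY_LUMEN",
    "DISEASED_LUMEN",
    "PROFILE_CHROMA",
    "PhantomSpec",
    "GroundTruth",
    "InvalidSpecError",
    "brightness_preserving_gains",
    "pattern_weight",
    "generate_eye_image",
    "environment_affine",
    "apply_environment",
    "transform_mask",
    "transform_truth",
    "map_circle",
    "add_noise",
    "solve_base_brightness",
    "solve_opacity",
    "generate_dataset",
    "generate_sweep",
    "DEFAULT_FACTOR_GRID",
]

CONDITIONS = (
    "healthy",
    "nuclear",
    "cortical",
    "posterior_subcapsular",
    "mature",
    "capsular",
)
DISEASED_TYPES = CONDITIONS[1:]
ANGLES = ("center", "up45", "down45", "left45", "right45")

#: Benchmark acquisition conditions; environment transforms are the identity here.
REFERENCE_ENVIRONMENT = {
    "ambient_lumens": 3100.0,
    "distance_cm": 20.0,
    "angle": "center",
    "profile_id": "iPhoneX",
}

#: Exponent of the ambient -> intensity coupling, scale=(ambient/3100)**gamma.
#: Weak by design: with a close-range flash and auto-exposure the ambient
#: level moves image brightness far less than proportionally; 0.12 reproduces
#: an ambient impact on mean luminance of roughly a third (percentage
#: difference between the 1600 and 6100 lumen extremes).
AMBIENT_EXPONENT = 0.12

#: Class mean/SD of masked lens luminance (lumens) the generator calibrates to.
HEALTHY_LUMEN = (94.7, 4.1)
DISEASED_LUMEN = (140.2, 19.4)

_SCLERA = 205.0
_IRIS = 60.0
_CAL_PROFILE = BUILTIN_PROFILES["iPhoneX"]


class InvalidSpecError(ValueError):
    """A phantom spec violates its invariants."""


def brightness_preserving_gains(g_r: float, g_b: float) -> tuple[float, float, float]:
    """Gain triple with the green gain solved so 0.299g_r+0.587g_g+0.114g_b = 1.

    Such a triple changes hue but leaves the brightness of gray pixels
    unchanged (up to 8-bit rounding).
    """
    g_g = (1.0 - 0.299 * g_r - 0.114 * g_b) / 0.587
    return (float(g_r), float(g_g), float(g_b))


#: Fixed sensor chroma of the three phone models, brightness-preserving.
PROFILE_CHROMA = {
    "iPhoneX": (1.0, 1.0, 1.0),
    "iPhone6": brightness_preserving_gains(1.12, 0.86),
    "iPhone11Pro": brightness_preserving_gains(0.87, 1.13),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic eye image.

    Identical specs (including the seed) produce bit-identical images and
    masks.  ``opacity`` is forced to 0 for the healthy condition.
    """

    image_size: tuple[int, int] = (128, 128)
    iris_center: tuple[float, float] = (64.0, 64.0)
    iris_radius: float = 44.0
    lens_radius: float = 26.0
    condition: str = "healthy"
    opacity: float = 0.0
    base_lens_brightness: float = 160.0
    ambient_lumens: float = 3100.0
    distance_cm: float = 20.0
    angle: str = "center"
    profile_id: str = "iPhoneX"
    chroma_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    saltpepper_density: float = 0.0
    glare_spots: int = 0
    texture_sd: float = 2.5
    n_spokes: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise InvalidSpecError(f"unknown condition {self.condition!r}")
        if self.angle not in ANGLES:
            raise InvalidSpecError(f"unknown angle {self.angle!r}")
        if not (0.0 <= self.opacity <= 1.0):
            raise InvalidSpecError("opacity must lie in [0, 1]")
        if not (0 <= self.saltpepper_density < 1.0):
            raise InvalidSpecError("saltpepper_density must lie in [0, 1)")
        if self.glare_spots < 0:
            raise InvalidSpecError("glare_spots must be >= 0")
        rows, cols = self.image_size
        if not (self.lens_radius < self.iris_radius < min(rows, cols) / 2):
            raise InvalidSpecError(
                "need lens_radius < iris_radius < min(image_size)/2"
            )
        if not (10.0 <= self.distance_cm <= 50.0):
            raise InvalidSpecError("distance_cm must lie in [10, 50]")
        if not (0.0 <= self.base_lens_brightness <= 255.0):
            raise InvalidSpecError("base_lens_brightness must lie in [0, 255]")
        if self.condition == "healthy" and self.opacity != 0.0:
            object.__setattr__(self, "opacity", 0.0)

    def rng_streams(self):
        """The documented (texture, noise, glare) random substreams."""
        tex, noise, glare = np.random.SeedSequence(self.seed).spawn(3)
        return (
            np.random.default_rng(tex),
            np.random.default_rng(noise),
            np.random.default_rng(glare),
        )


@dataclass
class GroundTruth:
    """Truth channel the physical eye model provides implicitly.

    ``opacity_mask`` marks opacified lens pixels (pattern weight > 0.5) and
    is always a subset of ``lens_mask``; it is empty iff the condition is
    healthy.
    """

    opacity_mask: np.ndarray
    lens_mask: np.ndarray
    condition: str
    environment: dict

    def __post_init__(self) -> None:
        self.opacity_mask = np.asarray(self.opacity_mask, dtype=bool)
        self.lens_mask = np.asarray(self.lens_mask, dtype=bool)


def _polar(spec: PhantomSpec):
    rows, cols = np.indices(spec.image_size, dtype=np.float64)
    dr = rows - spec.iris_center[0]
    dc = cols - spec.iris_center[1]
    rho = np.hypot(dr, dc) / spec.lens_radius
    theta = np.arctan2(dr, dc)
    return rho, theta


def pattern_weight(spec: PhantomSpec) -> np.ndarray:
    """Analytic opacity pattern weight in [0, 1] over the image grid.

    Purely deterministic in the spec (no RNG): the seed only rotates the
    cortical spoke phase.  Zero outside the lens disc.
    """
    rho, theta = _polar(spec)
    lens = rho <= 1.0
    cond = spec.condition
    if cond == "healthy":
        w = np.zeros(spec.image_size)
    elif cond == "mature":
        w = np.ones(spec.image_size)
    elif cond == "nuclear":
        w = np.exp(-((rho / 0.6) ** 2))
    elif cond == "posterior_subcapsular":
        w = 1.0 / (1.0 + np.exp((rho - 0.55) / 0.02))
    elif cond == "capsular":
        w = 1.0 / (1.0 + np.exp((0.68 - rho) / 0.03))
    elif cond == "cortical":
        phase = (spec.seed % 360) * np.pi / 180.0
        step = 2.0 * np.pi / spec.n_spokes
        ang = np.mod(theta - phase + step / 2.0, step) - step / 2.0
        sigma = np.pi / 14.0
        radial = np.clip((rho - 0.3) / 0.25, 0.0, 1.0)
        w = np.exp(-((ang / sigma) ** 2)) * radial
    else:  # pragma: no cover - guarded by the spec validator
        raise InvalidSpecError(cond)
    return np.where(lens, w, 0.0)


def generate_eye_image(spec: PhantomSpec):
    """Render a phantom at benchmark geometry; returns (RGB image, truth).

    Sclera, iris annulus and lens disc are painted gray with a mild texture;
    the cataract pattern elevates lens brightness by
    ``opacity * (255 - base) * weight``.  The ambient factor is compensated
    here (auto-exposure emulation) so that :func:`apply_environment` restores
    the intended brightness at the image's own ambient level.
    """
    rho, _ = _polar(spec)
    rows, cols = np.indices(spec.image_size, dtype=np.float64)
    d_iris = np.hypot(rows - spec.iris_center[0], cols - spec.iris_center[1])
    lens = rho <= 1.0
    iris = (d_iris <= spec.iris_radius) & ~lens

    w = pattern_weight(spec)
    base = spec.base_lens_brightness
    gray = np.full(spec.image_size, _SCLERA)
    gray[iris] = _IRIS
    lens_gray = base + spec.opacity * (255.0 - base) * w
    gray[lens] = lens_gray[lens]

    ambient_scale = _ambient_scale(spec.ambient_lumens)
    gray[lens] = gray[lens] / ambient_scale  # auto-exposure pre-compensation

    tex_rng, _, _ = spec.rng_streams()
    gray = gray + tex_rng.normal(0.0, spec.texture_sd, size=spec.image_size)
    gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    image = np.repeat(gray[..., None], 3, axis=2)

    truth = GroundTruth(
        opacity_mask=(w > 0.5) & lens,
        lens_mask=lens,
        condition=spec.condition,
        environment={
            "ambient_lumens": spec.ambient_lumens,
            "distance_cm": spec.distance_cm,
            "angle": spec.angle,
            "profile_id": spec.profile_id,
        },
    )
    return image, truth


def _ambient_scale(ambient_lumens: float) -> float:
    return float(
        (ambient_lumens / REFERENCE_ENVIRONMENT["ambient_lumens"])
        ** AMBIENT_EXPONENT
    )


_ANGLE_WARPS = {
    "center": (np.eye(2), np.zeros(2)),
    "up45": (np.diag([np.cos(np.pi / 4), 1.0]), np.array([-4.0, 0.0])),
    "down45": (np.diag([np.cos(np.pi / 4), 1.0]), np.array([4.0, 0.0])),
    "left45": (np.diag([1.0, np.cos(np.pi / 4)]), np.array([0.0, -4.0])),
    "right45": (np.diag([1.0, np.cos(np.pi / 4)]), np.array([0.0, 4.0])),
}


def environment_affine(spec: PhantomSpec):
    """Forward affine (matrix, translation, center) of the geometric warp.

    Composition of the distance rescale (reference 20 cm) and the fixed
    per-angle foreshortening, both about the image center.
    """
    if spec.angle not in _ANGLE_WARPS:
        raise ValueError(f"unknown angle {spec.angle!r}")
    zoom = REFERENCE_ENVIRONMENT["distance_cm"] / spec.distance_cm
    a_mat, a_t = _ANGLE_WARPS[spec.angle]
    mat = a_mat @ (zoom * np.eye(2))
    center = (np.asarray(spec.image_size, dtype=np.float64) - 1.0) / 2.0
    return mat, a_t, center


def _warp(raster: np.ndarray, spec: PhantomSpec, order: int) -> np.ndarray:
    mat, t, center = environment_affine(spec)
    if np.allclose(mat, np.eye(2)) and np.allclose(t, 0.0):
        return raster.astype(np.float64, copy=True)
    inv = np.linalg.inv(mat)
    offset = center - inv @ (center + t)
    return ndi.affine_transform(
        raster.astype(np.float64), inv, offset=offset, order=order,
        mode="constant", cval=0.0,
    )


def apply_environment(image: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Apply ambient intensity scale, distance rescale, angle warp, chroma gains.

    In that order; output clipped to [0, 255] and returned as uint8.  At the
    benchmark environment with unit gains this is the identity.
    """
    image = np.asarray(image)
    mat, t, _ = environment_affine(spec)
    scale = _ambient_scale(spec.ambient_lumens)
    gains = spec.chroma_gains
    if (
        scale == 1.0
        and np.array_equal(mat, np.eye(2))
        and not t.any()
        and tuple(gains) == (1.0, 1.0, 1.0)
    ):
        return image.copy()
    out = np.empty(image.shape, dtype=np.float64)
    for ch in range(3):
        plane = image[..., ch].astype(np.float64) * scale
        out[..., ch] = _warp(plane, spec, order=1) * gains[ch]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def transform_mask(mask: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Carry a binary raster through the geometric environment warp."""
    return _warp(np.asarray(mask, dtype=np.float64), spec, order=0) > 0.5


def transform_truth(truth: GroundTruth, spec: PhantomSpec) -> GroundTruth:
    """Ground truth with masks mapped through the environment warp."""
    return GroundTruth(
        opacity_mask=transform_mask(truth.opacity_mask, spec),
        lens_mask=transform_mask(truth.lens_mask, spec),
        condition=truth.condition,
        environment=dict(truth.environment),
    )


def map_circle(spec: PhantomSpec):
    """Post-warp (row, col, radius) of the lens circle.

    Exact under distance rescaling; for angled shots the circle becomes an
    ellipse and the returned radius is the unforeshortened one (the warped
    lens mask is the authoritative ROI there).
    """
    mat, t, center = environment_affine(spec)
    c = np.asarray(spec.iris_center, dtype=np.float64)
    c_out = mat @ (c - center) + center + t
    zoom = REFERENCE_ENVIRONMENT["distance_cm"] / spec.distance_cm
    return float(c_out[0]), float(c_out[1]), float(spec.lens_radius * zoom)


def add_noise(image: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Seeded salt-and-pepper pixels plus saturated glare discs in the iris.

    A fraction ``saltpepper_density`` of pixels is replaced by 0 or 255 with
    equal probability; ``glare_spots`` small saturated discs are stamped
    inside the (post-warp) iris.  Uses the noise and glare substreams only,
    so the result is reproducible independently of the painting stage.
    """
    image = np.asarray(image)
    out = image.copy()
    _, noise_rng, glare_rng = spec.rng_streams()
    h, w = image.shape[:2]
    if spec.saltpepper_density > 0:
        hit = noise_rng.random((h, w)) < spec.saltpepper_density
        vals = noise_rng.integers(0, 2, size=(h, w)).astype(np.uint8) * 255
        out[hit] = vals[hit][:, None]
    if spec.glare_spots > 0:
        mat, t, center = environment_affine(spec)
        c = np.asarray(spec.iris_center, dtype=np.float64)
        c_out = mat @ (c - center) + center + t
        zoom = REFERENCE_ENVIRONMENT["distance_cm"] / spec.distance_cm
        iris_r = spec.iris_radius * zoom
        lens_r = spec.lens_radius * zoom
        rows, cols = np.indices((h, w), dtype=np.float64)
        for _ in range(spec.glare_spots):
            spot_r = int(glare_rng.integers(2, 5))
            # glare sits on the iris annulus, clear of the lens ROI
            lo = min(lens_r + spot_r + 1.0, iris_r)
            hi = max(iris_r - spot_r, lo)
            rad = lo + (hi - lo) * glare_rng.random()
            ang = glare_rng.random() * 2.0 * np.pi
            gr = c_out[0] + rad * np.sin(ang)
            gc = c_out[1] + rad * np.cos(ang)
            disc = (rows - gr) ** 2 + (cols - gc) ** 2 <= spot_r**2
            out[disc] = 255
    return out


# ---------------------------------------------------------------------------
# Luminance calibration of the painting stage
# ---------------------------------------------------------------------------

def _forward_mean_lumen(
    base: float, opacity: float, w_lens: np.ndarray, ambient_scale: float
) -> float:
    """Predicted post-environment masked mean luminance of the lens."""
    bv = base + opacity * (255.0 - base) * w_lens
    bv = np.clip(np.clip(bv / ambient_scale, 0.0, 255.0) * ambient_scale, 0.0, 255.0)
    return float(np.mean(luminance_from_bv(bv_scale(bv), _CAL_PROFILE)))


def solve_base_brightness(target_lumen: float, ambient_lumens: float) -> float:
    """Base lens brightness whose post-environment luminance hits the target."""
    bv = bv_for_luminance(target_lumen, _CAL_PROFILE)
    scale = _ambient_scale(ambient_lumens)
    # painting pre-compensates ambient; keep the pre-compensated value in gamut
    return float(np.clip(bv, 5.0 * scale, 250.0 * scale))


def solve_opacity(
    spec: PhantomSpec, target_lumen: float, floor_above_base: float = 8.0
) -> float:
    """Opacity for which the masked mean lens luminance matches the target.

    Monotone in opacity, solved by bisection on the analytic forward model
    (texture-free).  Targets outside the achievable range are clipped.
    """
    w = pattern_weight(spec)
    w_lens = w[_polar(spec)[0] <= 1.0]
    a = _ambient_scale(spec.ambient_lumens)
    base = spec.base_lens_brightness
    lo_val = _forward_mean_lumen(base, 0.0, w_lens, a)
    hi_val = _forward_mean_lumen(base, 1.0, w_lens, a)
    target = float(np.clip(target_lumen, lo_val + floor_above_base, hi_val))
    if hi_val <= lo_val + floor_above_base:
        return 1.0
    lo, hi = 0.0, 1.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _forward_mean_lumen(base, mid, w_lens, a) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Dataset and sweep generators
# ---------------------------------------------------------------------------

DEFAULT_FACTOR_GRID = {
    "ambient_lumens": [1600.0, 3100.0, 4600.0, 6100.0],
    "distance_cm": [10.0, 20.0, 30.0, 40.0, 50.0],
    "angle": list(ANGLES),
    "profile_id": list(BUILTIN_PROFILES),
}

MANIFEST_COLUMNS = [
    "path",
    "label",
    "condition",
    "ambient_lumens",
    "distance_cm",
    "angle",
    "profile_id",
    "seed",
    "roi_row",
    "roi_col",
    "roi_radius",
]


def _render(spec: PhantomSpec):
    image, truth = generate_eye_image(spec)
    image = apply_environment(image, spec)
    truth = transform_truth(truth, spec)
    image = add_noise(image, spec)
    return image, truth


def generate_dataset(
    n_healthy: int,
    n_diseased: int,
    seed: int,
    out_dir: Optional[str] = None,
    factor_grid: Optional[dict] = None,
    saltpepper_density: float = 0.01,
    glare_spots: int = 2,
):
    """Generate a labeled phantom dataset; returns (records, manifest).

    Diseased images are split evenly across the five cataract types;
    environment factors are drawn per image from the acquisition grid
    (distances 10-50 cm step 10, ambient 1600-6100 lumens step 1500, five
    camera angles, three phone profiles).  Mean lens luminance is calibrated
    per image to the healthy/diseased class distributions.

    ``records`` is a list of (image, GroundTruth); with ``out_dir`` given the
    images, masks and ``manifest.csv`` are also written to disk.
    """
    if n_healthy < 0 or n_diseased < 0 or n_healthy + n_diseased == 0:
        raise ValueError("need a positive number of images")
    grid = dict(DEFAULT_FACTOR_GRID)
    if factor_grid:
        grid.update(factor_grid)
    conditions = ["healthy"] * n_healthy + [
        DISEASED_TYPES[i % len(DISEASED_TYPES)] for i in range(n_diseased)
    ]
    children = np.random.SeedSequence(seed).spawn(len(conditions))
    records, rows = [], []
    for i, (cond, child) in enumerate(zip(conditions, children)):
        rng = np.random.default_rng(child)
        spec_seed = int(child.generate_state(2)[1] % (2**31))
        ambient = float(rng.choice(grid["ambient_lumens"]))
        distance = float(rng.choice(grid["distance_cm"]))
        angle = str(rng.choice(grid["angle"]))
        profile_id = str(rng.choice(grid["profile_id"]))
        gains = PROFILE_CHROMA[profile_id]
        base_target = float(rng.normal(*HEALTHY_LUMEN))
        base = solve_base_brightness(base_target, ambient)
        spec = PhantomSpec(
            condition=cond,
            base_lens_brightness=base,
            ambient_lumens=ambient,
            distance_cm=distance,
            angle=angle,
            profile_id=profile_id,
            chroma_gains=gains,
            saltpepper_density=saltpepper_density,
            glare_spots=glare_spots,
            seed=spec_seed,
        )
        if cond != "healthy":
            target = float(rng.normal(*DISEASED_LUMEN))
            spec = replace(spec, opacity=solve_opacity(spec, target))
        image, truth = _render(spec)
        records.append((image, truth))
        roi_row, roi_col, roi_radius = map_circle(spec)
        path = f"img_{i:04d}.png"
        rows.append(
            {
                "path": path,
                "label": "healthy" if cond == "healthy" else "diseased",
                "condition": cond,
                "ambient_lumens": ambient,
                "distance_cm": distance,
                "angle": angle,
                "profile_id": profile_id,
                "seed": spec_seed,
                "roi_row": roi_row,
                "roi_col": roi_col,
                "roi_radius": roi_radius,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_dir is not None:
        import imageio.v3 as iio

        os.makedirs(os.path.join(out_dir, "masks"), exist_ok=True)
        for (image, truth), row in zip(records, manifest.itertuples()):
            iio.imwrite(os.path.join(out_dir, row.path), image)
            stem = os.path.splitext(row.path)[0]
            iio.imwrite(
                os.path.join(out_dir, "masks", f"{stem}_lens.png"),
                truth.lens_mask.astype(np.uint8) * 255,
            )
            iio.imwrite(
                os.path.join(out_dir, "masks", f"{stem}_opacity.png"),
                truth.opacity_mask.astype(np.uint8) * 255,
            )
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return records, manifest


def generate_sweep(
    factor: str,
    seed: int,
    n_per_level: int = 10,
    levels: Optional[Sequence] = None,
    condition: str = "healthy",
    gain_jitter: float = 0.15,
):
    """One-factor-at-a-time environment sweep (paired scenes across levels).

    All other factors stay at the benchmark.  Each replicate scene is
    rendered once per factor level; every non-phone level additionally draws
    its own brightness-preserving white-balance gains (shot-to-shot chroma
    variation), while the phone sweep uses the fixed per-profile gains.
    Ambient pre-compensation is disabled so the sweep exposes the raw
    sensitivity of the features.

    Returns (records, manifest) with a ``level`` column.
    """
    factor_keys = {
        "light": "ambient_lumens",
        "distance": "distance_cm",
        "angle": "angle",
        "phone": "profile_id",
    }
    if factor not in factor_keys:
        raise ValueError(f"unknown sweep factor {factor!r}; choose from {sorted(factor_keys)}")
    key = factor_keys[factor]
    if levels is None:
        levels = DEFAULT_FACTOR_GRID[key]
    ss = np.random.SeedSequence([seed, 1729])
    level_rngs = {
        lv: np.random.default_rng(child)
        for lv, child in zip(levels, ss.spawn(len(levels)))
    }
    scene_children = np.random.SeedSequence([seed, 42]).spawn(n_per_level)
    level_gains = {}
    for lv in levels:
        if key == "profile_id":
            level_gains[lv] = PROFILE_CHROMA[lv]
        else:
            r = level_rngs[lv]
            level_gains[lv] = brightness_preserving_gains(
                r.uniform(1 - gain_jitter, 1 + gain_jitter),
                r.uniform(1 - gain_jitter, 1 + gain_jitter),
            )
    records, rows = [], []
    for rep, child in enumerate(scene_children):
        rng = np.random.default_rng(child)
        spec_seed = int(child.generate_state(2)[1] % (2**31))
        if condition == "healthy":
            target = float(rng.normal(*HEALTHY_LUMEN))
        else:
            target = float(rng.normal(*DISEASED_LUMEN))
        base = solve_base_brightness(
            target if condition == "healthy" else HEALTHY_LUMEN[0],
            REFERENCE_ENVIRONMENT["ambient_lumens"],
        )
        for lv in levels:
            env = dict(REFERENCE_ENVIRONMENT)
            env[key] = lv
            spec = PhantomSpec(
                condition=condition,
                base_lens_brightness=base,
                ambient_lumens=float(env["ambient_lumens"]),
                distance_cm=float(env["distance_cm"]),
                angle=str(env["angle"]),
                profile_id=str(env["profile_id"]),
                chroma_gains=level_gains[lv],
                seed=spec_seed,
            )
            if condition != "healthy":
                spec = replace(spec, opacity=solve_opacity(spec, target))
            # disable auto-exposure compensation: paint at reference ambient,
            # then apply the full environment of this level
            paint_spec = replace(
                spec, ambient_lumens=REFERENCE_ENVIRONMENT["ambient_lumens"]
            )
            image, truth = generate_eye_image(paint_spec)
            image = apply_environment(image, spec)
            truth = transform_truth(truth, spec)
            records.append((image, truth))
            roi_row, roi_col, roi_radius = map_circle(spec)
            rows.append(
                {
                    "replicate": rep,
                    "factor": factor,
                    "level": lv,
                    "condition": condition,
                    "ambient_lumens": spec.ambient_lumens,
                    "distance_cm": spec.distance_cm,
                    "angle": spec.angle,
                    "profile_id": spec.profile_id,
                    "seed": spec_seed,
                    "roi_row": roi_row,
                    "roi_col": roi_col,
                    "roi_radius": roi_radius,
                }
            )
    return records, pd.DataFrame(rows)
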