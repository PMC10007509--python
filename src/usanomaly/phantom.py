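"""Synthetic ultrasound phantom generation and image preprocessing.

Real breast-ultrasound datasets with pixel-level lesion labels are rarely
shareable, so this module provides a stand-in world: speckled tissue-like
backgrounds for "normal" frames, plus hypoechoic (darkened) elliptical
lesions with exact ground-truth masks for "abnormal" frames.  The phantom
is a first-order surrogate — low-frequency tissue texture times unit-mean
multiplicative Rayleigh speckle — not a physical ultrasound simulation.

All images are float arrays in [0, 1], single-channel ``(H, W)`` or
3-channel ``(C, H, W)``.  Masks are uint8 arrays of {0, 1} on the same
``(H, W)`` grid.

Also implemented here is the standard preprocessing chain applied to 8-bit
ultrasound frames before training: 0–255 -> [0, 1] normalization, Gaussian
denoising, and gamma correction (gamma 0.5 / 1.5 used as a training-set
augmentation that emphasises dark regions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "SplitDataset",
    "generate_background",
    "apply_speckle",
    "insert_lesion",
    "generate_dataset",
    "normalize_pixels",
    "gaussian_denoise",
    "gamma_correct",
    "AUGMENT_GAMMAS",
]

# Gamma values used for training-set augmentation (0.5 brightens /
# emphasises dark structure, 1.5 darkens).
AUGMENT_GAMMAS = (0.5, 1.5)

# Rayleigh scale giving a unit-mean factor: E[Rayleigh(s)] = s * sqrt(pi/2).
_RAYLEIGH_UNIT_MEAN_SCALE = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and contrast of one elliptical hypoechoic lesion.

    Attributes
    ----------
    center : (row, col) of the ellipse center, pixels.
    semi_axes : (a, b) semi-axis lengths, pixels.
    rotation : rotation of the ``a`` axis from the row axis, radians.
    intensity_drop : multiplicative darkening in (0, 1]; interior pixels
        become ``pixel * (1 - intensity_drop)``.
    edge_softness : Gaussian blur scale (pixels) of the lesion boundary;
        0 gives a hard edge.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0
    intensity_drop: float = 0.5
    edge_softness: float = 0.0


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of a full synthetic dataset draw."""

    height: int = 64
    width: int = 64
    channels: int = 1
    n_train: int = 853
    n_val: int = 94
    n_test: int = 200
    lesion_area_min_px: float = 50.0
    lesion_area_max_px: float = 400.0
    lesion_drop_min: float = 0.3
    lesion_drop_max: float = 0.7
    lesion_softness: float = 1.0
    speckle_scale: float = 0.3
    smoothness: float = 8.0
    seed: int = 0


@dataclass
class SplitDataset:
    """Normal-train / normal-validation / abnormal-test image collections.

    Only the test split carries (nonempty) lesion masks; the training loop
    never sees a lesioned image.
    """

    train_normal: list[np.ndarray]
    val_normal: list[np.ndarray]
    test_abnormal: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    config: PhantomConfig | None = field(default=None, repr=False)


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim not in (2, 3):
        raise ValueError(f"image must be 2-D or (C, H, W) 3-D, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return img


def generate_background(
    height: int, width: int, seed: int, smoothness: float = 8.0
) -> np.ndarray:
    """Smooth low-frequency tissue-texture field in [0.2, 0.8].

    White noise is low-pass filtered with a Gaussian of scale ``smoothness``
    and min–max rescaled into [0.2, 0.8], leaving headroom for speckle and
    lesion contrast on both sides.
    """
    if height < 8 or width < 8:
        raise ValueError(f"dimensions must be >= 8, got {height}x{width}")
    if smoothness <= 0:
        raise ValueError(f"smoothness must be positive, got {smoothness}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:  # degenerate flat field
        return np.full((height, width), 0.5)
    return 0.2 + 0.6 * (smooth - lo) / (hi - lo)


def apply_speckle(img: np.ndarray, seed: int, scale: float) -> np.ndarray:
    """Multiplicative unit-mean Rayleigh speckle, clipped to [0, 1].

    Each pixel is multiplied by ``1 + scale * (r - 1)`` with
    ``r ~ Rayleigh`` normalised to unit mean, so the pre-clipping
    expectation equals the input and ``scale`` interpolates between no
    noise (0) and full Rayleigh speckle (1).
    """
    img = _check_image(img)
    if scale <= 0:
        raise ValueError(f"speckle scale must be positive, got {scale}")
    rng = np.random.default_rng(seed)
    r = rng.rayleigh(scale=_RAYLEIGH_UNIT_MEAN_SCALE, size=img.shape)
    factor = 1.0 + scale * (r - 1.0)
    return np.clip(img * factor, 0.0, 1.0)


def _ellipse_field(
    shape: tuple[int, int], spec: LesionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Hard interior mask and (optionally softened) weight field of an ellipse."""
    h, w = shape
    a, b = spec.semi_axes
    cr, cc = spec.center
    rows, cols = np.mgrid[0:h, 0:w]
    dr = rows - cr
    dc = cols - cc
    cosr, sinr = math.cos(spec.rotation), math.sin(spec.rotation)
    u = dr * cosr + dc * sinr
    v = -dr * sinr + dc * cosr
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = inside.astype(np.uint8)
    if spec.edge_softness > 0:
        weight = ndimage.gaussian_filter(
            inside.astype(np.float64), sigma=spec.edge_softness, mode="constant"
        )
    else:
        weight = inside.astype(np.float64)
    return mask, weight


def _ellipse_extent(spec: LesionSpec) -> tuple[float, float]:
    """Half-extent of the rotated ellipse along the row and column axes."""
    a, b = spec.semi_axes
    cosr, sinr = math.cos(spec.rotation), math.sin(spec.rotation)
    ext_r = math.hypot(a * cosr, b * sinr)
    ext_c = math.hypot(a * sinr, b * cosr)
    return ext_r, ext_c


def insert_lesion(
    img: np.ndarray, spec: LesionSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Darken an elliptical region and return (image, ground-truth mask).

    Interior pixels are scaled by ``1 - intensity_drop`` (hypoechoic masses
    are darker than surrounding tissue; a multiplicative rule keeps the
    image in [0, 1]).  The mask always marks the *hard* ellipse interior,
    independent of ``edge_softness``.  ``seed`` is accepted for API
    symmetry with the other generators; the operation is deterministic.
    """
    img = _check_image(img)
    shape = img.shape[-2:]
    a, b = spec.semi_axes
    if a <= 0 or b <= 0:
        raise ValueError(f"semi-axes must be positive, got {spec.semi_axes}")
    if not 0.0 <= spec.intensity_drop <= 1.0:
        raise ValueError(f"intensity_drop must be in [0, 1], got {spec.intensity_drop}")
    ext_r, ext_c = _ellipse_extent(spec)
    cr, cc = spec.center
    if (
        cr - ext_r < 0
        or cr + ext_r > shape[0] - 1
        or cc - ext_c < 0
        or cc + ext_c > shape[1] - 1
    ):
        raise ValueError(
            f"lesion ellipse (center {spec.center}, extent ({ext_r:.1f}, {ext_c:.1f})) "
            f"exceeds image bounds {shape}"
        )
    mask, weight = _ellipse_field(shape, spec)
    attenuation = 1.0 - spec.intensity_drop * weight
    out = img * attenuation  # broadcasts over a leading channel axis
    return np.clip(out, 0.0, 1.0), mask


def _as_channels(img2d: np.ndarray, channels: int) -> np.ndarray:
    if channels == 1:
        return img2d
    return np.repeat(img2d[None, :, :], channels, axis=0)


def _sample_lesion(
    cfg: PhantomConfig, rng: np.random.Generator
) -> LesionSpec:
    """Draw one lesion with area uniform in the configured pixel range."""
    area = rng.uniform(cfg.lesion_area_min_px, cfg.lesion_area_max_px)
    aspect = rng.uniform(0.5, 1.0)  # b/a; mildly elongated masses
    a = math.sqrt(area / (math.pi * aspect))
    b = a * aspect
    rotation = rng.uniform(0.0, math.pi)
    drop = rng.uniform(cfg.lesion_drop_min, cfg.lesion_drop_max)
    spec = LesionSpec(
        center=(0.0, 0.0),
        semi_axes=(a, b),
        rotation=rotation,
        intensity_drop=drop,
        edge_softness=cfg.lesion_softness,
    )
    ext_r, ext_c = _ellipse_extent(spec)
    margin = 1.0
    lo_r, hi_r = ext_r + margin, cfg.height - 1 - ext_r - margin
    lo_c, hi_c = ext_c + margin, cfg.width - 1 - ext_c - margin
    center = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
    return LesionSpec(
        center=center,
        semi_axes=spec.semi_axes,
        rotation=rotation,
        intensity_drop=drop,
        edge_softness=cfg.lesion_softness,
    )


def _check_feasible(cfg: PhantomConfig) -> None:
    if cfg.n_train < 1 or cfg.n_val < 1 or cfg.n_test < 1:
        raise ValueError("all split counts must be >= 1")
    if not 0 < cfg.lesion_area_min_px <= cfg.lesion_area_max_px:
        raise ValueError("lesion area range must satisfy 0 < min <= max")
    if not 0 < cfg.lesion_drop_min <= cfg.lesion_drop_max <= 1:
        raise ValueError("lesion drop range must satisfy 0 < min <= max <= 1")
    # worst case: circle of max area with the widest extent
    max_radius = math.sqrt(cfg.lesion_area_max_px / (math.pi * 0.5))
    if 2 * (max_radius + 2.0) >= min(cfg.height, cfg.width):
        raise ValueError(
            f"lesion area up to {cfg.lesion_area_max_px} px does not fit a "
            f"{cfg.height}x{cfg.width} image"
        )


def generate_dataset(cfg: PhantomConfig) -> SplitDataset:
    """Generate disjoint normal-train / normal-val / abnormal-test splits.

    Every image draws its own background and speckle stream from a child
    seed of ``cfg.seed``, so the whole dataset is reproducible bit-for-bit
    and the splits are disjoint by construction.  Each abnormal image
    receives exactly one lesion.
    """
    _check_feasible(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    n_total = cfg.n_train + cfg.n_val + cfg.n_test
    child_seeds = ss.generate_state(2 * n_total + 1)
    lesion_rng = np.random.default_rng(child_seeds[-1])

    def make_normal(i: int) -> np.ndarray:
        bg = generate_background(cfg.height, cfg.width, int(child_seeds[2 * i]), cfg.smoothness)
        img = apply_speckle(bg, int(child_seeds[2 * i + 1]), cfg.speckle_scale)
        return _as_channels(img, cfg.channels)

    def make_abnormal(i: int) -> tuple[np.ndarray, np.ndarray]:
        bg = generate_background(cfg.height, cfg.width, int(child_seeds[2 * i]), cfg.smoothness)
        spec = _sample_lesion(cfg, lesion_rng)
        lesioned, mask = insert_lesion(bg, spec)
        img = apply_speckle(lesioned, int(child_seeds[2 * i + 1]), cfg.speckle_scale)
        return _as_channels(img, cfg.channels), mask

    train = [make_normal(i) for i in range(cfg.n_train)]
    val = [make_normal(cfg.n_train + i) for i in range(cfg.n_val)]
    test = [make_abnormal(cfg.n_train + cfg.n_val + i) for i in range(cfg.n_test)]
    for _, mask in test:
        assert mask.sum() > 0, "abnormal mask must be nonempty"
    return SplitDataset(train_normal=train, val_normal=val, test_abnormal=test,
                        seed=cfg.seed, config=cfg)


def normalize_pixels(raw: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities 0–255 to [0, 1] by dividing by 255."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0 or raw.min() < 0 or raw.max() > 255:
        raise ValueError("raw pixel values must lie in [0, 255]")
    return raw / 255.0


def gaussian_denoise(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian low-pass denoising with reflective boundary handling.

    Reflective padding avoids the dark frame a zero-padded filter would
    paint along the borders (which would otherwise inflate border anomaly
    scores downstream).
    """
    img = _check_image(img)
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return img.copy()
    if img.ndim == 3:
        out = np.stack([ndimage.gaussian_filter(c, sigma=sigma, mode="reflect") for c in img])
    else:
        out = ndimage.gaussian_filter(img, sigma=sigma, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def gamma_correct(img: np.ndarray, gamma: float) -> np.ndarray:
    """Pointwise power-law correction ``out = img ** gamma`` (gamma > 0)."""
    img = _check_image(img)
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return np.power(img, gamma)
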