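"""Pixel-level anomaly detection from a trained reconstruction model.

A trained model reconstructs an input; the per-pixel absolute difference
between input and reconstruction is the *anomaly map* (error image), and a
binary lesion prediction is obtained by thresholding it.  Two threshold
sources are supported: fixed values (the study compares 0.1, 0.2, 0.3)
and the validation-set procedure that takes the maximum ReLU-rectified
residual of each normal validation map against the validation average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ReconstructionModel

__all__ = [
    "Threshold",
    "FIXED_THRESHOLDS",
    "anomaly_map",
    "find_threshold_algorithm1",
    "binarize",
    "detect",
    "validation_anomaly_maps",
]

# fixed comparison grid used alongside the validation-derived threshold
FIXED_THRESHOLDS = (0.1, 0.2, 0.3)


@dataclass(frozen=True)
class Threshold:
    value: float
    source: str = "fixed"  # 'fixed' | 'algorithm1'

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"threshold must be >= 0, got {self.value}")


def anomaly_map(x: np.ndarray, xhat: np.ndarray) -> np.ndarray:
    """Per-pixel absolute difference |x - xhat| as an (H, W) map.

    Multi-channel inputs are reduced by the mean of per-channel absolute
    differences, which keeps the map in [0, 1] and coincides with the
    single-channel map when channels are replicated.
    """
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    diff = np.abs(x - xhat)
    if diff.ndim == 3:
        diff = diff.mean(axis=0)
    return diff


def find_threshold_algorithm1(
    val_maps: list[np.ndarray], baseline: str = "pixelwise"
) -> Threshold:
    """Validation-set threshold: max ReLU residual against the average map.

    Compute the average of the validation anomaly maps (per-pixel mean map
    by default; ``baseline='scalar'`` uses the grand scalar mean instead),
    rectify each map's residual against it with ReLU, and return the
    maximum entry over all maps and pixels.
    """
    if not val_maps:
        raise ValueError("need at least one validation anomaly map")
    maps = [np.asarray(m, dtype=np.float64) for m in val_maps]
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("validation maps must share one shape")
    stack = np.stack(maps)
    if baseline == "pixelwise":
        average = stack.mean(axis=0)
    elif baseline == "scalar":
        average = stack.mean()
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    max_relu = 0.0
    for v in stack:
        relu_th = np.maximum(v - average, 0.0)
        max_relu = max(max_relu, float(relu_th.max()))
    return Threshold(value=max_relu, source="algorithm1")


def binarize(amap: np.ndarray, th: Threshold | float) -> np.ndarray:
    """Strict thresholding: pixel = 1 iff map value > threshold."""
    value = th.value if isinstance(th, Threshold) else float(th)
    if value < 0:
        raise ValueError(f"threshold must be >= 0, got {value}")
    amap = np.asarray(amap, dtype=np.float64)
    return (amap > value).astype(np.uint8)


def detect(
    model: ReconstructionModel, img: np.ndarray, th: Threshold | float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reconstruct -> anomaly map -> binarize; deterministic at inference.

    Returns ``(reconstruction, anomaly_map, predicted_mask)``.  The VAE
    decodes the posterior mean, so repeated calls agree bit-for-bit.
    """
    xhat = model.reconstruct(img)
    amap = anomaly_map(np.asarray(img, dtype=np.float64), xhat)
    mask = binarize(amap, th)
    return xhat, amap, mask


def validation_anomaly_maps(
    model: ReconstructionModel, val_images: list[np.ndarray]
) -> list[np.ndarray]:
    """Anomaly maps of the normal validation split (Algorithm-1 input)."""
    return [anomaly_map(np.asarray(im, dtype=np.float64), model.reconstruct(im))
            for im in val_images]
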