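"""Illumination-correction functions: estimation, subtraction, residual check.

The per-channel correction function is the pixel-by-pixel fluorescence
baseline produced by illumination and background. It is estimated from many
fields of one plate (pixel-wise median across images, then a large-kernel
2-D median smoothing) and *subtracted* from each image — division-based
flat-fielding is deliberately not used. Corrected images are clamped at
zero so downstream intensity integrals stay non-negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi

from .errors import (
    ChannelMismatchError,
    OverConfluentError,
    ParameterError,
    ShapeMismatchError,
)

DEFAULT_SMOOTHING_SCALE = 50


@dataclass
class IlluminationProfile:
    """Smooth per-channel baseline raster, same shape as the field images."""

    channel_role: str
    raster: np.ndarray
    n_images_used: int
    smoothing_scale: int

    def __post_init__(self) -> None:
        raster = np.asarray(self.raster, dtype=float)
        if not np.all(np.isfinite(raster)) or np.any(raster < 0):
            raise ParameterError("illumination profile must be finite and non-negative")
        self.raster = raster

    def save(self, path: str | Path) -> None:
        """Persist as float TIFF plus a JSON sidecar with provenance."""
        path = Path(path)
        tifffile.imwrite(path, self.raster.astype(np.float32))
        sidecar = {
            "channel_role": self.channel_role,
            "n_images_used": self.n_images_used,
            "smoothing_scale": self.smoothing_scale,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "IlluminationProfile":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(raster=tifffile.imread(path).astype(float), **meta)


def estimate_illumination(
    images: Sequence[np.ndarray] | Iterable[np.ndarray],
    smoothing_scale: int = DEFAULT_SMOOTHING_SCALE,
    channel_role: str = "",
) -> IlluminationProfile:
    """Estimate the per-channel baseline from a collection of fields.

    Pixel-wise median across images (robust to the sparse cell foreground)
    followed by a 2-D median filter of width ``smoothing_scale`` pixels.
    """
    stack = [np.asarray(img, dtype=float) for img in images]
    if len(stack) == 0:
        raise ParameterError("estimate_illumination requires at least one image")
    shape = stack[0].shape
    for img in stack[1:]:
        if img.shape != shape:
            raise ShapeMismatchError(f"image shapes differ: {img.shape} vs {shape}")
    pixelwise = np.median(np.stack(stack), axis=0) if len(stack) > 1 else stack[0]
    if smoothing_scale > 1:
        raster = ndi.median_filter(pixelwise, size=smoothing_scale, mode="nearest")
    else:
        raster = pixelwise
    raster = np.clip(raster, 0.0, None)
    return IlluminationProfile(
        channel_role=channel_role,
        raster=raster,
        n_images_used=len(stack),
        smoothing_scale=smoothing_scale,
    )


def apply_correction(
    image: np.ndarray, profile: IlluminationProfile, channel_role: str | None = None
) -> np.ndarray:
    """Subtract the baseline; negative residuals clamp to 0. Returns float64."""
    if channel_role is not None and channel_role != profile.channel_role:
        raise ChannelMismatchError(
            f"image channel {channel_role!r} does not match profile "
            f"channel {profile.channel_role!r}"
        )
    image = np.asarray(image, dtype=float)  # widen before subtracting: no wraparound
    if image.shape != profile.raster.shape:
        raise ShapeMismatchError(
            f"image shape {image.shape} does not match profile shape {profile.raster.shape}"
        )
    return np.clip(image - profile.raster, 0.0, None)


def residual_background(
    corrected: np.ndarray, cell_mask: np.ndarray, min_free_fraction: float = 0.01
) -> float:
    """Mean corrected intensity over cell-free pixels (background accuracy check)."""
    corrected = np.asarray(corrected, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if corrected.shape != cell_mask.shape:
        raise ShapeMismatchError("corrected image and cell mask shapes differ")
    free = ~cell_mask
    if free.sum() < min_free_fraction * free.size:
        raise OverConfluentError(
            "fewer than {:.0%} of pixels are cell-free; field too confluent for "
            "background estimation".format(min_free_fraction)
        )
    return float(corrected[free].mean())


def background_robust_sd(corrected: np.ndarray, cell_mask: np.ndarray) -> float:
    """Robust spread (1.4826 x MAD) of cell-free corrected intensities."""
    corrected = np.asarray(corrected, dtype=float)
    free = ~np.asarray(cell_mask, dtype=bool)
    values = corrected[free]
    if values.size == 0:
        raise OverConfluentError("no cell-free pixels available")
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))
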