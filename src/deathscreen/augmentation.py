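"""Five-crop extraction and seeded stochastic augmentation.

Each field image is reduced to five square crops (four corners + center);
training crops are then randomly flipped, rotated by multiples of 90 degrees
and perturbed with additive Gaussian noise. All randomness flows through an
explicit numpy Generator so augmented batches are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

CROP_ORDER = ("top_left", "top_right", "bottom_left", "bottom_right", "center")


@dataclass(frozen=True)
class AugmentConfig:
    crop_size: int = 512
    flip_horizontal: bool = True
    flip_vertical: bool = True
    rot90: bool = True
    gaussian_noise: bool = True
    noise_sd: float = 0.01
    crop_fallback: bool = False  # fall back to the full image if too small

    def __post_init__(self) -> None:
        if self.crop_size < 1:
            raise ValueError("crop_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def five_crop(image: np.ndarray, crop_size: int, fallback: bool = False) -> list[np.ndarray]:
    """Extract the four corner crops and the center crop of a (C, H, W) image.

    Order: top-left, top-right, bottom-left, bottom-right, center. The
    center crop starts at row (H-s)//2 and column (W-s)//2; all intervals
    are half-open.
    """
    if image.ndim != 3:
        raise ValueError(f"expected (C, H, W) image, got shape {image.shape}")
    c, h, w = image.shape
    s = crop_size
    if h < s or w < s:
        if fallback:
            warnings.warn(
                f"image {h}x{w} smaller than crop {s}; returning five full-image copies",
                stacklevel=2,
            )
            return [image.copy() for _ in range(5)]
        raise ValueError(f"image {h}x{w} smaller than crop size {s}")
    r0, c0 = (h - s) // 2, (w - s) // 2
    return [
        image[:, :s, :s].copy(),
        image[:, :s, w - s:].copy(),
        image[:, h - s:, :s].copy(),
        image[:, h - s:, w - s:].copy(),
        image[:, r0:r0 + s, c0:c0 + s].copy(),
    ]


def flip_horizontal(crop: np.ndarray) -> np.ndarray:
    """Mirror left-right (last axis)."""
    return crop[:, :, ::-1].copy()


def flip_vertical(crop: np.ndarray) -> np.ndarray:
    """Mirror top-bottom (row axis)."""
    return crop[:, ::-1, :].copy()


def rot90(crop: np.ndarray, k: int = 1) -> np.ndarray:
    """Rotate a square crop by k * 90 degrees in the image plane."""
    if crop.shape[1] != crop.shape[2]:
        raise ValueError(f"rot90 requires a square crop, got {crop.shape}")
    return np.ascontiguousarray(np.rot90(crop, k=k, axes=(1, 2)))


def add_gaussian_noise(crop: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise, clipped back to [0, 1]."""
    noisy = crop + rng.normal(0.0, sd, size=crop.shape).astype(crop.dtype)
    return np.clip(noisy, 0.0, 1.0)


def augment(crop: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply the enabled transforms, each with probability 0.5, in fixed order.

    Order: horizontal flip, vertical flip, 90-degree rotation (k drawn from
    {1, 2, 3} when triggered), additive Gaussian noise. Equal generator
    state gives identical output.
    """
    out = crop
    if cfg.flip_horizontal and rng.random() < 0.5:
        out = flip_horizontal(out)
    if cfg.flip_vertical and rng.random() < 0.5:
        out = flip_vertical(out)
    if cfg.rot90 and rng.random() < 0.5:
        out = rot90(out, k=int(rng.integers(1, 4)))
    if cfg.gaussian_noise and cfg.noise_sd > 0 and rng.random() < 0.5:
        out = add_gaussian_noise(out, cfg.noise_sd, rng)
    return out
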