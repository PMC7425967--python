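"""Mammogram preprocessing: contrast enhancement, bilateral filtering,
normalization, and resizing to the network input size.

The chain is fixed in this order: CLAHE contrast enhancement, edge-preserving
bilateral filtering, per-image min-max rescaling to [0, 1], bilinear resize
to the square network input (512 by default). Parameters follow the common
OpenCV-style conventions (CLAHE clip 2.0 on 8x8 tiles; bilateral diameter 9
with sigma 75 on a 0-255 intensity scale) and are converted internally to
the scikit-image equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.restoration import denoise_bilateral
from skimage.transform import resize

__all__ = ["PreprocessConfig", "preprocess", "load_grayscale", "to_unit_range"]


@dataclass
class PreprocessConfig:
    clahe_clip: float = 2.0          # OpenCV-style clip limit (per 256-bin tile)
    clahe_tiles: tuple[int, int] = (8, 8)
    bilateral_diameter: int = 9
    bilateral_sigma_color: float = 75.0   # on a 0-255 intensity scale
    bilateral_sigma_space: float = 75.0   # pixels
    target_size: int = 512

    def __post_init__(self):
        if self.target_size < 8:
            raise ValueError("target size too small")
        if self.bilateral_diameter % 2 == 0:
            raise ValueError("bilateral diameter must be odd")


def load_grayscale(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF as an integer array."""
    from imageio.v3 import imread

    img = imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return np.asarray(img)


def to_unit_range(img: np.ndarray) -> np.ndarray:
    """Scale by declared bit depth (8/16-bit integers) or pass floats through."""
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        peak = 65535.0 if img.dtype.itemsize > 1 else 255.0
        return img.astype(np.float64) / peak
    return img.astype(np.float64)


def preprocess(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain; returns a (1, target, target) float map in [0, 1].

    A constant input (including all-zero) short-circuits to an all-zero
    output: the min-max normalization guard pins degenerate images to 0
    rather than dividing by a zero range.
    """
    cfg = cfg if cfg is not None else PreprocessConfig()
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    x = to_unit_range(img)
    t = cfg.target_size
    if x.max() == x.min():
        return np.zeros((1, t, t))
    x = np.clip(x, 0.0, 1.0)

    # contrast enhancement (CLAHE); skimage clip_limit is per-unit, OpenCV per-bin
    kernel = (max(1, x.shape[0] // cfg.clahe_tiles[0]),
              max(1, x.shape[1] // cfg.clahe_tiles[1]))
    x = equalize_adapthist(x, kernel_size=kernel,
                           clip_limit=min(1.0, cfg.clahe_clip / 256.0))

    # edge-preserving smoothing
    x = denoise_bilateral(
        x,
        win_size=cfg.bilateral_diameter,
        sigma_color=cfg.bilateral_sigma_color / 255.0,
        sigma_spatial=cfg.bilateral_sigma_space,
    )

    # per-image min-max normalization with degenerate guard
    lo, hi = x.min(), x.max()
    x = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)

    x = resize(x, (t, t), order=1, anti_aliasing=True, preserve_range=True)
    return np.clip(x, 0.0, 1.0)[None]
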