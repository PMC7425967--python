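"""Data enhancement for single-view and paired two-view mammograms.

Single-view expansion builds each augmented image from one or two geometric
operations (flip up-down, flip left-right, random crop, random down-scale in
[0.8, 1.0], translate by 10% in one of four directions) followed by one or
two photometric operations (gamma contrast adjustment, Gaussian noise,
rotation in [0, 180] degrees), producing exactly ``n_single`` (default 50)
outputs per input, reproducibly from the seed.

Two-view expansion preserves the CC/MLO correlation: a CC up-down flip
leaves the MLO untouched, while a left-right flip is applied to both views
jointly. The default closure emits four pairs: identity, the two rules, and
their composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import shift as nd_shift
from skimage.transform import resize, rotate

__all__ = ["AugmentConfig", "augment_single_view", "augment_two_view",
           "GEOMETRIC_OPS", "PHOTOMETRIC_OPS"]


@dataclass
class AugmentConfig:
    n_single: int = 50
    scale_range: tuple[float, float] = (0.8, 1.0)
    translate_frac: float = 0.10
    rotation_range: tuple[float, float] = (0.0, 180.0)
    noise_sigma: float = 0.01
    contrast_gamma: tuple[float, float] = (0.8, 1.2)
    crop_frac: tuple[float, float] = (0.85, 1.0)
    include_flip_composition: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_single < 1:
            raise ValueError("n_single must be >= 1")
        lo, hi = self.scale_range
        if not (0.8 - 1e-12 <= lo <= hi <= 1.0 + 1e-12):
            raise ValueError("scale_range must lie within [0.8, 1.0]")


# ------------------------------------------------------------- primitive ops
def _flip_ud(img, rng, cfg):
    return np.flipud(img).copy(), {}


def _flip_lr(img, rng, cfg):
    return np.fliplr(img).copy(), {}


def _random_crop(img, rng, cfg):
    h, w = img.shape
    fh = rng.uniform(*cfg.crop_frac)
    fw = rng.uniform(*cfg.crop_frac)
    ch, cw = max(1, int(round(fh * h))), max(1, int(round(fw * w)))
    top = rng.integers(0, h - ch + 1)
    left = rng.integers(0, w - cw + 1)
    crop = img[top:top + ch, left:left + cw]
    out = resize(crop, (h, w), order=1, anti_aliasing=False, preserve_range=True)
    return out, {"frac": (fh, fw)}


def _random_scale(img, rng, cfg):
    h, w = img.shape
    s = float(rng.uniform(*cfg.scale_range))
    nh, nw = max(1, int(round(s * h))), max(1, int(round(s * w)))
    small = resize(img, (nh, nw), order=1, anti_aliasing=False, preserve_range=True)
    out = np.zeros_like(img)
    top, left = (h - nh) // 2, (w - nw) // 2
    out[top:top + nh, left:left + nw] = small
    return out, {"scale": s}


def _translate(img, rng, cfg):
    h, w = img.shape
    direction = rng.integers(0, 4)  # up, down, left, right
    dy = {0: -1, 1: 1}.get(int(direction), 0) * cfg.translate_frac * h
    dx = {2: -1, 3: 1}.get(int(direction), 0) * cfg.translate_frac * w
    out = nd_shift(img, (dy, dx), order=1, cval=0.0)
    return out, {"shift": (dy, dx)}


def _contrast(img, rng, cfg):
    gamma = float(rng.uniform(*cfg.contrast_gamma))
    return np.clip(img, 0.0, 1.0) ** gamma, {"gamma": gamma}


def _noise(img, rng, cfg):
    out = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return out, {"sigma": cfg.noise_sigma}


def _rotate(img, rng, cfg):
    angle = float(rng.uniform(*cfg.rotation_range))
    return rotate(img, angle, order=1, preserve_range=True), {"angle": angle}


GEOMETRIC_OPS = {
    "flip_ud": _flip_ud,
    "flip_lr": _flip_lr,
    "crop": _random_crop,
    "scale": _random_scale,
    "translate": _translate,
}
PHOTOMETRIC_OPS = {
    "contrast": _contrast,
    "noise": _noise,
    "rotate": _rotate,
}


# ---------------------------------------------------------------- expansion
def augment_single_view(img: np.ndarray, cfg: AugmentConfig | None = None,
                        return_ops: bool = False):
    """Expand one preprocessed [0, 1] image into ``cfg.n_single`` variants.

    Each output applies 1-2 sampled geometric ops then 1-2 photometric ops;
    intensities are clipped back to [0, 1]. With ``return_ops`` the list of
    (image, op-name list) pairs is returned instead (for manifests).
    """
    cfg = cfg if cfg is not None else AugmentConfig()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    rng = np.random.default_rng(cfg.seed)
    geo_names = list(GEOMETRIC_OPS)
    photo_names = list(PHOTOMETRIC_OPS)
    results = []
    for _ in range(cfg.n_single):
        chosen_geo = list(rng.choice(geo_names, size=rng.integers(1, 3), replace=False))
        chosen_photo = list(rng.choice(photo_names, size=rng.integers(1, 3), replace=False))
        out = img
        applied = []
        for name in chosen_geo:
            out, _info = GEOMETRIC_OPS[name](out, rng, cfg)
            applied.append(name)
        for name in chosen_photo:
            out, _info = PHOTOMETRIC_OPS[name](out, rng, cfg)
            applied.append(name)
        out = np.clip(out, 0.0, 1.0)
        results.append((out, applied) if return_ops else out)
    return results


def augment_two_view(cc: np.ndarray, mlo: np.ndarray,
                     cfg: AugmentConfig | None = None
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Correlation-preserving flip expansion of a CC/MLO pair.

    Emits the identity pair, the CC up-down flip (MLO unchanged), the joint
    left-right flip, and (by default) the composition of the two rules.
    """
    cfg = cfg if cfg is not None else AugmentConfig()
    cc = np.asarray(cc, dtype=np.float64)
    mlo = np.asarray(mlo, dtype=np.float64)
    pairs = [
        (cc.copy(), mlo.copy()),
        (np.flipud(cc).copy(), mlo.copy()),                    # rule 1
        (np.fliplr(cc).copy(), np.fliplr(mlo).copy()),         # rule 2
    ]
    if cfg.include_flip_composition:
        pairs.append((np.fliplr(np.flipud(cc)).copy(), np.fliplr(mlo).copy()))
    return pairs
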