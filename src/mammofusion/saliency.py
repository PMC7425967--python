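"""Grad-CAM heat maps over each view, with the softmax score P.

The class-gradient-weighted activation map is computed at a chosen dense
block of the selected branch (the last block by default): channel weights
are the spatial means of the class logit's gradient, the weighted activation
sum is ReLU-rectified, upsampled to the view size, and min-max normalized
to [0, 1] (an all-constant raw map normalizes to all-zero). The overlay
blends a jet-style colormap over the grayscale view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .cases import CasePair
from .fusion import TwoViewFusionNet
from .nn import softmax

__all__ = ["HeatmapOverlay", "normalize_heatmap", "heatmap_for_view"]


@dataclass
class HeatmapOverlay:
    heat: np.ndarray      # (H, W) in [0, 1]
    overlay: np.ndarray   # (H, W, 3) RGB in [0, 1]
    score: float          # softmax score P of the target class


def normalize_heatmap(raw: np.ndarray) -> np.ndarray:
    """Min-max to [0, 1]; a constant map collapses to all-zero. Idempotent."""
    raw = np.asarray(raw, dtype=np.float64)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def heatmap_for_view(net: TwoViewFusionNet, case: CasePair, view: str = "cc",
                     target_class: int = 1, block_index: int = -1,
                     colormap: str = "jet", alpha: float = 0.4) -> HeatmapOverlay:
    """Grad-CAM for one view of a case.

    Works for any parameterisation (an untrained model yields a valid but
    meaningless map). ``block_index`` selects which dense block's output is
    visualized; -1 is the last.
    """
    if view not in ("cc", "mlo"):
        raise ValueError("view must be 'cc' or 'mlo'")
    net.eval()
    net.zero_grad()
    cc_t = TwoViewFusionNet._view_tensor(case.cc)
    mlo_t = TwoViewFusionNet._view_tensor(case.mlo)
    logits = net.forward(cc_t, mlo_t)
    probs = softmax(logits.data)[0]
    logits[0, target_class].backward()

    branch = net.branch_cc if view == "cc" else net.branch_mlo
    activation = branch.block_outputs[block_index]
    if activation.grad is None:
        raise RuntimeError("no gradient reached the selected block")
    weights = activation.grad[0].mean(axis=(1, 2))           # (C,)
    cam = np.maximum(np.tensordot(weights, activation.data[0], axes=(0, 0)), 0.0)
    net.zero_grad()

    source = case.cc if view == "cc" else case.mlo
    heat = resize(cam, source.shape, order=1, preserve_range=True)
    heat = normalize_heatmap(heat)

    cmap = colormaps[colormap]
    colored = cmap(heat)[..., :3]
    gray = np.repeat(np.clip(source, 0, 1)[..., None], 3, axis=2)
    overlay = np.clip((1.0 - alpha) * gray + alpha * colored, 0.0, 1.0)
    return HeatmapOverlay(heat=heat, overlay=overlay, score=float(probs[target_class]))
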