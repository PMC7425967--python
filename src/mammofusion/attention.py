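"""Parallel channel + spatial attention with residual aggregation (CSAM).

The module computes two attention maps from an input feature map
``F`` of shape (C, H, W):

* channel attention ``M_C = sigmoid(MLP(avg_pool(F)) + MLP(max_pool(F)))``,
  a length-C vector from spatially pooled descriptors passed through a
  shared one-hidden-layer MLP with reduction ratio ``r``;
* spatial attention ``M_S = sigmoid(f([avg; max]))``, an H x W map from the
  channel-pooled descriptors stacked into two channels and passed through a
  1x1 convolution (2 -> 1 channels) followed by factorised 7x1 and 1x7
  convolutions with "same" padding.

Both branches carry a residual connection and are aggregated by summation:

    F' = (F + F * M_C) + (F + F * M_S)

so with all parameters at zero (both maps uniformly 0.5) the module is
exactly ``3 * F``.

Two equivalent routes are provided: straight-line NumPy functions operating
on (C, H, W) arrays with an explicit :class:`CSAMParams` container (the
reference surface used by the tests), and the trainable :class:`CSAM`
module over batched tensors used inside the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

from .nn import Conv2d, Module, Parameter, Tensor, concat, kaiming_normal

__all__ = [
    "PooledDescriptors",
    "CSAMParams",
    "pool_descriptors",
    "channel_attention",
    "spatial_attention",
    "csam_forward",
    "CSAM",
]


# --------------------------------------------------------------------- types
@dataclass
class PooledDescriptors:
    """Per-channel and per-position mean/max summaries of a feature map."""

    channel_avg: np.ndarray  # (C,)
    channel_max: np.ndarray  # (C,)
    spatial_avg: np.ndarray  # (H, W)
    spatial_max: np.ndarray  # (H, W)


@dataclass
class CSAMParams:
    """Learnable weights of the channel MLP and factorised spatial convs.

    ``W0`` maps C -> C/r, ``W1`` maps C/r -> C (shared between the avg and
    max descriptors); the spatial branch is a 1x1 conv reducing 2 channels
    to 1, then single-channel 7x1 and 1x7 convolutions.
    """

    r: int
    W0: np.ndarray          # (C/r, C)
    b0: np.ndarray          # (C/r,)
    W1: np.ndarray          # (C, C/r)
    b1: np.ndarray          # (C,)
    spatial_reduce_w: np.ndarray  # (1, 2, 1, 1)
    spatial_reduce_b: np.ndarray  # (1,)
    spatial_k7x1: np.ndarray      # (7, 1)
    spatial_k7x1_b: np.ndarray    # (1,)
    spatial_k1x7: np.ndarray      # (1, 7)
    spatial_k1x7_b: np.ndarray    # (1,)

    @property
    def channels(self) -> int:
        return self.W0.shape[1]

    @classmethod
    def zeros(cls, channels: int, r: int = 16) -> "CSAMParams":
        _check_reduction(channels, r)
        h = channels // r
        return cls(
            r=r,
            W0=np.zeros((h, channels)), b0=np.zeros(h),
            W1=np.zeros((channels, h)), b1=np.zeros(channels),
            spatial_reduce_w=np.zeros((1, 2, 1, 1)), spatial_reduce_b=np.zeros(1),
            spatial_k7x1=np.zeros((7, 1)), spatial_k7x1_b=np.zeros(1),
            spatial_k1x7=np.zeros((1, 7)), spatial_k1x7_b=np.zeros(1),
        )

    @classmethod
    def random(cls, channels: int, r: int = 16,
               rng: np.random.Generator | None = None) -> "CSAMParams":
        """Kaiming-style seeded initialisation with zero biases."""
        _check_reduction(channels, r)
        rng = rng if rng is not None else np.random.default_rng(0)
        h = channels // r
        return cls(
            r=r,
            W0=kaiming_normal(rng, (h, channels), channels), b0=np.zeros(h),
            W1=kaiming_normal(rng, (channels, h), h), b1=np.zeros(channels),
            spatial_reduce_w=kaiming_normal(rng, (1, 2, 1, 1), 2),
            spatial_reduce_b=np.zeros(1),
            spatial_k7x1=kaiming_normal(rng, (7, 1), 7), spatial_k7x1_b=np.zeros(1),
            spatial_k1x7=kaiming_normal(rng, (1, 7), 7), spatial_k1x7_b=np.zeros(1),
        )


# ---------------------------------------------------------------- validation
def _check_reduction(channels: int, r: int) -> None:
    if r < 1:
        raise ValueError("reduction ratio r must be a positive integer")
    if channels % r != 0:
        raise ValueError(f"channel count {channels} must be divisible by r={r}")


def _validate_feature_map(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 3:
        raise ValueError(f"feature map must be (C, H, W), got shape {F.shape}")
    if min(F.shape) < 1:
        raise ValueError("feature map axes must all be >= 1")
    if not np.all(np.isfinite(F)):
        raise ValueError("feature map contains non-finite values")
    return F


def _sigmoid(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ------------------------------------------------------- functional operations
def pool_descriptors(F: np.ndarray) -> PooledDescriptors:
    """Mean/max pooled descriptors of ``F`` along space and along channels."""
    F = _validate_feature_map(F)
    return PooledDescriptors(
        channel_avg=F.mean(axis=(1, 2)),
        channel_max=F.max(axis=(1, 2)),
        spatial_avg=F.mean(axis=0),
        spatial_max=F.max(axis=0),
    )


def _mlp(v: np.ndarray, p: CSAMParams) -> np.ndarray:
    hidden = np.maximum(p.W0 @ v + p.b0, 0.0)
    return p.W1 @ hidden + p.b1


def channel_attention(F: np.ndarray, p: CSAMParams) -> np.ndarray:
    """Per-channel gate in (0, 1): shared MLP on each pooled descriptor, summed."""
    F = _validate_feature_map(F)
    if p.channels != F.shape[0]:
        raise ValueError(
            f"CSAMParams built for {p.channels} channels, feature map has {F.shape[0]}"
        )
    _check_reduction(F.shape[0], p.r)
    d = pool_descriptors(F)
    return _sigmoid(_mlp(d.channel_avg, p) + _mlp(d.channel_max, p))


def spatial_attention(F: np.ndarray, p: CSAMParams) -> np.ndarray:
    """Per-position gate in (0, 1) from the stacked channel-pooled maps."""
    F = _validate_feature_map(F)
    d = pool_descriptors(F)
    stacked = np.stack([d.spatial_avg, d.spatial_max])  # (2, H, W)
    reduced = np.tensordot(p.spatial_reduce_w[0, :, 0, 0], stacked, axes=(0, 0))
    reduced = reduced + p.spatial_reduce_b[0]
    out = correlate(reduced, p.spatial_k7x1, mode="constant", cval=0.0)
    out = out + p.spatial_k7x1_b[0]
    out = correlate(out, p.spatial_k1x7, mode="constant", cval=0.0)
    out = out + p.spatial_k1x7_b[0]
    return _sigmoid(out)


def csam_forward(F: np.ndarray, p: CSAMParams) -> np.ndarray:
    """Residual channel + spatial attention: (F + F*M_C) + (F + F*M_S)."""
    F = _validate_feature_map(F)
    mc = channel_attention(F, p)[:, None, None]
    ms = spatial_attention(F, p)[None, :, :]
    return (F + F * mc) + (F + F * ms)


# ------------------------------------------------------------ trainable module
class CSAM(Module):
    """Trainable CSAM over batched (N, C, H, W) tensors."""

    def __init__(self, channels: int, r: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        _check_reduction(channels, r)
        self.channels = channels
        self.r = r
        rng = rng if rng is not None else np.random.default_rng(0)
        hidden = channels // r
        self.w0 = Parameter(kaiming_normal(rng, (hidden, channels), channels))
        self.b0 = Parameter(np.zeros(hidden))
        self.w1 = Parameter(kaiming_normal(rng, (channels, hidden), hidden))
        self.b1 = Parameter(np.zeros(channels))
        self.conv_reduce = Conv2d(2, 1, (1, 1), rng=rng)
        self.conv_7x1 = Conv2d(1, 1, (7, 1), padding=(3, 0), rng=rng)
        self.conv_1x7 = Conv2d(1, 1, (1, 7), padding=(0, 3), rng=rng)

    # ------------------------------------------------------------ conversions
    def zero_(self) -> "CSAM":
        for p in self.parameters():
            p.data = np.zeros_like(p.data)
        return self

    def load_csam_params(self, p: CSAMParams) -> "CSAM":
        if p.channels != self.channels:
            raise ValueError("channel mismatch between CSAMParams and module")
        self.w0.data = p.W0.copy()
        self.b0.data = p.b0.copy()
        self.w1.data = p.W1.copy()
        self.b1.data = p.b1.copy()
        self.conv_reduce.weight.data = p.spatial_reduce_w.copy()
        self.conv_reduce.bias.data = p.spatial_reduce_b.copy()
        self.conv_7x1.weight.data = p.spatial_k7x1.reshape(1, 1, 7, 1).copy()
        self.conv_7x1.bias.data = p.spatial_k7x1_b.copy()
        self.conv_1x7.weight.data = p.spatial_k1x7.reshape(1, 1, 1, 7).copy()
        self.conv_1x7.bias.data = p.spatial_k1x7_b.copy()
        return self

    def get_csam_params(self) -> CSAMParams:
        return CSAMParams(
            r=self.r,
            W0=self.w0.data.copy(), b0=self.b0.data.copy(),
            W1=self.w1.data.copy(), b1=self.b1.data.copy(),
            spatial_reduce_w=self.conv_reduce.weight.data.copy(),
            spatial_reduce_b=self.conv_reduce.bias.data.copy(),
            spatial_k7x1=self.conv_7x1.weight.data.reshape(7, 1).copy(),
            spatial_k7x1_b=self.conv_7x1.bias.data.copy(),
            spatial_k1x7=self.conv_1x7.weight.data.reshape(1, 7).copy(),
            spatial_k1x7_b=self.conv_1x7.bias.data.copy(),
        )

    # ---------------------------------------------------------------- forward
    def _mlp(self, v: Tensor) -> Tensor:
        hidden = (v @ self.w0.transpose((1, 0)) + self.b0.reshape(1, -1)).relu()
        return hidden @ self.w1.transpose((1, 0)) + self.b1.reshape(1, -1)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"CSAM built for {self.channels} channels, got {C}")
        flat = x.reshape(N, C, H * W)
        mc = (self._mlp(flat.mean(axis=2)) + self._mlp(flat.max(axis=2))).sigmoid()
        savg = x.mean(axis=1, keepdims=True)
        smax = x.max(axis=1, keepdims=True)
        s = concat([savg, smax], axis=1)
        ms = self.conv_1x7(self.conv_7x1(self.conv_reduce(s))).sigmoid()
        mc_b = mc.reshape(N, C, 1, 1)
        return (x + x * mc_b) + (x + x * ms)
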