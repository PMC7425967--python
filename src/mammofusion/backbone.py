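"""Multi-scale attention DenseNet backbone.

The building block replaces the classic dense-layer bottleneck with a
hierarchical multi-scale convolution: after a 1x1 bottleneck to the growth
rate ``k`` the channels are split contiguously into four equal subsets
X1..X4; the first passes through untouched (y1 = X1) and each subsequent
subset is combined with the previous output and filtered by a factorised
3x1 + 1x3 convolution pair,

    y_i = K_i(X_i + y_{i-1}),   i = 2..4,

so y4's path has seen three K applications and the largest receptive field.
The concatenated (y1..y4) map is gated by CSAM and returned as the block's
``k`` new feature channels; the dense block concatenates each layer's new
features with everything before it. Transition layers (BN - 1x1 conv - 2x2
average pool) halve both channels and spatial size between blocks.

The canonical network (512x512 input, stem 7x7/2 + 3x3 max pool/2, blocks
of 6, 12, 24, 32, 16 layers, growth rate 32, four transitions, final 8x8
global average pool) has depth 186 under the counting convention audited by
:func:`count_depth`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import CSAM
from .nn import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool2d,
    MaxPool2d,
    Module,
    ModuleList,
    Tensor,
    concat,
    no_grad,
)

__all__ = [
    "DenseBlockSpec",
    "BackboneSpec",
    "MultiScaleBlock",
    "DenseBlock",
    "Transition",
    "MultiScaleAttentionDenseNet",
    "count_depth",
    "multiscale_block_forward",
    "dense_block_forward",
    "transition_forward",
    "backbone_forward",
]

CANONICAL_BLOCK_SIZES = (6, 12, 24, 32, 16)


@dataclass
class DenseBlockSpec:
    """Number of building blocks L and growth rate k of one dense block."""

    L: int
    growth_rate: int = 32

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("dense block needs at least one layer")
        if self.growth_rate % 4 != 0:
            raise ValueError("growth rate must be divisible by 4 (four-way split)")


@dataclass
class BackboneSpec:
    """Architecture description of the multi-scale attention DenseNet."""

    input_size: int = 512
    in_channels: int = 1
    stem_channels: int = 64
    block_sizes: tuple[int, ...] = CANONICAL_BLOCK_SIZES
    growth_rate: int = 32
    compression: float = 0.5
    reduction_ratio: int = 16
    batch_norm: bool = True

    def __post_init__(self):
        if self.growth_rate % 4 != 0:
            raise ValueError("growth rate must be divisible by 4 (four-way split)")
        if self.growth_rate % self.reduction_ratio != 0:
            raise ValueError(
                "growth rate must be divisible by the CSAM reduction ratio"
            )
        if self.compression != 0.5:
            raise ValueError("transition compression is fixed at 1/2")
        if self.input_size % (4 * 2 ** (len(self.block_sizes) - 1)) != 0:
            raise ValueError(
                "input size must be divisible by the total downsampling factor"
            )

    # -------------------------------------------------------------- accounting
    def channel_trace(self) -> list[int]:
        """Channel width after the stem, each block, and each transition."""
        trace = [self.stem_channels]
        c = self.stem_channels
        for i, L in enumerate(self.block_sizes):
            c = c + L * self.growth_rate
            trace.append(c)
            if i < len(self.block_sizes) - 1:
                if c % 2 != 0:
                    raise ValueError("transition requires an even channel count")
                c = c // 2
                trace.append(c)
        return trace

    @property
    def feature_dim(self) -> int:
        return self.channel_trace()[-1]

    def spatial_trace(self) -> list[int]:
        """Per-stage output sizes: stem conv, stem pool, block/transition
        alternation, and the final global pool (the Output Size column)."""
        s = self.input_size
        trace = [s // 2, s // 4]  # stem conv /2, stem max pool /2
        s = s // 4
        for i in range(len(self.block_sizes)):
            if i > 0:
                s = s // 2  # transition pool
                trace.append(s)
            trace.append(s)  # dense block preserves size
        trace.append(1)  # global average pool
        return trace

    def table_trace(self) -> tuple[int, ...]:
        """The 11-entry canonical stage trace: conv, pool, (block, transition)
        x4, final global pool. Block 5 preserves the last transition's size."""
        s = self.input_size
        out = [s // 2, s // 4]
        s = s // 4
        for i in range(len(self.block_sizes) - 1):
            out.append(s)      # dense block i+1
            s = s // 2
            out.append(s)      # transition i+1
        out.append(1)          # global average pool after the final block
        return tuple(out)


def count_depth(spec: BackboneSpec) -> int:
    """Network depth under the DenseNet convention: the stem convolution,
    two counted convolutions per building block (bottleneck + multi-scale
    pair), one per transition, and the classifier layer."""
    n_blocks = sum(spec.block_sizes)
    n_transitions = len(spec.block_sizes) - 1
    return 1 + 2 * n_blocks + n_transitions + 1


# ----------------------------------------------------------------- modules
class _KUnit(Module):
    """One K_i: pre-activation (BN-)ReLU-3x1 conv-(BN-)ReLU-1x3 conv, g -> g."""

    def __init__(self, g: int, batch_norm: bool, rng: np.random.Generator):
        super().__init__()
        self.batch_norm = batch_norm
        if batch_norm:
            self.bn_a = BatchNorm2d(g)
            self.bn_b = BatchNorm2d(g)
        self.conv_3x1 = Conv2d(g, g, (3, 1), padding=(1, 0), rng=rng)
        self.conv_1x3 = Conv2d(g, g, (1, 3), padding=(0, 1), rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn_a(x) if self.batch_norm else x
        h = self.conv_3x1(h.relu())
        h = self.bn_b(h) if self.batch_norm else h
        return self.conv_1x3(h.relu())

    def set_identity(self) -> None:
        """Centre-impulse kernels and zero biases: K_i becomes ReLU-identity
        (exact identity on non-negative inputs). Only valid without BN."""
        for conv in (self.conv_3x1, self.conv_1x3):
            w = np.zeros_like(conv.weight.data)
            g = w.shape[0]
            kh, kw = w.shape[2], w.shape[3]
            for c in range(g):
                w[c, c, kh // 2, kw // 2] = 1.0
            conv.weight.data = w
            conv.bias.data = np.zeros_like(conv.bias.data)


class MultiScaleBlock(Module):
    """The CSAM-gated multi-scale building block producing k new channels."""

    def __init__(self, in_channels: int, growth_rate: int = 32,
                 reduction_ratio: int = 16, batch_norm: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if growth_rate % 4 != 0:
            raise ValueError("growth rate must be divisible by 4 (four-way split)")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.growth_rate = growth_rate
        self.g = growth_rate // 4
        self.batch_norm = batch_norm
        if batch_norm:
            self.bn0 = BatchNorm2d(in_channels)
        self.bottleneck = Conv2d(in_channels, growth_rate, (1, 1), rng=rng)
        self.k_units = ModuleList([_KUnit(self.g, batch_norm, rng) for _ in range(3)])
        self.csam = CSAM(growth_rate, r=reduction_ratio, rng=rng)

    def split_subsets(self, x: Tensor) -> list[Tensor]:
        """Contiguous four-way channel split of the post-bottleneck map."""
        g = self.g
        return [x[:, i * g:(i + 1) * g] for i in range(4)]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"block built for {self.in_channels} input channels, got {x.shape[1]}"
            )
        h = self.bn0(x) if self.batch_norm else x
        h = self.bottleneck(h.relu())
        subsets = self.split_subsets(h)
        ys = [subsets[0]]  # y1 = X1, untouched
        for i in range(1, 4):
            ys.append(self.k_units[i - 1](subsets[i] + ys[-1]))
        return self.csam(concat(ys, axis=1))

    def set_identity_kernels(self) -> None:
        """Identity impulses in every K_i and an identity bottleneck (requires
        in_channels == growth_rate); used for analytic unrolling checks."""
        if self.batch_norm:
            raise ValueError("identity-kernel mode requires batch_norm=False")
        if self.in_channels != self.growth_rate:
            raise ValueError("identity bottleneck requires in_channels == growth_rate")
        w = np.zeros_like(self.bottleneck.weight.data)
        for c in range(self.growth_rate):
            w[c, c, 0, 0] = 1.0
        self.bottleneck.weight.data = w
        self.bottleneck.bias.data = np.zeros_like(self.bottleneck.bias.data)
        for unit in self.k_units:
            unit.set_identity()


class DenseBlock(Module):
    """L multi-scale blocks with dense connectivity (each layer consumes the
    concatenation of the block input and all previous layers' new features)."""

    def __init__(self, in_channels: int, spec: DenseBlockSpec,
                 reduction_ratio: int = 16, batch_norm: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.spec = spec
        self.layers = ModuleList()
        c = in_channels
        for _ in range(spec.L):
            self.layers.append(
                MultiScaleBlock(c, spec.growth_rate, reduction_ratio, batch_norm, rng)
            )
            c += spec.growth_rate
        self.out_channels = c
        self.connection_count = 0

    def forward(self, x: Tensor) -> Tensor:
        features = [x]
        self.connection_count = 0
        for layer in self.layers:
            self.connection_count += len(features)
            inp = features[0] if len(features) == 1 else concat(features, axis=1)
            features.append(layer(inp))
        return concat(features, axis=1)


class Transition(Module):
    """BN - 1x1 conv (channels halved) - 2x2 average pool stride 2."""

    def __init__(self, in_channels: int, batch_norm: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % 2 != 0:
            raise ValueError("transition requires an even input channel count")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = in_channels // 2
        self.batch_norm = batch_norm
        if batch_norm:
            self.bn = BatchNorm2d(in_channels)
        self.conv = Conv2d(in_channels, self.out_channels, (1, 1), rng=rng)
        self.pool = AvgPool2d(2, 2)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 2 != 0 or x.shape[3] % 2 != 0:
            raise ValueError("transition requires even spatial dimensions")
        h = self.bn(x) if self.batch_norm else x
        return self.pool(self.conv(h.relu()))


class MultiScaleAttentionDenseNet(Module):
    """The full backbone: stem, alternating dense blocks and transitions,
    final BN-ReLU and global average pooling to a feature vector."""

    def __init__(self, spec: BackboneSpec | None = None, seed: int = 0):
        super().__init__()
        self.spec = spec if spec is not None else BackboneSpec()
        spec = self.spec
        rng = np.random.default_rng(seed)
        self.stem_conv = Conv2d(spec.in_channels, spec.stem_channels, (7, 7),
                                stride=2, padding=(3, 3), rng=rng)
        self.stem_pool = MaxPool2d(3, 2, padding=1)
        self.blocks = ModuleList()
        self.transitions = ModuleList()
        c = spec.stem_channels
        for i, L in enumerate(spec.block_sizes):
            block = DenseBlock(c, DenseBlockSpec(L, spec.growth_rate),
                               spec.reduction_ratio, spec.batch_norm, rng)
            self.blocks.append(block)
            c = block.out_channels
            if i < len(spec.block_sizes) - 1:
                tr = Transition(c, spec.batch_norm, rng)
                self.transitions.append(tr)
                c = tr.out_channels
        if spec.batch_norm:
            self.final_bn = BatchNorm2d(c)
        self.gap = GlobalAvgPool2d()
        self.feature_dim = c
        self.stage_trace: list[tuple[str, tuple[int, ...]]] = []
        self.block_outputs: list[Tensor] = []
        self.last_block_output: Tensor | None = None

    def forward(self, x: Tensor) -> Tensor:
        spec = self.spec
        if x.ndim != 4 or x.shape[1] != spec.in_channels:
            raise ValueError(
                f"expected input of shape (N, {spec.in_channels}, "
                f"{spec.input_size}, {spec.input_size})"
            )
        if x.shape[2] != spec.input_size or x.shape[3] != spec.input_size:
            raise ValueError(
                f"expected {spec.input_size}x{spec.input_size} input, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        trace = []
        h = self.stem_conv(x)
        trace.append(("stem_conv", h.shape))
        h = self.stem_pool(h)
        trace.append(("stem_pool", h.shape))
        self.block_outputs = []
        for i, block in enumerate(self.blocks):
            h = block(h)
            trace.append((f"dense_block_{i + 1}", h.shape))
            self.block_outputs.append(h)
            if i < len(self.transitions):
                h = self.transitions[i](h)
                trace.append((f"transition_{i + 1}", h.shape))
        self.last_block_output = h
        if spec.batch_norm:
            h = self.final_bn(h)
        v = self.gap(h.relu())
        trace.append(("global_pool", (v.shape[0], v.shape[1], 1, 1)))
        self.stage_trace = trace
        return v


# ------------------------------------------------------- functional wrappers
def _as_batched(F: np.ndarray) -> Tensor:
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 3:
        raise ValueError(f"expected a (C, H, W) feature map, got shape {F.shape}")
    if not np.all(np.isfinite(F)):
        raise ValueError("feature map contains non-finite values")
    return Tensor(F[None])


def multiscale_block_forward(F: np.ndarray, block: MultiScaleBlock) -> np.ndarray:
    """Run one multi-scale building block on a (C, H, W) map (inference mode)."""
    block.eval()
    with no_grad():
        return block(_as_batched(F)).data[0]


def dense_block_forward(F: np.ndarray, block: DenseBlock) -> np.ndarray:
    block.eval()
    with no_grad():
        return block(_as_batched(F)).data[0]


def transition_forward(F: np.ndarray, transition: Transition | None = None) -> np.ndarray:
    if transition is None:
        transition = Transition(np.asarray(F).shape[0])
    transition.eval()
    with no_grad():
        return transition(_as_batched(F)).data[0]


def backbone_forward(image: np.ndarray, net: MultiScaleAttentionDenseNet
                     ) -> tuple[np.ndarray, list[tuple[str, tuple[int, ...]]]]:
    """Run the backbone on a (1, H, W) image; returns (feature vector, stage trace)."""
    net.eval()
    with no_grad():
        v = net(_as_batched(image))
    return v.data[0], list(net.stage_trace)
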