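"""Neural-network layers and the module container system.

Layers follow the familiar NCHW convention and pre-activation style used by
densely connected networks. Weight initialisation is Kaiming-style fan-in
scaling, driven by an explicit ``numpy.random.Generator`` so every network
build is reproducible from a single seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "AvgPool2d",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "ReLU",
    "softmax",
    "softmax_cross_entropy",
    "kaiming_normal",
]


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int) -> np.ndarray:
    """He-normal init: std = sqrt(2 / fan_in)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Minimal module container: parameter registry, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -------------------------------------------------------------- traversal
    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, ModuleList):
                yield from v

    def modules(self) -> Iterator["Module"]:
        yield self
        for c in self.children():
            yield from c.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, ModuleList):
                for i, m in enumerate(v):
                    yield from m.named_parameters(f"{key}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        """Non-learnable state (batch-norm running statistics)."""
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_buffers(f"{key}.")
            elif isinstance(v, ModuleList):
                for i, m in enumerate(v):
                    yield from m.named_buffers(f"{key}.{i}.")
            elif name.startswith("running_") and isinstance(v, np.ndarray):
                yield key, v

    # ------------------------------------------------------------------ mode
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # ----------------------------------------------------------------- state
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_params = dict(self.named_parameters())
        own_buffers = dict(self.named_buffers())
        missing = (set(own_params) | set(own_buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]} ...")
        for name, p in own_params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for name, b in own_buffers.items():
            arr = np.asarray(state[name], dtype=np.float64)
            b[...] = arr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class ModuleList(list):
    """A list whose Module elements are visible to the parent's registry."""


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int] | int, stride: int = 1,
                 padding: tuple[int, int] | int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        if isinstance(padding, int):
            padding = (padding, padding)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        kh, kw = kernel_size
        fan_in = in_channels * kh * kw
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(kaiming_normal(rng, (out_channels, in_channels, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(kaiming_normal(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose((1, 0))
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.out_features)
        return out


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel, with running statistics.

    In training mode the batch statistics are used and running estimates are
    updated with momentum 0.1; in eval mode the running estimates are used, so
    a frozen branch is a fixed affine map of its input.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        C = self.num_features
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(C)
            unbiased = var.data.reshape(C) * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = xc * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, C, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, C, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class AvgPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride if stride is not None else kernel
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.pool2d(self.kernel, self.stride, self.padding, mode="avg")


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride if stride is not None else kernel
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.pool2d(self.kernel, self.stride, self.padding, mode="max")


class GlobalAvgPool2d(Module):
    """Collapse (N, C, H, W) to the per-channel spatial mean (N, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis (plain ndarray helper)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between row-wise softmax(logits) and integer labels.

    Implemented as a single primitive with the closed-form gradient
    (softmax - onehot) / N for stability.
    """
    labels = np.asarray(labels, dtype=np.intp)
    N = logits.shape[0]
    p = softmax(logits.data)
    nll = -np.log(np.clip(p[np.arange(N), labels], 1e-300, None))
    loss_val = nll.mean()

    def bwd(g):
        if logits.requires_grad:
            onehot = np.zeros_like(p)
            onehot[np.arange(N), labels] = 1.0
            logits._accum(g * (p - onehot) / N)

    return logits._make(np.asarray(loss_val), (logits,), bwd)
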