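"""Reverse-mode automatic differentiation over NumPy arrays.

A compact tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers the operation that produced it. ``Tensor.backward`` walks the graph
in reverse topological order and accumulates gradients into every tensor with
``requires_grad=True``. Only the primitives the network modules need are
implemented (elementwise arithmetic, matmul, 2-D convolution/pooling, axis
reductions, concatenation, slicing, the usual activations).

All data is kept in float64: the test suite verifies analytic identities to
tight tolerances, and the models involved are small enough that the extra
precision is cheap.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Tensor", "Parameter", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------ graph build
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            return Tensor(data, requires_grad=True, _parents=parents, _backward=backward)
        return Tensor(data)

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), bwd)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return self._make(out_data, (self, other), bwd)

    # ------------------------------------------------------------ activations
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(out_data, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        d = self.data
        s = np.empty_like(d)
        pos = d >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
        e = np.exp(d[~pos])
        s[~pos] = e / (1.0 + e)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), bwd)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e)

        return self._make(e, (self,), bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            out_b = self.data.max(axis=axis, keepdims=True)
            mask = (self.data == out_b).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask * g)

        return self._make(out_data, (self,), bwd)

    # ---------------------------------------------------------- shape surgery
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(out_data, (self,), bwd)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), bwd)

    def pad2d(self, ph: int, pw: int) -> "Tensor":
        """Zero-pad the last two axes by (ph, pw) on each side."""
        if ph == 0 and pw == 0:
            return self
        pad = [(0, 0)] * (self.ndim - 2) + [(ph, ph), (pw, pw)]
        out_data = np.pad(self.data, pad)

        def bwd(g):
            if self.requires_grad:
                sl = [slice(None)] * (self.ndim - 2)
                sl += [slice(ph, g.shape[-2] - ph), slice(pw, g.shape[-1] - pw)]
                self._accum(g[tuple(sl)])

        return self._make(out_data, (self,), bwd)

    # ------------------------------------------------------------ convolution
    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None,
               stride: int = 1, padding: tuple[int, int] = (0, 0)) -> "Tensor":
        """2-D cross-correlation, NCHW layout.

        ``weight`` has shape (C_out, C_in, kh, kw); ``padding`` is per-axis
        symmetric zero padding. Implemented by im2col + one matmul, with the
        col2im scatter written out in the backward pass.
        """
        x = self
        N, C, H, W = x.shape
        Cout, Cin, kh, kw = weight.shape
        if Cin != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Cin}")
        ph, pw = padding
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
        Hp, Wp = xp.shape[2], xp.shape[3]
        Ho = (Hp - kh) // stride + 1
        Wo = (Wp - kw) // stride + 1
        sN, sC, sH, sW = xp.strides
        cols = as_strided(
            xp, (N, C, kh, kw, Ho, Wo), (sN, sC, sH, sW, sH * stride, sW * stride)
        )
        cols_m = np.ascontiguousarray(cols).reshape(N, C * kh * kw, Ho * Wo)
        w_m = weight.data.reshape(Cout, C * kh * kw)
        out = np.matmul(w_m, cols_m).reshape(N, Cout, Ho, Wo)
        if bias is not None:
            out = out + bias.data.reshape(1, Cout, 1, 1)

        def bwd(g):
            g_m = g.reshape(N, Cout, Ho * Wo)
            if weight.requires_grad:
                dw = np.einsum("nop,ncp->oc", g_m, cols_m).reshape(weight.shape)
                weight._accum(dw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = np.matmul(w_m.T, g_m).reshape(N, C, kh, kw, Ho, Wo)
                dxp = np.zeros((N, C, Hp, Wp))
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += dcols[:, :, i, j]
                if ph or pw:
                    dxp = dxp[:, :, ph:Hp - ph, pw:Wp - pw]
                x._accum(dxp)

        parents = (x, weight) if bias is None else (x, weight, bias)
        return self._make(out, parents, bwd)

    # ---------------------------------------------------------------- pooling
    def pool2d(self, kernel: int, stride: int, padding: int = 0,
               mode: str = "avg") -> "Tensor":
        """Average or max pooling over kh=kw=kernel windows, NCHW layout."""
        if mode not in ("avg", "max"):
            raise ValueError("mode must be 'avg' or 'max'")
        x = self
        N, C, H, W = x.shape
        p = padding
        if mode == "max" and p:
            xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                        constant_values=-np.inf)
        elif p:
            xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x.data
        Hp, Wp = xp.shape[2], xp.shape[3]
        Ho = (Hp - kernel) // stride + 1
        Wo = (Wp - kernel) // stride + 1
        sN, sC, sH, sW = xp.strides
        win = as_strided(
            xp, (N, C, Ho, Wo, kernel, kernel), (sN, sC, sH * stride, sW * stride, sH, sW)
        )
        if mode == "avg":
            out = win.mean(axis=(4, 5))
        else:
            out = win.max(axis=(4, 5))

        def bwd(g):
            if not x.requires_grad:
                return
            dxp = np.zeros((N, C, Hp, Wp))
            if mode == "avg":
                gk = g / (kernel * kernel)
                for i in range(kernel):
                    for j in range(kernel):
                        dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += gk
            else:
                # ties split evenly, matching Tensor.max
                eq = (win == out[..., None, None])
                ties = eq.sum(axis=(4, 5), keepdims=True)
                contrib = eq / ties * g[..., None, None]
                for i in range(kernel):
                    for j in range(kernel):
                        dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += contrib[..., i, j]
            if p:
                dxp = dxp[:, :, p:Hp - p, p:Wp - p]
            x._accum(dxp)

        return self._make(out, (x,), bwd)


class Parameter(Tensor):
    """A tensor registered as learnable by the module system."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    ref = tensors[0]
    return ref._make(out_data, tuple(tensors), bwd)
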