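"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-based engine in the micrograd style, sized for the small set models
in this package: dense/batched matmul, broadcasting elementwise arithmetic,
reductions, basic slicing/concatenation, and a strided 2-D convolution
implemented by im2col. Gradients are accumulated on every tensor reachable
from the loss; ``Tensor.backward`` runs a topological sweep.

Every operation here is covered by finite-difference gradient checks in the
test suite; that, rather than framework parity, is the correctness contract.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- graph bookkeeping ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = np.zeros_like(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: List[Tensor] = []
        seen = set()

        def visit(node: "Tensor"):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out._parents = tuple(parents)
        out._backward = backward
        return out

    # -- elementwise arithmetic ----------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward():
            self.grad += _unbroadcast(out.grad, self.data.shape)
            other.grad += _unbroadcast(out.grad, other.data.shape)

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            self.grad -= out.grad

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward():
            self.grad += _unbroadcast(out.grad * other.data, self.data.shape)
            other.grad += _unbroadcast(out.grad * self.data, other.data.shape)

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward():
            self.grad += out.grad * exponent * self.data ** (exponent - 1.0)

        out = self._make(out_data, (self,), backward)
        return out

    # -- matmul ----------------------------------------------------------------

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward():
            a, b, g = self.data, other.data, out.grad
            if a.ndim == 1 and b.ndim == 1:
                self.grad += g * b
                other.grad += g * a
                return
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            self.grad += _unbroadcast(ga, a.shape)
            other.grad += _unbroadcast(gb, b.shape)

        out = self._make(out_data, (self, other), backward)
        return out

    # -- nonlinearities and transcendentals -----------------------------------

    def relu(self):
        mask = self.data > 0

        def backward():
            self.grad += out.grad * mask

        out = self._make(self.data * mask, (self,), backward)
        return out

    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            self.grad += out.grad * out_data

        out = self._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward():
            self.grad += out.grad / self.data

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward():
            self.grad += out.grad * (1.0 - out_data**2)

        out = self._make(out_data, (self,), backward)
        return out

    # -- reductions and shaping ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.grad += np.broadcast_to(g, self.data.shape)

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward():
            self.grad += out.grad.reshape(orig)

        out = self._make(self.data.reshape(shape), (self,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def backward():
            self.grad += out.grad.transpose(inverse)

        out = self._make(self.data.transpose(axes), (self,), backward)
        return out

    def __getitem__(self, key):
        def backward():
            np.add.at(self.grad, key, out.grad)

        out = self._make(self.data[key], (self,), backward)
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along ``axis``, splitting the gradient back."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * data.ndim
            index[axis] = slice(start, stop)
            t.grad += out.grad[tuple(index)]

    out = Tensor._make(data, tuple(tensors), backward)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from primitive ops."""
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (NCHW) via im2col; backward by col2im scatter-add.

    ``x``: (N, C, H, W); ``w``: (Co, C, kh, kw); ``b``: (Co,).
    """
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    Co, Ci, kh, kw = wd.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Ci}")
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else xd
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw
    )
    wm = wd.reshape(Co, -1)
    out2d = cols @ wm.T + b.data
    out_data = out2d.reshape(N, Ho, Wo, Co).transpose(0, 3, 1, 2)

    def backward():
        g2 = out.grad.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Co)
        w.grad += (g2.T @ cols).reshape(wd.shape)
        b.grad += g2.sum(axis=0)
        dcols = g2 @ wm
        dwin = dcols.reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += dwin[
                    :, :, :, :, i, j
                ]
        x.grad += dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp

    out = Tensor._make(out_data, (x, w, b), backward)
    return out
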