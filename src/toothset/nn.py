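"""Neural-network building blocks on top of the autodiff engine.

Provides the pieces the set classifier needs: linear and convolutional
layers, layer normalization, multi-head self-attention, post-norm
Transformer encoder blocks, and an Adam optimizer with optional decoupled
weight decay applied to weight matrices only (never biases or norm gains).
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from ._autograd import Tensor, concat, conv2d, softmax

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "Adam",
]


class Parameter(Tensor):
    """A trainable tensor; ``decay`` marks eligibility for weight decay."""

    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(data, requires_grad=True)
        self.decay = decay


class Module:
    """Lightweight parameter container with recursive traversal."""

    def parameters(self) -> List[Parameter]:
        params: List[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> Dict[str, Parameter]:
        named: Dict[str, Parameter] = {}
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                named[key] = value
            elif isinstance(value, Module):
                named.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        named.update(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        named[f"{key}.{i}"] = item
        return named

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]):
        named = self.named_parameters()
        missing = set(named) - set(state)
        unexpected = set(state) - set(named)
        if missing or unexpected:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)}, "
                f"unexpected={sorted(unexpected)}"
            )
        for key, param in named.items():
            if param.data.shape != state[key].shape:
                raise ValueError(f"shape mismatch for {key}")
            param.data = state[key].astype(np.float32).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = math.sqrt(6.0 / (n_in + n_out))
        self.weight = Parameter(rng.uniform(-bound, bound, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out), decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
        pad: Optional[int] = None,
    ):
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(
            rng.normal(0.0, math.sqrt(2.0 / fan_in), (c_out, c_in, kernel, kernel))
        )
        self.bias = Parameter(np.zeros(c_out), decay=False)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(dim), decay=False)
        self.shift = Parameter(np.zeros(dim), decay=False)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.gain + self.shift


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.head_dim = dim // heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, hd = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, hd).transpose(0, 2, 1, 3)  # (B,h,T,hd)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        attn = softmax(scores, axis=-1)
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.proj(mixed)


class TransformerBlock(Module):
    """Transformer encoder block, pre-norm by default.

    Pre-norm (``x + attn(LN(x))``) keeps the residual path unnormalized and
    trains stably in short schedules; post-norm (``LN(x + attn(x))``), the
    original formulation, is available via ``pre_norm=False``.
    """

    def __init__(
        self,
        dim: int,
        heads: int,
        mlp_ratio: int,
        rng: np.random.Generator,
        pre_norm: bool = True,
    ):
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = Linear(mlp_ratio * dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.pre_norm = pre_norm

    def __call__(self, x: Tensor) -> Tensor:
        if self.pre_norm:
            x = x + self.attn(self.norm1(x))
            x = x + self.fc2(self.fc1(self.norm2(x)).relu())
            return x
        x = self.norm1(x + self.attn(x))
        x = self.norm2(x + self.fc2(self.fc1(x).relu()))
        return x


class Adam:
    """Adam with optional decoupled weight decay on decay-tagged parameters.

    ``decoupled=True`` subtracts ``lr * weight_decay * w`` outside the
    moment estimates; ``decoupled=False`` adds ``weight_decay * w`` to the
    gradient before the moment update (classic L2-in-gradient coupling).
    """

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-4,
        betas: Tuple[float, float] = (0.9, 0.99),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        decoupled: bool = True,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    @property
    def decay_params(self) -> List[Parameter]:
        return [p for p in self.params if p.decay]

    @property
    def no_decay_params(self) -> List[Parameter]:
        return [p for p in self.params if not p.decay]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay and p.decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1**self.t)
            v_hat = self._v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay and p.decay and self.decoupled:
                p.data = p.data - self.lr * self.weight_decay * p.data

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
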