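"""Neural-network building blocks for the separation model.

Thin module system over :mod:`neosep.tensor`: parameter registration,
the layers the mask generator needs (pointwise/strided convolutions,
layer norm, PReLU, multi-head self-attention, pre-norm transformer
blocks) and an AdamW optimizer with the AMSGrad extension.
"""

from __future__ import annotations

import numpy as np

from .tensor import (DTYPE, Tensor, conv1d, conv_transpose1d, layer_norm)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: child modules/parameters are discovered by attribute scan."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            for v in obj.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    out.append(v)
                elif isinstance(v, Module):
                    collect(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Module):
                            collect(item)
        collect(self)
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                if isinstance(v, Parameter):
                    state[prefix + k] = v.data.copy()
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")
        walk(self, "")
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                if isinstance(v, Parameter):
                    key = prefix + k
                    if key not in state:
                        raise KeyError(f"missing parameter {key!r} in state")
                    arr = np.asarray(state[key], dtype=DTYPE)
                    if arr.shape != v.data.shape:
                        raise ValueError(
                            f"shape mismatch for {key!r}: "
                            f"{arr.shape} vs {v.data.shape}")
                    v.data = arr.copy()
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")
        walk(self, "")


# ----------------------------------------------------------------------
# Layers
# ----------------------------------------------------------------------

class Conv1d(Module):
    """(B, Cin, L) -> (B, Cout, Lout); Kaiming-uniform init like the field's default."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_ch * kernel)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_ch, in_ch, kernel)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 bias: bool = True, *, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_ch * kernel)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_ch, out_ch, kernel)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_ch)) if bias else None
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose1d(x, self.weight, self.bias, self.stride)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True, *,
                 rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_dim, out_dim)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    """Normalises one axis; parameters broadcast along the others."""

    def __init__(self, dim: int, axis: int = -1, ndim: int = 3):
        shape = [1] * ndim
        shape[axis] = dim
        self.gamma = Parameter(np.ones(shape))
        self.beta = Parameter(np.zeros(shape))
        self.axis = axis

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, axis=self.axis)


class PReLU(Module):
    """Parametric ReLU with a single learned slope (the common default)."""

    def __init__(self, init: float = 0.25):
        self.alpha = Parameter(np.array(init))

    def __call__(self, x: Tensor) -> Tensor:
        return x.relu() - self.alpha * (-x).relu()


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention over (B, M, D) sequences."""

    def __init__(self, dim: int, num_heads: int, *, rng: np.random.Generator):
        if dim % num_heads != 0:
            raise ValueError(f"attention width {dim} not divisible by "
                             f"{num_heads} heads")
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.out = Linear(dim, dim, rng=rng)
        self.num_heads = num_heads
        self.head_dim = dim // num_heads

    def __call__(self, x: Tensor) -> Tensor:
        B, M, D = x.shape
        h, d = self.num_heads, self.head_dim
        qkv = self.qkv(x)                                    # (B, M, 3D)
        qkv = qkv.reshape(B, M, 3, h, d).transpose(2, 0, 3, 1, 4)  # (3,B,h,M,d)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v                                       # (B, h, M, d)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, M, D)
        return self.out(ctx)


class TransformerBlock(Module):
    """Pre-norm residual block: x + MHA(LN(x)); x + FF(LN(x)) with GELU."""

    def __init__(self, dim: int, num_heads: int, ff_multiplier: int = 4, *,
                 rng: np.random.Generator):
        self.norm1 = LayerNorm(dim, axis=-1, ndim=3)
        self.attn = MultiheadSelfAttention(dim, num_heads, rng=rng)
        self.norm2 = LayerNorm(dim, axis=-1, ndim=3)
        self.ff1 = Linear(dim, ff_multiplier * dim, rng=rng)
        self.ff2 = Linear(ff_multiplier * dim, dim, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ff2(self.ff1(self.norm2(x)).gelu())


class ConvBlock(Module):
    """Residual depth block: same-padded conv, channel layer norm, PReLU."""

    def __init__(self, channels: int, kernel: int, *, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("conv block kernel must be odd for same padding")
        self.conv = Conv1d(channels, channels, kernel,
                           padding=kernel // 2, rng=rng)
        self.norm = LayerNorm(channels, axis=1, ndim=3)
        self.act = PReLU()

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.act(self.norm(self.conv(x)))


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding, shape (length, dim)."""
    pos = np.arange(length, dtype=DTYPE)[:, None]
    i = np.arange(dim, dtype=DTYPE)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.empty((length, dim), dtype=DTYPE)
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


# ----------------------------------------------------------------------
# Optimisation
# ----------------------------------------------------------------------

def global_grad_norm(params: list[Parameter]) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad ** 2))
    return float(np.sqrt(total))


def clip_grad_norm(params: list[Parameter], max_l2: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``max_l2``.

    Returns the pre-clip norm.
    """
    if max_l2 <= 0:
        raise ValueError("max_l2 must be positive")
    norm = global_grad_norm(params)
    if norm > max_l2:
        scale = max_l2 / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


class AdamW:
    """Decoupled weight decay Adam with the AMSGrad maximum-of-v correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.1, amsgrad: bool = True):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.amsgrad = amsgrad
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.vhat = [np.zeros_like(p.data) for p in params] if amsgrad else None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            if self.amsgrad:
                np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
                denom = np.sqrt(self.vhat[i] / bc2) + self.eps
            else:
                denom = np.sqrt(self.v[i] / bc2) + self.eps
            p.data = p.data - self.lr * (
                (self.m[i] / bc1) / denom + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
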