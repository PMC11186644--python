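"""Minimal reverse-mode automatic differentiation over numpy arrays.

The separation network is small (a few million parameters, sequence
lengths of a few hundred frames), so a compact define-by-run tape over
numpy's BLAS-backed primitives is sufficient to train it on a single
CPU.  Only the operations the model needs are provided; every backward
rule is checked against central finite differences in the test suite.

Conventions
-----------
* ``Tensor.data`` is always a ``numpy.ndarray`` of dtype ``DTYPE``.
* Gradients accumulate into ``Tensor.grad`` (same shape as ``data``)
  during :meth:`Tensor.backward`, which topologically sorts the tape.
* Broadcasting follows numpy; gradients are summed back over broadcast
  axes.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # Leading axes added by broadcasting.
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # Axes of size 1 that were stretched.
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or not g.flags.owndata else g
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        """Backpropagate from this tensor through the tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.data.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        a, b = self.data, other.data

        def bw(g):
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.expand_dims(g, -1) * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.expand_dims(a, -1) * np.expand_dims(g, -2) \
                        if g.ndim else np.outer(a, g)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, b.shape))
        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bw
        return out

    # -- reductions / reshapes -----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bw
        return out

    # -- elementwise nonlinearities ------------------------------------
    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = bw
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out.data)
        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))
        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0.0))
        out._backward = bw
        return out

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = Tensor(0.5 * x * (1.0 + t), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
                d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
                self._accum(g * d)
        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        """Clamp with zero gradient outside [lo, hi]."""
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                mask = (self.data >= lo) & (self.data <= hi)
                self._accum(g * mask)
        out._backward = bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))
        out._backward = bw
        return out


# ----------------------------------------------------------------------
# Framing helpers shared by the convolution ops
# ----------------------------------------------------------------------

def _im2col(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(B, C, L) -> (B, Lout, C*kernel) patch matrix (copied, contiguous)."""
    B, C, L = x.shape
    Lout = (L - kernel) // stride + 1
    sB, sC, sL = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(B, Lout, C, kernel), strides=(sB, sL * stride, sC, sL))
    return np.ascontiguousarray(patches).reshape(B, Lout, C * kernel)


def _col2im(cols: np.ndarray, C: int, kernel: int, stride: int,
            L: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (B, C, L)."""
    B, Lout, _ = cols.shape
    cols = cols.reshape(B, Lout, C, kernel)
    x = np.zeros((B, C, L), dtype=cols.dtype)
    for k in range(kernel):
        x[:, :, k:k + Lout * stride:stride] += cols[:, :, :, k].transpose(0, 2, 1)
    return x


def conv1d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """1-D convolution (cross-correlation): (B,Cin,L) * (Cout,Cin,K) -> (B,Cout,Lout)."""
    B, Cin, L = x.shape
    Cout, Cin_w, K = w.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    Lp = L + 2 * padding
    if Lp < K:
        raise ValueError(f"input length {Lp} shorter than kernel {K}")
    cols = _im2col(xp, K, stride)                        # (B, Lout, Cin*K)
    Wm = w.data.reshape(Cout, Cin * K).T                 # (Cin*K, Cout)
    y = cols @ Wm                                        # (B, Lout, Cout)
    if b is not None:
        y = y + b.data
    out = Tensor(np.ascontiguousarray(y.transpose(0, 2, 1)),
                 _parents=tuple(t for t in (x, w, b) if t is not None))

    def bw(g):
        gy = g.transpose(0, 2, 1)                        # (B, Lout, Cout)
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=(0, 1)))
        if w.requires_grad:
            gW = np.tensordot(gy, cols, axes=([0, 1], [0, 1])).T  # (Cin*K, Cout) -> T
            w._accum(gW.T.reshape(Cout, Cin, K))
        if x.requires_grad:
            gcols = gy @ Wm.T                            # (B, Lout, Cin*K)
            gx = _col2im(gcols, Cin, K, stride, Lp)
            if padding:
                gx = gx[:, :, padding:Lp - padding]
            x._accum(gx)
    out._backward = bw
    return out


def conv_transpose1d(x: Tensor, w: Tensor, b: Tensor | None,
                     stride: int = 1) -> Tensor:
    """1-D transposed convolution: (B,Cin,M) * (Cin,Cout,K) -> (B,Cout,(M-1)*stride+K)."""
    B, Cin, M = x.shape
    Cin_w, Cout, K = w.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    Lout = (M - 1) * stride + K
    Wm = w.data.reshape(Cin, Cout * K)                   # (Cin, Cout*K)
    xt = x.data.transpose(0, 2, 1)                       # (B, M, Cin)
    cols = xt @ Wm                                       # (B, M, Cout*K)
    y = _col2im(cols, Cout, K, stride, Lout)             # (B, Cout, Lout)
    if b is not None:
        y = y + b.data[None, :, None]
    out = Tensor(y, _parents=tuple(t for t in (x, w, b) if t is not None))

    def bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        gcols = _im2col(g, K, stride)                    # (B, M, Cout*K)
        if w.requires_grad:
            gW = np.tensordot(xt, gcols, axes=([0, 1], [0, 1]))  # (Cin, Cout*K)
            w._accum(gW.reshape(Cin, Cout, K))
        if x.requires_grad:
            gx = gcols @ Wm.T                            # (B, M, Cin)
            x._accum(np.ascontiguousarray(gx.transpose(0, 2, 1)))
    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, axis: int = -1,
               eps: float = 1e-6) -> Tensor:
    """Layer normalisation over one axis with learned affine parameters.

    ``gamma``/``beta`` must broadcast against ``x`` (shape 1s elsewhere).
    """
    mu = x.data.mean(axis=axis, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=axis, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(gamma.data * xhat + beta.data, _parents=(x, gamma, beta))
    n = x.data.shape[axis]

    def bw(g):
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if x.requires_grad:
            gh = g * gamma.data
            t1 = gh.sum(axis=axis, keepdims=True)
            t2 = (gh * xhat).sum(axis=axis, keepdims=True)
            x._accum(inv * (gh - t1 / n - xhat * t2 / n))
    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    out._backward = bw
    return out


def pad_last(x: Tensor, left: int, right: int) -> Tensor:
    """Zero-pad the last axis."""
    widths = [(0, 0)] * (x.ndim - 1) + [(left, right)]
    out = Tensor(np.pad(x.data, widths), _parents=(x,))

    def bw(g):
        if x.requires_grad:
            sl = [slice(None)] * g.ndim
            sl[-1] = slice(left, g.shape[-1] - right if right else None)
            x._accum(g[tuple(sl)])
    out._backward = bw
    return out
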