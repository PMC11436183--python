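"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the compute core of the package: a :class:`Tensor` wrapping an
``ndarray`` with a dynamically built backward graph, the handful of
primitives the capsule network needs (elementwise arithmetic, reductions,
reshapes, binary ``einsum``, 2-D convolution with optional depthwise
grouping, average pooling, ELU/ReLU), and an :class:`Adam` optimizer.

Design constraints:

* float64 throughout — determinism and gradient-check accuracy beat speed
  at the model sizes used here;
* convolutions are stride-1 (the architecture downsamples only through
  pooling), with explicit, possibly asymmetric zero padding;
* ``einsum`` supports two operands whose subscripts are unique within each
  operand — sufficient for every contraction in the model, and it makes
  the gradient rule a pure subscript swap.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion depth can exceed limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = astensor(other)
        out = _node(self.data + other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = astensor(other)
        out = _node(self.data * other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __truediv__(self, other):
        return self * astensor(other) ** -1.0

    def __rtruediv__(self, other):
        return astensor(other) * self**-1.0

    def __pow__(self, exponent: float):
        out = _node(self.data**exponent, (self,))

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def exp(self):
        out = _node(np.exp(self.data), (self,))

        def backward(g):
            self._accum(g * out.data)

        out._backward = backward
        return out

    def relu(self):
        out = _node(np.maximum(self.data, 0.0), (self,))

        def backward(g):
            self._accum(g * (self.data > 0.0))

        out._backward = backward
        return out

    def elu(self, alpha: float = 1.0):
        out = _node(np.where(self.data > 0.0, self.data, alpha * np.expm1(self.data)), (self,))

        def backward(g):
            self._accum(g * np.where(self.data > 0.0, 1.0, out.data + alpha))

        out._backward = backward
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape, nd = self.shape, self.ndim

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            axes = tuple(a % nd for a in axes)
            if not keepdims:
                for a in sorted(axes):
                    g = np.expand_dims(g, a)
            self._accum(np.broadcast_to(g, shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------ shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        orig = self.shape

        def backward(g):
            self._accum(g.reshape(orig))

        out._backward = backward
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        out = _node(self.data.transpose(axes), (self,))
        inv = tuple(np.argsort(axes))

        def backward(g):
            self._accum(g.transpose(inv))

        out._backward = backward
        return out


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._prev = tuple(p for p in parents if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad or p._prev for p in out._prev)
    return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    """Wrap an array as a trainable leaf tensor."""
    t = Tensor(np.array(data, dtype=np.float64, copy=True), requires_grad=True)
    return t


# ---------------------------------------------------------------------- einsum
def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Binary einsum with autodiff.

    Requires explicit output subscripts and no repeated index within a
    single operand; the gradient of each operand is then the einsum of the
    output gradient with the other operand under swapped subscripts.
    """
    a, b = astensor(a), astensor(b)
    lhs, out_sub = spec.replace(" ", "").split("->")
    sub_a, sub_b = lhs.split(",")
    for s in (sub_a, sub_b, out_sub):
        if len(set(s)) != len(s):
            raise ValueError(f"repeated subscript in '{s}' is not supported")
    out = _node(np.einsum(spec, a.data, b.data, optimize=True), (a, b))

    def backward(g):
        a._accum(np.einsum(f"{out_sub},{sub_b}->{sub_a}", g, b.data, optimize=True))
        b._accum(np.einsum(f"{out_sub},{sub_a}->{sub_b}", g, a.data, optimize=True))

    out._backward = backward
    return out


# ----------------------------------------------------------------- convolution
def conv2d(
    x: Tensor,
    w: Tensor,
    bias: Tensor | None = None,
    padding: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0)),
    depthwise: bool = False,
) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) over (B, C, H, W) input.

    ``w`` has shape (C_out, C_in, kh, kw) for a dense convolution, or
    (C_in * mult, 1, kh, kw) for a depthwise one (``depthwise=True``),
    where each input channel is filtered by ``mult`` private kernels.
    """
    x, w = astensor(x), astensor(w)
    (pt, pb), (pl, pr) = padding
    B, Ci, H, W = x.shape
    kh, kw = w.shape[2], w.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (B,Ci,Ho,Wo,kh,kw)

    if depthwise:
        mult = w.shape[0] // Ci
        w2 = w.data.reshape(Ci, mult, kh, kw)
        out_data = np.einsum("bcijuv,cmuv->bcmij", win, w2, optimize=True)
        out_data = out_data.reshape(B, Ci * mult, Ho, Wo)
    else:
        out_data = np.einsum("bcijuv,ocuv->boij", win, w.data, optimize=True)

    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)
    parents = (x, w, bias) if bias is not None else (x, w)
    out = _node(out_data, parents)

    def backward(g):
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if depthwise:
            mult = w.shape[0] // Ci
            g4 = g.reshape(B, Ci, mult, Ho, Wo)
            gw = np.einsum("bcijuv,bcmij->cmuv", win, g4, optimize=True)
            w._accum(gw.reshape(w.shape))
        else:
            w._accum(np.einsum("bcijuv,boij->ocuv", win, g, optimize=True))
        gxp = np.zeros((B, Ci, Hp, Wp))
        if depthwise:
            mult = w.shape[0] // Ci
            w2 = w.data.reshape(Ci, mult, kh, kw)
            g4 = g.reshape(B, Ci, mult, Ho, Wo)
            for u in range(kh):
                for v in range(kw):
                    contrib = np.einsum("bcmij,cm->bcij", g4, w2[:, :, u, v], optimize=True)
                    gxp[:, :, u : u + Ho, v : v + Wo] += contrib
        else:
            for u in range(kh):
                for v in range(kw):
                    contrib = np.einsum("boij,oc->bcij", g, w.data[:, :, u, v], optimize=True)
                    gxp[:, :, u : u + Ho, v : v + Wo] += contrib
        x._accum(gxp[:, :, pt : pt + H, pl : pl + W])

    out._backward = backward
    return out


def same_padding(k: int) -> tuple[int, int]:
    """Left/right zero padding preserving length under a width-k kernel."""
    total = k - 1
    return total // 2, total - total // 2


def avg_pool2d(x: Tensor, pool: tuple[int, int]) -> Tensor:
    """Non-overlapping average pooling; trailing remainders are dropped."""
    x = astensor(x)
    ph, pw = pool
    B, C, H, W = x.shape
    Ho, Wo = H // ph, W // pw
    if Ho < 1 or Wo < 1:
        raise ValueError(f"pool {pool} larger than input plane ({H}, {W})")
    trimmed = x.data[:, :, : Ho * ph, : Wo * pw]
    out_data = trimmed.reshape(B, C, Ho, ph, Wo, pw).mean(axis=(3, 5))
    out = _node(out_data, (x,))

    def backward(g):
        gx = np.zeros((B, C, H, W))
        spread = np.repeat(np.repeat(g, ph, axis=2), pw, axis=3) / (ph * pw)
        gx[:, :, : Ho * ph, : Wo * pw] = spread
        x._accum(gx)

    out._backward = backward
    return out


# -------------------------------------------------------------------- optimizer
class Adam:
    """Adaptive-moment gradient descent over a list of leaf tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 0.02,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
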