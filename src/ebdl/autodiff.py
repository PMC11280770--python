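"""Minimal reverse-mode automatic differentiation on numpy arrays.

The trainable parts of the framework — sub-band filter locations/scales, the
shared convolutional encoder, and the class proxies — are all optimized by
gradient descent through one scalar loss.  This module provides the tape:
a :class:`Tensor` wrapping an ``ndarray`` plus the closed set of operations
the model graph needs (broadcast arithmetic, ``exp``/``log``/``abs``/powers,
batched ``matmul``, convolution via im2col, pooling, reductions, indexing).

Everything is float64.  The engine is deliberately small: no graph
optimization, no in-place views, stride-1 convolutions only.  Gradients are
accumulated by topological sweep from the output, exactly like the standard
define-by-run tape engines.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (the reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph: value, gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph plumbing ------------------------------------------------------

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)

            def _bw():
                backward(out.grad)

            out._backward = _bw
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS: graphs from long training loops overflow recursion
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                topo.append(stack_.pop())
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent):
        """Constant exponent only.  Integer exponents accept negative bases."""
        if isinstance(exponent, Tensor):
            raise TypeError("tensor exponents are not supported")
        if float(exponent) == int(exponent):
            exponent = int(exponent)
        out_data = np.power(self.data, exponent)

        def bw(g):
            self._accum(g * exponent * np.power(self.data, exponent - 1))

        return self._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        def bw(g):
            self._accum(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    # -- reductions / shaping ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            self._accum(g.reshape(self.shape))

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), bw)

    # -- linear algebra ------------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = Tensor.as_tensor(other)

        def bw(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), bw)

    __matmul__ = matmul

    # -- convolution / pooling (stride 1, square padding) --------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None,
               padding: int = 0):
        """2-D cross-correlation.  self: (N,C,H,W); weight: (O,C,kh,kw)."""
        x, w = self.data, weight.data
        n, c, h, wdt = x.shape
        o, _, kh, kw = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        ho, wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,Ho,Wo,kh,kw), a view
        # one materialized im2col copy, shared by forward and both backward products
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * kh * kw)
        wmat = w.reshape(o, -1)
        out = cols @ wmat.T
        if bias is not None:
            out = out + bias.data
        out = np.ascontiguousarray(out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2))
        parents = [self, weight] if bias is None else [self, weight, bias]

        def bw(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
            weight._accum((g2.T @ cols).reshape(w.shape))
            if bias is not None:
                bias._accum(g2.sum(axis=0))
            if self.requires_grad:
                # gx[n,c,ho+i,wo+j] += g[n,o,ho,wo] * w[o,c,i,j]
                gcols = (g2 @ wmat).reshape(n, ho, wo, c, kh, kw)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + ho, j:j + wo] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                self._accum(gxp)

        return self._make(out, parents, bw)

    def avg_pool2d(self, k: int = 2):
        """Non-overlapping k x k average pooling on (N,C,H,W)."""
        n, c, h, w = self.shape
        if h % k or w % k:
            raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {k}")
        out = self.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

        def bw(g):
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            self._accum(gx)

        return self._make(out, (self,), bw)


class Parameter(Tensor):
    """A trainable tensor (requires_grad on by default)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis, with gradient routing to each input."""
    tensors = list(tensors)
    out_data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)

        def _bw():
            slices = np.split(out.grad, len(tensors), axis=axis)
            for t, g in zip(tensors, slices):
                t._accum(np.squeeze(g, axis=axis))

        out._backward = _bw
    return out
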