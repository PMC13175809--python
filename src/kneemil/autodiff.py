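"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tensor engine: every :class:`Tensor` wraps an
``ndarray``, records its parents and a closure that accumulates gradients,
and ``backward`` walks the graph in reverse topological order.  It powers
the slice-encoder / attention / fusion model, the training loop, and the
projected-gradient solver, all of which need gradients of scalar
objectives with respect to parameter arrays.

Only the operations the package actually uses are implemented; each op's
backward closure handles numpy broadcasting by summing gradients back to
the operand's shape.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "conv2d", "dropout", "softmax", "relu",
           "sigmoid", "tanh", "exp", "log", "clip", "matmul"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64 if arr.dtype == np.int64 else np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                               other.data.shape))
        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = _bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along an axis; ties share the gradient equally."""
        m = self.data.max(axis=axis, keepdims=True)
        out = Tensor(m if keepdims else np.squeeze(m, axis=axis), _prev=(self,))
        mask = (self.data == m)
        counts = mask.sum(axis=axis, keepdims=True)

        def _bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask * (g / counts))
        out._backward = _bw
        return out

    def item(self) -> float:
        return float(self.data)


# -- elementwise functions ---------------------------------------------------

def exp(x: Tensor) -> Tensor:
    out = Tensor(np.exp(x.data), _prev=(x,))
    out._backward = lambda g: x._accumulate(g * out.data)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), _prev=(x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def tanh(x: Tensor) -> Tensor:
    out = Tensor(np.tanh(x.data), _prev=(x,))
    out._backward = lambda g: x._accumulate(g * (1.0 - out.data ** 2))
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _prev=(x,))
    out._backward = lambda g: x._accumulate(g * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    out = Tensor(1.0 / (1.0 + np.exp(-x.data)), _prev=(x,))
    out._backward = lambda g: x._accumulate(g * out.data * (1.0 - out.data))
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside [lo, hi]."""
    out = Tensor(np.clip(x.data, lo, hi), _prev=(x,))
    inside = (x.data >= lo) & (x.data <= hi)
    out._backward = lambda g: x._accumulate(g * inside)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, shift-invariant
    e = exp(x - shift)
    return e / e.sum(axis=axis, keepdims=True)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a = Tensor._lift(a)
    b = Tensor._lift(b)
    out = Tensor(a.data @ b.data, _prev=(a, b))

    def _bw(g):
        A, B = a.data, b.data
        if a.requires_grad or a._prev:
            if B.ndim == 1:                      # (..., m) @ (m,) -> (...)
                ga = np.expand_dims(g, -1) * B
            elif A.ndim == 1:                    # (m,) @ (..., m, n) -> (..., n)
                ga = np.einsum("...mn,...n->m", B, g, optimize=True)
            else:
                ga = g @ np.swapaxes(B, -1, -2)
            a._accumulate(_unbroadcast(ga, A.shape))
        if b.requires_grad or b._prev:
            if B.ndim == 1:
                gb = np.einsum("...m,...->m", A, g, optimize=True)
            elif A.ndim == 1:
                gb = np.einsum("m,...n->...mn", A, g, optimize=True)
            else:
                gb = np.swapaxes(A, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, B.shape))
    out._backward = _bw
    return out


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])
    out._backward = _bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(keep)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution: x (N,C,H,W), weight (O,C,k,k), bias (O,)."""
    n, c, h, w = x.data.shape
    oc, _, k, _ = weight.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,k,k)
    ho, wo = windows.shape[2], windows.shape[3]
    out_data = np.einsum("nchwij,ocij->nohw", windows, weight.data,
                         optimize=True) + bias.data[None, :, None, None]
    out = Tensor(out_data, _prev=(x, weight, bias))

    def _bw(g):
        if weight.requires_grad:
            weight._accumulate(np.einsum("nchwij,nohw->ocij", windows, g,
                                         optimize=True))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            gxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    contrib = np.einsum("nohw,oc->nchw", g,
                                        weight.data[:, :, ki, kj], optimize=True)
                    gxp[:, :, ki:ki + stride * ho:stride,
                        kj:kj + stride * wo:stride] += contrib
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)
    out._backward = _bw
    return out
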