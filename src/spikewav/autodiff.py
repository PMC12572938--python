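"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The forward pass of a spiking network is piecewise constant (Heaviside
spikes), so gradient-based training needs a surrogate relaxation in the
backward pass only.  No autodiff framework is available in this
environment, so this module provides a small tape-based engine with
exactly the operations the network needs: broadcast arithmetic, batched
matmul, im2col convolution, reductions, shape ops, and a spike op whose
forward is the exact Heaviside and whose backward is the derivative of a
sharpened sigmoid.

All arrays are float32 by default (float64 works too; dtypes follow the
inputs).  Graphs are built eagerly; ``Tensor.backward()`` runs a
topological sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "spike", "sigmoid", "conv2d", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference passes)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


_SCALARS = (int, float)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    # Python scalars take a fast path that avoids wrapping them in float64
    # 0-d arrays (which would silently upcast float32 graphs) and keeps the
    # tape binary-input-free where possible.
    def __add__(self, other):
        if isinstance(other, _SCALARS):
            return Tensor._make(self.data + other, (self,), lambda g: (g,))
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        if isinstance(other, _SCALARS):
            return Tensor._make(self.data - other, (self,), lambda g: (g,))
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, _SCALARS):
            return Tensor._make(other - self.data, (self,), lambda g: (-g,))
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, _SCALARS):
            return Tensor._make(self.data * other, (self,), lambda g: (g * other,))
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, _SCALARS):
            return self * (1.0 / other)
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return Tensor._make(np.log(self.data), (self,), backward)

    def abs(self):
        def backward(g):
            return (g * np.sign(self.data),)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            return (g * 0.5 / out_data,)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            return (g.reshape(orig),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis; backward scatters into zeros."""
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def backward(g):
            out = np.zeros_like(self.data)
            out[idx] = g
            return (out,)

        return Tensor._make(self.data[idx], (self,), backward)

    def strided2(self, row_off: int, col_off: int):
        """Every-other-element slice ``x[..., row_off::2, col_off::2]``."""
        idx = (Ellipsis, slice(row_off, None, 2), slice(col_off, None, 2))

        def backward(g):
            out = np.zeros_like(self.data)
            out[idx] = g
            return (out,)

        return Tensor._make(self.data[idx], (self,), backward)

    def expand0(self, n: int):
        """Broadcast a new leading axis of length ``n`` (no copy)."""
        out_data = np.broadcast_to(self.data[None], (n,) + tuple(self.shape))

        def backward(g):
            return (g.sum(axis=0),)

        return Tensor._make(out_data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tensors, backward)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        return (g * out_data * (1.0 - out_data),)

    return Tensor._make(out_data, (x,), backward)


def spike(u: Tensor, alpha: float = 4.0) -> Tensor:
    """Heaviside forward (1 iff u >= 0), sigmoid-derivative surrogate backward.

    The backward kernel is d/du sigmoid(alpha*u) = alpha*s*(1-s); at u=0 with
    alpha=4 it equals 1.
    """
    u = as_tensor(u)
    out_data = (u.data >= 0).astype(u.data.dtype)

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-alpha * u.data))
        return (g * alpha * s * (1.0 - s),)

    return Tensor._make(out_data, (u,), backward)


def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(B,C,Hp,Wp) padded input -> (C*k*k, B*ho*wo) patch matrix (one copy)."""
    b, c, _, _ = xp.shape
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(c, k, k, b, ho, wo),
        strides=(s1, s2, s3, s0, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(cols).reshape(c * k * k, b * ho * wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 1) -> Tensor:
    """2D convolution, NCHW layout; w is (F, C, k, k), bias (F,).

    Implemented as im2col + a single large GEMM; the column matrix is
    shared with the backward pass (weight gradient and col2im scatter).
    """
    x, w = as_tensor(x), as_tensor(w)
    bsz, c, h, wid = x.shape
    f, _, k, _ = w.shape
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wid + 2 * padding - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, k, stride, ho, wo)  # (C*k*k, B*ho*wo)
    wmat = w.data.reshape(f, c * k * k)
    out_data = (wmat @ cols).reshape(f, bsz, ho, wo).transpose(1, 0, 2, 3)
    if b is not None:
        out_data = out_data + b.data.reshape(1, f, 1, 1)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(f, -1)
        gw = (gmat @ cols.T).reshape(w.shape)
        gcols = (wmat.T @ gmat).reshape(c, k, k, bsz, ho, wo)
        gxp = np.zeros_like(xp)
        gv = gxp.transpose(1, 0, 2, 3)  # (C, B, Hp, Wp) view for the scatter
        for i in range(k):
            for j in range(k):
                gv[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gcols[
                    :, i, j
                ]
        gx = gxp[:, :, padding : padding + h, padding : padding + wid]
        if b is not None:
            gb = g.sum(axis=(0, 2, 3))
            return gx, gw, gb
        return gx, gw

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)
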