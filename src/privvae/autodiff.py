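"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides the small set of differentiable operations the
variational autoencoder and its multi-scale structural-similarity loss are
built from: broadcasting arithmetic, matmul, reductions, reshapes, 2-D
convolution / transposed convolution (im2col based), nearest-neighbour
upsampling and elementwise nonlinearities.  Gradients are accumulated by a
tape of `Tensor` nodes and released eagerly once consumed.

The engine is dtype-preserving: float32 is used for training speed, float64
for finite-difference gradient checks in the test-suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "upsample_nearest2x",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this (typically scalar) node."""
        if not self.requires_grad:
            raise RuntimeError("called backward() on a non-differentiable Tensor")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topo sort; graphs can be deep
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node is not self and node._parents:
                node.grad = None  # free intermediate grads eagerly

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=False)
        else:
            self.grad = self.grad + grad

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out_data = self.data**e

        def bwd(g):
            self._accum(g * e * self.data ** (e - 1.0))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    # -- elementwise functions -----------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / out_data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bwd(g):
            self._accum(np.where(mask, g, slope * g))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def clamp_min(self, lo: float) -> "Tensor":
        """max(x, lo); gradient flows only where x > lo."""
        mask = self.data > lo
        out_data = np.where(mask, self.data, lo)

        def bwd(g):
            self._accum(np.where(mask, g, 0.0))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- reductions & reshapes -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(a % self.ndim for a in axes))
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bwd)

    def slice_axis(self, axis: int, start: int, stop: int) -> "Tensor":
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, stop)
        idx = tuple(idx)

        def bwd(g):
            full = np.zeros(self.shape, dtype=g.dtype)
            full[idx] = g
            self._accum(full)

        return Tensor(self.data[idx], _parents=(self,), _backward=bwd)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bwd)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    """Concatenate tensors along `axis`."""
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=bwd)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    x: (N, C, H, W); w: (F, C, kh, kw); b: (F,).  Implemented as im2col +
    matmul; the column matrix is kept alive for the backward pass.
    """
    N, C, H, W = x.shape
    F, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    view = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # (N, C, Ho, Wo, kh, kw) -> (N*Ho*Wo, C*kh*kw)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw
    )
    wmat = w.data.reshape(F, -1)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out_data = out.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)

    def bwd(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, F)
        if w.requires_grad:
            w._accum((gm.T @ cols).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(gm.sum(axis=0))
        if x.requires_grad:
            dcols = gm @ wmat  # (N*Ho*Wo, C*kh*kw)
            dview = dcols.reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros(
                (N, C, H + 2 * p, W + 2 * p), dtype=x.dtype
            )
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dview[
                        ..., i, j
                    ]
            x._accum(dxp[:, :, p : p + H, p : p + W] if p else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, _parents=parents, _backward=bwd)


def conv_transpose2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 2,
    padding: int = 0,
    out_hw: tuple[int, int] | None = None,
) -> Tensor:
    """Transposed 2-D convolution, NCHW layout.

    x: (N, C, H, W); w: (C, F, kh, kw).  The full output has spatial size
    (H-1)*stride + k; `out_hw` crops a window starting at `padding` (this
    subsumes PyTorch's padding/output_padding bookkeeping).
    """
    N, C, H, W = x.shape
    Cw, F, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"conv_transpose2d channel mismatch: input {C}, weight {Cw}")
    s, p = stride, padding
    Hf, Wf = (H - 1) * s + kh, (W - 1) * s + kw
    if out_hw is None:
        out_hw = (Hf - 2 * p, Wf - 2 * p)
    Ho, Wo = out_hw
    if p + Ho > Hf or p + Wo > Wf:
        raise ValueError("requested output window exceeds full transposed-conv size")

    # (N,H,W,F,kh,kw): contribution of every input position through the kernel
    tmp = np.tensordot(x.data, w.data, axes=([1], [0]))
    full = np.zeros((N, F, Hf, Wf), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            full[:, :, i : i + s * H : s, j : j + s * W : s] += tmp[
                :, :, :, :, i, j
            ].transpose(0, 3, 1, 2)
    out_data = full[:, :, p : p + Ho, p : p + Wo]
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def bwd(g):
        gfull = np.zeros((N, F, Hf, Wf), dtype=g.dtype)
        gfull[:, :, p : p + Ho, p : p + Wo] = g
        # gather: dtmp[n,h,w,f,i,j] = gfull[n,f,h*s+i,w*s+j]
        dtmp = np.empty((N, H, W, F, kh, kw), dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                dtmp[:, :, :, :, i, j] = gfull[
                    :, :, i : i + s * H : s, j : j + s * W : s
                ].transpose(0, 2, 3, 1)
        if x.requires_grad:
            dx = np.tensordot(dtmp, w.data, axes=([3, 4, 5], [1, 2, 3]))
            x._accum(dx.transpose(0, 3, 1, 2))
        if w.requires_grad:
            dw = np.tensordot(x.data, dtmp, axes=([0, 2, 3], [0, 1, 2]))
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, _parents=parents, _backward=bwd)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling, NCHW."""
    N, C, H, W = x.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor(out_data, _parents=(x,), _backward=bwd)
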