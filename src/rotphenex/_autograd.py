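"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it; :meth:`Tensor.backward` accumulates gradients by reverse topological
traversal.  The op set is exactly what the detection network and its losses
need: broadcasting arithmetic, exp/log/sigmoid/atan, reductions, slicing,
concatenation, nearest-neighbor upsampling and a grouped 2-D convolution
implemented with ``sliding_window_view`` + ``einsum``.

The module also exposes a tiny dispatch layer (:func:`exp`, :func:`log`,
:func:`sigmoid`, ...) that falls back to plain NumPy when given an ndarray,
so loss functions can be written once and evaluated either eagerly (for the
public metric-style API) or under autodiff (for training).
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

ArrayLike = Union["Tensor", np.ndarray, float, int]

__all__ = [
    "Tensor",
    "exp", "log", "sigmoid", "atan", "sqrt", "relu", "absolute", "silu",
    "maximum", "minimum", "clip_min",
    "tsum", "tmean", "concatenate", "stack",
    "conv2d", "upsample_nearest", "asdata",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum out broadcast dimensions so ``grad`` matches ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operator
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(x: ArrayLike) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other: ArrayLike) -> "Tensor":
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return self._coerce(other) + (-self)

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(self.data ** p, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


# -- elementwise functions (dispatch: Tensor or ndarray) ----------------------


def asdata(x: ArrayLike) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _unary(x: ArrayLike, fwd, dfx):
    if not isinstance(x, Tensor):
        return fwd(np.asarray(x, dtype=float))
    y = fwd(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * dfx(x.data, y))

    return Tensor._make(y, (x,), backward)


def exp(x: ArrayLike):
    return _unary(x, np.exp, lambda d, y: y)


def log(x: ArrayLike):
    return _unary(x, np.log, lambda d, y: 1.0 / d)


def sqrt(x: ArrayLike):
    return _unary(x, np.sqrt, lambda d, y: 0.5 / np.maximum(y, 1e-300))


def sigmoid(x: ArrayLike):
    def fwd(d):
        out = np.empty_like(d)
        pos = d >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
        e = np.exp(d[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    return _unary(x, fwd, lambda d, y: y * (1.0 - y))


def atan(x: ArrayLike):
    return _unary(x, np.arctan, lambda d, y: 1.0 / (1.0 + d * d))


def relu(x: ArrayLike):
    return _unary(x, lambda d: np.maximum(d, 0.0), lambda d, y: (d > 0).astype(float))


def absolute(x: ArrayLike):
    return _unary(x, np.abs, lambda d, y: np.sign(d))


def silu(x: ArrayLike):
    return x * sigmoid(x)


def _binary_minmax(a: ArrayLike, b: ArrayLike, op):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return op(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    ta, tb = Tensor._coerce(a), Tensor._coerce(b)
    out_data = op(ta.data, tb.data)
    a_wins = (out_data == ta.data)

    def backward(g):
        if ta.requires_grad:
            ta._accum(_unbroadcast(g * a_wins, ta.shape))
        if tb.requires_grad:
            tb._accum(_unbroadcast(g * (~a_wins), tb.shape))

    return Tensor._make(out_data, (ta, tb), backward)


def maximum(a: ArrayLike, b: ArrayLike):
    return _binary_minmax(a, b, np.maximum)


def minimum(a: ArrayLike, b: ArrayLike):
    return _binary_minmax(a, b, np.minimum)


def clip_min(x: ArrayLike, lo: float):
    return maximum(x, lo)


def tsum(x: ArrayLike, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def tmean(x: ArrayLike, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)


def concatenate(tensors: Sequence[ArrayLike], axis: int = 0):
    if not any(isinstance(t, Tensor) for t in tensors):
        return np.concatenate(tensors, axis=axis)
    ts = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in ts], axis=axis), tuple(ts), backward
    )


def stack(tensors: Sequence[ArrayLike], axis: int = 0):
    ts = [t.reshape(*t.shape[:axis], 1, *t.shape[axis:]) if isinstance(t, Tensor)
          else np.expand_dims(t, axis) for t in tensors]
    return concatenate(ts, axis=axis)


# -- structured ops ----------------------------------------------------------


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbor upsampling of (B, C, H, W) by an integer factor."""
    def fwd(d):
        return d.repeat(factor, axis=2).repeat(factor, axis=3)

    if not isinstance(x, Tensor):
        return fwd(x)
    B, C, H, W = x.shape

    def backward(g):
        if x.requires_grad:
            gg = g.reshape(B, C, H, factor, W, factor).sum(axis=(3, 5))
            x._accum(gg)

    return Tensor._make(fwd(x.data), (x,), backward)


def _patches(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B, C, Ho, Wo, kh, kw) view of the padded input."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(
    x: ArrayLike,
    weight: ArrayLike,
    bias: Optional[ArrayLike] = None,
    stride: int = 1,
    padding: Union[int, tuple[int, int]] = 0,
    groups: int = 1,
):
    """Grouped 2-D convolution (cross-correlation) on (B, C, H, W).

    ``weight`` has shape (Cout, Cin/groups, kh, kw); ``padding`` may be a
    single int or an asymmetric (ph, pw) pair.
    """
    tx = Tensor._coerce(x)
    tw = Tensor._coerce(weight)
    tb = Tensor._coerce(bias) if bias is not None else None
    B, Cin, H, W = tx.shape
    Cout, cin_g, kh, kw = tw.shape
    g = groups
    assert Cin % g == 0 and Cout % g == 0 and cin_g == Cin // g
    ph, pw = (padding, padding) if isinstance(padding, int) else padding

    xp = np.pad(tx.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    pat = _patches(xp, kh, kw, stride)  # (B, Cin, Ho, Wo, kh, kw)
    Ho, Wo = pat.shape[2], pat.shape[3]
    pat_g = pat.reshape(B, g, Cin // g, Ho, Wo, kh, kw)
    w_g = tw.data.reshape(g, Cout // g, Cin // g, kh, kw)
    out = np.einsum("bgchwkl,gockl->bgohw", pat_g, w_g, optimize=True)
    out = out.reshape(B, Cout, Ho, Wo)
    if tb is not None:
        out = out + tb.data.reshape(1, Cout, 1, 1)

    parents = (tx, tw) if tb is None else (tx, tw, tb)

    def backward(grad):
        grad_g = grad.reshape(B, g, Cout // g, Ho, Wo)
        if tw.requires_grad:
            dw = np.einsum("bgohw,bgchwkl->gockl", grad_g, pat_g, optimize=True)
            tw._accum(dw.reshape(Cout, Cin // g, kh, kw))
        if tb is not None and tb.requires_grad:
            tb._accum(grad.sum(axis=(0, 2, 3)))
        if tx.requires_grad:
            dxp = np.zeros_like(xp)
            dxp_g = dxp.reshape(B, g, Cin // g, xp.shape[2], xp.shape[3])
            for k in range(kh):
                for l in range(kw):
                    contrib = np.einsum(
                        "bgohw,goc->bgchw", grad_g, w_g[:, :, :, k, l], optimize=True
                    )
                    dxp_g[:, :, :, k : k + Ho * stride : stride,
                          l : l + Wo * stride : stride] += contrib
            dx = dxp[:, :, ph : ph + H, pw : pw + W]
            tx._accum(dx)

    return Tensor._make(out, parents, backward)
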