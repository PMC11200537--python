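"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every operation returns a new
:class:`Tensor` holding the result plus a closure that scatters the incoming
gradient to its parents.  Gradients are accumulated by a single reverse
topological sweep from a scalar loss.

Only the operations the segmentation network needs are provided: elementwise
arithmetic, reductions, reshaping/slicing/concatenation, dense and depth-wise
3D convolutions (stride-1 "same", non-overlapping stride-2 down/up sampling),
and separable trilinear resampling.  Feature maps are laid out channels-last,
(N, D, H, W, C), so the convolutions reduce to cache-friendly GEMMs over
shifted views.  Tensors keep the floating dtype of the data they are built
from (network parameters are float32 for speed; feeding float64 inputs gives
a float64 graph), and correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "concat",
    "conv3d",
    "conv_down2",
    "conv_up2",
    "dw_conv3",
    "dw_conv_axis",
    "softmax",
    "transpose",
    "upsample_linear",
]


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff ------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for long networks
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        if _is_scalar_const(other):
            return add(self, -float(other))
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if _is_scalar_const(other):
            return mul(self, 1.0 / float(other))
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else _axis_size(self.data.shape, axis)
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _axis_size(shape, axis) -> int:
    if isinstance(axis, int):
        axis = (axis,)
    return int(np.prod([shape[a] for a in axis]))


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        if g.dtype != t.data.dtype:  # keep each subgraph in its forward dtype
            g = g.astype(t.data.dtype)
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


# -- elementwise -------------------------------------------------------

def _is_scalar_const(x) -> bool:
    return not isinstance(x, Tensor) and np.ndim(x) == 0


def add(a, b) -> Tensor:
    # python-scalar operands stay weakly typed so they never upcast a
    # float32 graph (NEP 50 treats 0-d arrays as strong)
    if _is_scalar_const(a):
        a, b = b, a
    if _is_scalar_const(b):
        a = as_tensor(a)
        c = float(b)
        out_data = a.data + c

        def backward_s():
            _accum(a, out.grad)

        out = _make(out_data, (a,), backward_s)
        return out
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward():
        _accum(a, _unbroadcast(out.grad, a.data.shape))
        _accum(b, _unbroadcast(out.grad, b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def mul(a, b) -> Tensor:
    if _is_scalar_const(a):
        a, b = b, a
    if _is_scalar_const(b):
        a = as_tensor(a)
        c = float(b)
        out_data = a.data * c

        def backward_s():
            _accum(a, out.grad * c)

        out = _make(out_data, (a,), backward_s)
        return out
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward():
        _accum(a, _unbroadcast(out.grad * b.data, a.data.shape))
        _accum(b, _unbroadcast(out.grad * a.data, b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward():
        _accum(a, out.grad * p * a.data ** (p - 1.0))

    out = _make(out_data, (a,), backward)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward():
        _accum(a, out.grad / a.data)

    out = _make(out_data, (a,), backward)
    return out


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward():
        _accum(a, out.grad * out_data)

    out = _make(out_data, (a,), backward)
    return out


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp; gradient passes only where the input is strictly interior."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    pass_mask = (a.data > lo) & (a.data < hi)

    def backward():
        _accum(a, out.grad * pass_mask)

    out = _make(out_data, (a,), backward)
    return out


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    out_data = np.where(pos, a.data, slope * a.data)

    def backward():
        _accum(a, np.where(pos, out.grad, slope * out.grad))

    out = _make(out_data, (a,), backward)
    return out


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    from scipy.special import erf

    a = as_tensor(a)
    cdf = 0.5 * (1.0 + erf(a.data * _INV_SQRT2))
    out_data = a.data * cdf

    def backward():
        pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data * a.data)
        _accum(a, out.grad * (cdf + a.data * pdf))

    out = _make(out_data, (a,), backward)
    return out


# -- reductions / shaping ---------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward():
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    out = _make(out_data, (a,), backward)
    return out


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward():
        _accum(a, out.grad.reshape(a.data.shape))

    out = _make(out_data, (a,), backward)
    return out


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    out_data = np.ascontiguousarray(a.data.transpose(axes))
    inv = tuple(np.argsort(axes))

    def backward():
        _accum(a, np.ascontiguousarray(out.grad.transpose(inv)))

    out = _make(out_data, (a,), backward)
    return out


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]

    def backward():
        g = np.zeros_like(a.data)
        g[idx] = out.grad  # basic slicing only: index sets are disjoint
        _accum(a, g)

    out = _make(out_data, (a,), backward)
    return out


def concat(tensors: Sequence, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, out.grad[tuple(sl)])

    out = _make(out_data, tensors, backward)
    return out


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (fused primitive)."""
    a = as_tensor(a)
    e = np.exp(a.data - a.data.max(axis=axis, keepdims=True))
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward():
        g = out.grad
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        _accum(a, out_data * (g - dot))

    out = _make(out_data, (a,), backward)
    return out


def instance_norm(x, gamma, beta, eps: float = 1e-5, axes=(1, 2, 3)) -> Tensor:
    """Fused per-sample, per-channel normalization with learnable affine.

    Statistics are taken over ``axes`` (the spatial axes for channels-last
    maps); ``gamma``/``beta`` broadcast over the normalized result.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = gamma.data * xhat + beta.data

    def backward():
        g = out.grad
        if gamma.requires_grad:
            _accum(gamma, _unbroadcast(g * xhat, gamma.data.shape))
            _accum(beta, _unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gh = g * gamma.data
            m1 = gh.mean(axis=axes, keepdims=True)
            m2 = (gh * xhat).mean(axis=axes, keepdims=True)
            _accum(x, inv * (gh - m1 - xhat * m2))

    out = _make(out_data, (x, gamma, beta), backward)
    return out


def select_class(P, labels: np.ndarray) -> Tensor:
    """Gather per-voxel probabilities of the true class.

    ``P``: channels-first (K, *spatial*); ``labels``: integer (*spatial*).
    """
    P = as_tensor(P)
    labels = np.asarray(labels)
    idx = (labels.reshape(-1), np.arange(labels.size))
    flat = P.data.reshape(P.data.shape[0], -1)
    out_data = flat[idx].reshape(labels.shape)

    def backward():
        g = np.zeros_like(flat)
        g[idx] = out.grad.reshape(-1)
        _accum(P, g.reshape(P.data.shape))

    out = _make(out_data, (P,), backward)
    return out


# -- convolutions (channels-last) --------------------------------------

def _pad_spatial(x: np.ndarray, pad) -> np.ndarray:
    spec = [(0, 0)] + [(p, p) for p in pad] + [(0, 0)]
    return np.pad(x, spec)


def _conv3d_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 "same" cross-correlation by shift-accumulate GEMMs.

    ``x``: (N, D, H, W, C); ``w``: (kd, kh, kw, C, O), odd kernel extents.
    """
    kd, kh, kw = w.shape[:3]
    if kd == kh == kw == 1:
        return x @ w[0, 0, 0]
    N, D, H, W, _ = x.shape
    xp = _pad_spatial(x, ((kd - 1) // 2, (kh - 1) // 2, (kw - 1) // 2))
    out = np.zeros((N, D, H, W, w.shape[4]), dtype=x.dtype)
    for dz in range(kd):
        for dy in range(kh):
            for dx in range(kw):
                out += xp[:, dz : dz + D, dy : dy + H, dx : dx + W, :] @ w[dz, dy, dx]
    return out


def conv3d(x, w, b=None) -> Tensor:
    """3D convolution, stride 1, "same" zero padding, odd kernel extents.

    ``x``: (N, D, H, W, C); ``w``: (kd, kh, kw, C, O); ``b``: (O,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    kd, kh, kw = w.data.shape[:3]
    if kd % 2 == 0 or kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv3d requires odd kernel extents")
    if x.data.shape[-1] != w.data.shape[3]:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[-1]}, kernel expects "
            f"{w.data.shape[3]}"
        )
    N, D, H, W, _ = x.data.shape
    pointwise = kd == kh == kw == 1
    if pointwise:
        xp = None
        out_data = x.data @ w.data[0, 0, 0]
    else:
        pad = ((kd - 1) // 2, (kh - 1) // 2, (kw - 1) // 2)
        xp = _pad_spatial(x.data, pad)  # cached for the weight gradient
        out_data = np.zeros(x.data.shape[:4] + (w.data.shape[4],), dtype=x.data.dtype)
        for dz in range(kd):
            for dy in range(kh):
                for dx in range(kw):
                    out_data += (
                        xp[:, dz : dz + D, dy : dy + H, dx : dx + W, :] @ w.data[dz, dy, dx]
                    )
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data

    def backward():
        g = out.grad
        if x.requires_grad:
            w_t = np.ascontiguousarray(
                np.flip(w.data, (0, 1, 2)).transpose(0, 1, 2, 4, 3)
            )
            _accum(x, _conv3d_raw(g, w_t))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            if pointwise:
                gw[0, 0, 0] = np.tensordot(x.data, g, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
            else:
                for dz in range(kd):
                    for dy in range(kh):
                        for dx in range(kw):
                            sl = xp[:, dz : dz + D, dy : dy + H, dx : dx + W, :]
                            gw[dz, dy, dx] = np.tensordot(
                                sl, g, axes=([0, 1, 2, 3], [0, 1, 2, 3])
                            )
            _accum(w, gw)
        if b is not None:
            _accum(b, g.sum(axis=(0, 1, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents, backward)
    return out


def conv_down2(x, w, b=None) -> Tensor:
    """Non-overlapping 2x2x2 stride-2 convolution (downsampling by 2).

    ``w``: (2, 2, 2, C, O); spatial extents of ``x`` must be even.
    """
    x, w = as_tensor(x), as_tensor(w)
    N, D, H, W, C = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError("conv_down2 requires even spatial extents")
    xr = x.data.reshape(N, D // 2, 2, H // 2, 2, W // 2, 2, C)
    out_data = np.tensordot(xr, w.data, axes=([2, 4, 6, 7], [0, 1, 2, 3]))
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data

    def backward():
        g = out.grad  # (N, D/2, H/2, W/2, O)
        if x.requires_grad:
            gx = np.tensordot(g, w.data, axes=([4], [4]))  # N,d,h,w,2,2,2,C
            gx = gx.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(N, D, H, W, C)
            _accum(x, np.ascontiguousarray(gx))
        if w.requires_grad:
            gw = np.tensordot(xr, g, axes=([0, 1, 3, 5], [0, 1, 2, 3]))
            _accum(w, gw)  # (2,2,2,C,O)
        if b is not None:
            _accum(b, g.sum(axis=(0, 1, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents, backward)
    return out


def conv_up2(x, w, b=None) -> Tensor:
    """Strided deconvolution: 2x2x2 transposed convolution, stride 2.

    ``w``: (C, 2, 2, 2, O); output spatial extents are doubled.
    """
    x, w = as_tensor(x), as_tensor(w)
    N, D, H, W, C = x.data.shape
    O = w.data.shape[4]
    t = np.tensordot(x.data, w.data, axes=([4], [0]))  # N,D,H,W,2,2,2,O
    out_data = np.ascontiguousarray(
        t.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(N, 2 * D, 2 * H, 2 * W, O)
    )
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data

    def backward():
        g = out.grad.reshape(N, D, 2, H, 2, W, 2, O)
        if x.requires_grad:
            gx = np.tensordot(g, w.data, axes=([2, 4, 6, 7], [1, 2, 3, 4]))
            _accum(x, np.ascontiguousarray(gx))
        if w.requires_grad:
            gw = np.tensordot(x.data, g, axes=([0, 1, 2, 3], [0, 1, 3, 5]))
            _accum(w, gw)  # (C,2,2,2,O)
        if b is not None:
            _accum(b, out.grad.sum(axis=(0, 1, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents, backward)
    return out


def _dw_axis_raw(x: np.ndarray, w: np.ndarray, axis: int) -> np.ndarray:
    """Depth-wise stride-1 1D cross-correlation along one spatial axis."""
    k = w.shape[1]
    p = (k - 1) // 2
    padspec = [(0, 0)] * x.ndim
    padspec[axis] = (p, p)
    xp = np.pad(x, padspec)
    out = np.zeros_like(x)
    sl = [slice(None)] * x.ndim
    for d in range(k):
        sl[axis] = slice(d, d + x.shape[axis])
        out += xp[tuple(sl)] * w[:, d]
    return out


def dw_conv_axis(x, w, axis: int) -> Tensor:
    """Depth-wise strip convolution along spatial ``axis`` in {1, 2, 3}.

    ``w``: (C, k) with k odd — one 1D kernel per channel, "same" padding.
    """
    x, w = as_tensor(x), as_tensor(w)
    if axis not in (1, 2, 3):
        raise ValueError("axis must be a spatial axis (1, 2 or 3)")
    if w.data.shape[1] % 2 == 0:
        raise ValueError("strip kernel extent must be odd")
    out_data = _dw_axis_raw(x.data, w.data, axis)

    def backward():
        g = out.grad
        if x.requires_grad:
            _accum(x, _dw_axis_raw(g, w.data[:, ::-1], axis))
        if w.requires_grad:
            k = w.data.shape[1]
            p = (k - 1) // 2
            padspec = [(0, 0)] * x.data.ndim
            padspec[axis] = (p, p)
            xp = np.pad(x.data, padspec)
            gw = np.empty_like(w.data)
            sl = [slice(None)] * x.data.ndim
            red = tuple(i for i in range(x.data.ndim) if i != x.data.ndim - 1)
            for d in range(k):
                sl[axis] = slice(d, d + x.data.shape[axis])
                gw[:, d] = (xp[tuple(sl)] * g).sum(axis=red)
            _accum(w, gw)

    out = _make(out_data, (x, w), backward)
    return out


def _dw3_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Depth-wise 3D cross-correlation; ``w``: (C, kd, kh, kw)."""
    kd, kh, kw = w.shape[1:]
    N, D, H, W, C = x.shape
    xp = _pad_spatial(x, ((kd - 1) // 2, (kh - 1) // 2, (kw - 1) // 2))
    out = np.zeros_like(x)
    for dz in range(kd):
        for dy in range(kh):
            for dx in range(kw):
                out += xp[:, dz : dz + D, dy : dy + H, dx : dx + W, :] * w[:, dz, dy, dx]
    return out


def dw_conv3(x, w) -> Tensor:
    """Depth-wise 3D convolution, "same" padding; ``w``: (C, kd, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    if any(k % 2 == 0 for k in w.data.shape[1:]):
        raise ValueError("depth-wise kernel extents must be odd")
    out_data = _dw3_raw(x.data, w.data)

    def backward():
        g = out.grad
        if x.requires_grad:
            _accum(x, _dw3_raw(g, np.flip(w.data, (1, 2, 3))))
        if w.requires_grad:
            kd, kh, kw = w.data.shape[1:]
            N, D, H, W, C = x.data.shape
            xp = _pad_spatial(x.data, ((kd - 1) // 2, (kh - 1) // 2, (kw - 1) // 2))
            gw = np.empty_like(w.data)
            for dz in range(kd):
                for dy in range(kh):
                    for dx in range(kw):
                        sl = xp[:, dz : dz + D, dy : dy + H, dx : dx + W, :]
                        gw[:, dz, dy, dx] = (sl * g).sum(axis=(0, 1, 2, 3))
            _accum(w, gw)

    out = _make(out_data, (x, w), backward)
    return out


# -- trilinear resampling ---------------------------------------------

_interp_cache: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1D linear interpolation matrix between voxel-center grids."""
    key = (n_in, n_out)
    if key in _interp_cache:
        return _interp_cache[key]
    M = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for j in range(n_out):
        c = np.clip((j + 0.5) * scale - 0.5, 0.0, n_in - 1.0)
        i0 = int(np.floor(c))
        i1 = min(i0 + 1, n_in - 1)
        t = c - i0
        M[j, i0] += 1.0 - t
        M[j, i1] += t
    _interp_cache[key] = M
    return M


def _apply_axis(x: np.ndarray, M: np.ndarray, axis: int) -> np.ndarray:
    y = np.tensordot(M.astype(x.dtype), x, axes=([1], [axis]))
    return np.ascontiguousarray(np.moveaxis(y, 0, axis))


def upsample_linear(x, out_spatial) -> Tensor:
    """Separable trilinear resampling of (N, D, H, W, C) to ``out_spatial``."""
    x = as_tensor(x)
    mats = [
        _interp_matrix(n_in, n_out)
        for n_in, n_out in zip(x.data.shape[1:4], out_spatial)
    ]
    out_data = x.data
    for ax, M in enumerate(mats):
        out_data = _apply_axis(out_data, M, ax + 1)

    def backward():
        g = out.grad
        for ax, M in reversed(list(enumerate(mats))):
            g = _apply_axis(g, M.T, ax + 1)
        _accum(x, g)

    out = _make(out_data, (x,), backward)
    return out
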