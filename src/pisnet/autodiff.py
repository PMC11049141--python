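"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for every operation, a
closure that propagates the upstream gradient to its parents.  Calling
:meth:`Tensor.backward` runs the closures in reverse topological order.

The operation set is deliberately small and segmentation-shaped: dense 2-D
convolution (with stride, zero padding and channel groups), stride-1 and
strided max pooling, channel layer/batch normalisation, bilinear resizing,
zero-fill translations used by the shifted-window mixers, and the
elementwise/reduction primitives the losses need.  Each primitive carries a
hand-written adjoint; the test-suite checks every one against central finite
differences.

Arrays flow as float32 by default (float64 is preserved when given, which
the gradient-check tests rely on).
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.special import erf

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled():
    return _GRAD_ENABLED


def _as_array(x):
    a = np.asarray(x)
    if a.dtype.kind in "iub":
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g):
        self.grad = g if self.grad is None else self.grad + g

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self):
        return Tensor(self.data)

    def numpy(self):
        return self.data

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._result(data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._result(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        return Tensor._result(data, (self, other), bw)

    def __pow__(self, p):
        assert np.isscalar(p)
        data = self.data ** p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._result(data, (self,), bw)

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        data = self.data.reshape(shape)

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._result(data, (self,), bw)

    def __getitem__(self, idx):
        data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor._result(data, (self,), bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._result(data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities ----------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._result(self.data * mask, (self,), bw)

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        data = (x * cdf).astype(x.dtype)
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def bw(g):
            self._accum(g * (cdf + x * pdf).astype(x.dtype))

        return Tensor._result(data, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._result(s.astype(self.data.dtype), (self,), bw)

    def log(self):
        data = np.log(self.data)

        def bw(g):
            self._accum(g / self.data)

        return Tensor._result(data, (self,), bw)

    def clip(self, lo, hi):
        data = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self._accum(g * mask)

        return Tensor._result(data, (self,), bw)

    # -- spatial primitives (N, C, H, W) ----------------------------------
    def shift2d(self, drow, dcol):
        """Translate by (drow, dcol) with zero fill; shape preserved.

        Positive drow moves content down, positive dcol moves it right.
        The adjoint of a zero-fill translation is the opposite translation.
        """
        data = _shift2d(self.data, drow, dcol)

        def bw(g):
            self._accum(_shift2d(g, -drow, -dcol))

        return Tensor._result(data, (self,), bw)

    def shift_rows_grouped(self, offsets):
        """Vertical zero-fill shift of contiguous channel groups.

        Channels are split into ``len(offsets)`` near-equal contiguous
        groups; group g translates by ``offsets[g]`` rows.
        """
        return self._shift_grouped(offsets, axis=0)

    def shift_cols_grouped(self, offsets):
        """Horizontal counterpart of :meth:`shift_rows_grouped`."""
        return self._shift_grouped(offsets, axis=1)

    def _shift_grouped(self, offsets, axis):
        bounds = _group_bounds(self.data.shape[1], len(offsets))

        def apply(a, sign):
            out = np.empty_like(a)
            for (lo, hi), off in zip(bounds, offsets):
                dr, dc = (sign * off, 0) if axis == 0 else (0, sign * off)
                out[:, lo:hi] = _shift2d(a[:, lo:hi], dr, dc)
            return out

        def bw(g):
            self._accum(apply(g, -1))

        return Tensor._result(apply(self.data, 1), (self,), bw)

    def conv2d(self, weight, bias=None, stride=1, padding=0, groups=1):
        return _conv2d(self, weight, bias, stride, padding, groups)

    def maxpool2d(self, kernel, stride=None, padding=0):
        return _maxpool2d(self, kernel, stride, padding)

    def bilinear_resize(self, out_h, out_w):
        return _bilinear_resize(self, out_h, out_w)


def concat(tensors, axis=1):
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._result(data, tuple(tensors), bw)


# ---------------------------------------------------------------------------
# primitive implementations


def _shift2d(a, drow, dcol):
    out = np.zeros_like(a)
    H, W = a.shape[-2], a.shape[-1]
    if abs(drow) >= H or abs(dcol) >= W:
        return out
    rs = slice(max(drow, 0), H + min(drow, 0))
    rsrc = slice(max(-drow, 0), H + min(-drow, 0))
    cs = slice(max(dcol, 0), W + min(dcol, 0))
    csrc = slice(max(-dcol, 0), W + min(-dcol, 0))
    out[..., rs, cs] = a[..., rsrc, csrc]
    return out


def _group_bounds(channels, ngroups):
    base, rem = divmod(channels, ngroups)
    bounds, start = [], 0
    for g in range(ngroups):
        size = base + (1 if g < rem else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def _im2col(x, kh, kw, stride, padding):
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    H, W = x.shape[2], x.shape[3]
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    s = x.strides
    view = as_strided(
        x, (n, c, oh, ow, kh, kw),
        (s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]))
    return view, oh, ow


def _conv2d(x, weight, bias, stride, padding, groups):
    xd, wd = x.data, weight.data
    n, cin, h, w = xd.shape
    cout, cin_g, kh, kw = wd.shape
    assert cin == cin_g * groups, "channel/group mismatch"
    view, oh, ow = _im2col(xd, kh, kw, stride, padding)
    if groups == 1:
        out = np.einsum("nchwij,ocij->nohw", view, wd, optimize=True)
    else:
        out = np.empty((n, cout, oh, ow), dtype=xd.dtype)
        og = cout // groups
        for g in range(groups):
            out[:, g * og:(g + 1) * og] = np.einsum(
                "nchwij,ocij->nohw",
                view[:, g * cin_g:(g + 1) * cin_g],
                wd[g * og:(g + 1) * og], optimize=True)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        og = cout // groups
        if weight.requires_grad:
            if groups == 1:
                dw = np.einsum("nohw,nchwij->ocij", g, view, optimize=True)
            else:
                dw = np.empty_like(wd)
                for gr in range(groups):
                    dw[gr * og:(gr + 1) * og] = np.einsum(
                        "nohw,nchwij->ocij", g[:, gr * og:(gr + 1) * og],
                        view[:, gr * cin_g:(gr + 1) * cin_g], optimize=True)
            weight._accum(dw)
        if x.requires_grad:
            hp, wp = h + 2 * padding, w + 2 * padding
            dxp = np.zeros((n, cin, hp, wp), dtype=xd.dtype)
            if groups == 1:
                dcols = np.einsum("nohw,ocij->nchwij", g, wd, optimize=True)
            else:
                dcols = np.empty((n, cin, oh, ow, kh, kw), dtype=xd.dtype)
                for gr in range(groups):
                    dcols[:, gr * cin_g:(gr + 1) * cin_g] = np.einsum(
                        "nohw,ocij->nchwij", g[:, gr * og:(gr + 1) * og],
                        wd[gr * og:(gr + 1) * og], optimize=True)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + oh * stride:stride,
                        j:j + ow * stride:stride] += dcols[:, :, :, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._result(out, parents, bw)


def _maxpool2d(x, kernel, stride, padding):
    """Max pooling via two separable 1-D passes (O(k) work, O(HW) memory).

    The column pass records, per output column, which window offset won;
    the row pass does the same over rows of the column maxima.  Combining
    the two recovers the absolute argmax coordinates for the backward
    scatter without ever materialising (k, k) windows — the adaptive
    pyramid can request kernels comparable to the map side.
    """
    stride = kernel if stride is None else stride
    xd = x.data
    n, c, h, w = xd.shape
    if padding:
        xp = np.full((n, c, h + 2 * padding, w + 2 * padding),
                     -np.inf, dtype=xd.dtype)
        xp[:, :, padding:padding + h, padding:padding + w] = xd
    else:
        xp = xd
    H, W = xp.shape[2], xp.shape[3]
    oh = (H - kernel) // stride + 1
    ow = (W - kernel) // stride + 1

    colmax = np.full((n, c, H, ow), -np.inf, dtype=xd.dtype)
    colarg = np.zeros((n, c, H, ow), dtype=np.intp)
    for i in range(kernel):
        sl = xp[:, :, :, i:i + (ow - 1) * stride + 1:stride]
        better = sl > colmax
        colmax[better] = sl[better]
        colarg[better] = i
    out = np.full((n, c, oh, ow), -np.inf, dtype=xd.dtype)
    rowarg = np.zeros((n, c, oh, ow), dtype=np.intp)
    for i in range(kernel):
        sl = colmax[:, :, i:i + (oh - 1) * stride + 1:stride, :]
        better = sl > out
        out[better] = sl[better]
        rowarg[better] = i

    def bw(g):
        abs_row = (np.arange(oh) * stride)[None, None, :, None] + rowarg
        ni = np.broadcast_to(np.arange(n)[:, None, None, None], rowarg.shape)
        ci = np.broadcast_to(np.arange(c)[None, :, None, None], rowarg.shape)
        oj = np.broadcast_to(np.arange(ow)[None, None, None, :], rowarg.shape)
        abs_col = oj * stride + colarg[ni, ci, abs_row, oj]
        dxp = np.zeros_like(xp)
        np.add.at(dxp, (ni, ci, abs_row, abs_col), g)
        if padding:
            dxp = dxp[:, :, padding:padding + h, padding:padding + w]
        x._accum(dxp)

    return Tensor._result(out, (x,), bw)


def _resize_matrix(n_in, n_out, dtype):
    """Row-interpolation matrix for align_corners=False bilinear resizing."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[i, lo_c] += 1.0 - frac
        m[i, hi_c] += frac
    return m


def _bilinear_resize(x, out_h, out_w):
    xd = x.data
    h, w = xd.shape[2], xd.shape[3]
    mh = _resize_matrix(h, out_h, xd.dtype)
    mw = _resize_matrix(w, out_w, xd.dtype)
    out = np.einsum("oh,nchw,pw->ncop", mh, xd, mw, optimize=True)

    def bw(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", mh, g, mw, optimize=True))

    return Tensor._result(out, (x,), bw)
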