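"""Minimal define-by-run autograd engine on numpy.

Provides exactly the primitives the detector needs: elementwise ops,
matmul, 2-D convolution (im2col), modulated deformable convolution with
bilinear sampling, group normalization, max pooling, nearest/bilinear
resizing, gather, and an SGD optimizer with momentum and weight decay.

All arrays are channel-first ``(N, C, H, W)``. Dtype follows the inputs
(float32 in the pipeline, float64 in gradient-checking tests).
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

# ---------------------------------------------------------------------------
# Tensor and graph machinery
# ---------------------------------------------------------------------------

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return pow_scalar(self, p)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    # -- backprop ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node is not self:
                node._parents = ()
                node._backward = None


def astensor(x, dtype=None):
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _coerce(a, b):
    """Wrap operands; python scalars adopt the tensor operand's dtype."""
    if isinstance(a, Tensor):
        if not isinstance(b, Tensor):
            dt = a.dtype if np.issubdtype(a.dtype, np.floating) else None
            b = Tensor(np.asarray(b, dtype=dt))
        return a, b
    if isinstance(b, Tensor):
        dt = b.dtype if np.issubdtype(b.dtype, np.floating) else None
        return Tensor(np.asarray(a, dtype=dt)), b
    return astensor(a), astensor(b)


def _make(data, parents, backward):
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad += g


def _unbroadcast(g, shape):
    """Sum gradient g down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Elementwise & reduction ops
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _coerce(a, b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    a, b = _coerce(a, b)
    out_data = a.data - b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _coerce(a, b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def div(a, b):
    a, b = _coerce(a, b)
    out_data = a.data / b.data

    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(out_data, (a, b), backward)


def pow_scalar(a, p):
    a = astensor(a)
    out_data = a.data ** p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1))

    return _make(out_data, (a,), backward)


def exp(a):
    a = astensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    a = astensor(a)
    out_data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _make(out_data, (a,), backward)


def sqrt(a):
    a = astensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        _accum(a, g * 0.5 / out_data)

    return _make(out_data, (a,), backward)


def relu(a):
    a = astensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = astensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def softplus(a):
    """log(1 + e^x), numerically stable; gradient is sigmoid(x)."""
    a = astensor(a)
    out_data = np.logaddexp(np.asarray(0.0, dtype=a.dtype), a.data)

    def backward(g):
        _accum(a, g / (1.0 + np.exp(-a.data)))

    return _make(out_data, (a,), backward)


def clamp(a, lo, hi):
    a = astensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), backward)


def hard_sigmoid(a, offset=3.0, divisor=6.0):
    """Piecewise-linear logistic approximation clamp((x+offset)/divisor, 0, 1)."""
    return clamp(div(add(a, offset), divisor), 0.0, 1.0)


def maximum(a, b):
    a, b = _coerce(a, b)
    out_data = np.maximum(a.data, b.data)
    amask = a.data >= b.data  # ties route to the first argument

    def backward(g):
        _accum(a, _unbroadcast(g * amask, a.data.shape))
        _accum(b, _unbroadcast(g * (~amask), b.data.shape))

    return _make(out_data, (a, b), backward)


def minimum(a, b):
    a, b = _coerce(a, b)
    out_data = np.minimum(a.data, b.data)
    amask = a.data <= b.data

    def backward(g):
        _accum(a, _unbroadcast(g * amask, a.data.shape))
        _accum(b, _unbroadcast(g * (~amask), b.data.shape))

    return _make(out_data, (a, b), backward)


def sum_(a, axis=None, keepdims=False):
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            shape = [1 if i in axes else s for i, s in enumerate(a.data.shape)]
            g = g.reshape(shape)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def mean(a, axis=None, keepdims=False):
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return div(sum_(a, axis, keepdims), float(n))


def reshape(a, shape):
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes):
    a = astensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, g.transpose(inv))

    return _make(out_data, (a,), backward)


def concat(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return _make(out_data, tuple(tensors), backward)


def slice_axis(a, axis, lo, hi):
    """Contiguous slice along one axis."""
    a = astensor(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(lo, hi)
    idx = tuple(idx)
    out_data = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[idx] = g
        _accum(a, ga)

    return _make(out_data, (a,), backward)


def take(a, index, axis=0):
    """Gather rows along ``axis`` with an integer index array."""
    a = astensor(a)
    index = np.asarray(index)
    out_data = np.take(a.data, index, axis=axis)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, (slice(None),) * axis + (index,), g)
        _accum(a, ga)

    return _make(out_data, (a,), backward)


def matmul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _accum(a, _unbroadcast(ga, a.data.shape))
        _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# Spatial ops
# ---------------------------------------------------------------------------

def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def pad2d(a, pad):
    """Zero-pad the last two axes by (top, bottom, left, right)."""
    a = astensor(a)
    t, b, l, r = pad
    out_data = np.pad(a.data, ((0, 0),) * (a.ndim - 2) + ((t, b), (l, r)))
    H, W = a.data.shape[-2:]

    def backward(g):
        _accum(a, g[..., t:t + H, l:l + W])

    return _make(out_data, (a,), backward)


def _im2col(xp, kh, kw, sh, sw, Ho, Wo):
    N, C = xp.shape[:2]
    cols = np.empty((N, C, kh, kw, Ho, Wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw]
    return cols.reshape(N, C * kh * kw, Ho * Wo)


def _col2im(gcols, xp_shape, kh, kw, sh, sw, Ho, Wo):
    N, C = xp_shape[:2]
    g6 = gcols.reshape(N, C, kh, kw, Ho, Wo)
    gxp = np.zeros(xp_shape, dtype=gcols.dtype)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += g6[:, :, i, j]
    return gxp


def conv2d(x, w, b=None, stride=1, padding=0):
    """2-D convolution (cross-correlation), NCHW, OIHW weights."""
    x, w = astensor(x), astensor(w)
    if b is not None:
        b = astensor(b)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    N, C, H, W = x.shape
    Co, Ci, kh, kw = w.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input has {C}, weight expects {Ci}")
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    if _HAVE_NUMBA:
        cols = _im2col_nb(np.ascontiguousarray(x.data), kh, kw, sh, sw,
                          ph, pw, Ho, Wo)
    else:  # pragma: no cover - numpy fallback
        xp = (np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
              if (ph or pw) else x.data)
        cols = _im2col(xp, kh, kw, sh, sw, Ho, Wo)      # (N, C*kh*kw, Ho*Wo)
    w2 = w.data.reshape(Co, -1)
    out = w2 @ cols                                     # (N, Co, Ho*Wo)
    if b is not None:
        out = out + b.data[:, None]
    out = out.reshape(N, Co, Ho, Wo)

    def backward(g):
        g2 = g.reshape(N, Co, Ho * Wo)
        if w.requires_grad:
            gw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            _accum(w, gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum(b, g2.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = w2.T @ g2
            if _HAVE_NUMBA:
                gx = _col2im_nb(
                    np.ascontiguousarray(gcols.reshape(N, C, kh * kw, Ho * Wo)),
                    kh, kw, sh, sw, ph, pw, Ho, Wo, H, W)
                _accum(x, gx)
                return
            xp_shape = (N, C, H + 2 * ph, W + 2 * pw)
            gxp = _col2im(gcols, xp_shape, kh, kw, sh, sw, Ho, Wo)
            if ph or pw:
                gxp = gxp[:, :, ph:ph + H, pw:pw + W]
            _accum(x, gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def linear(x, w, b=None):
    """x:(N,Ci) @ w:(Co,Ci)^T + b."""
    out = matmul(x, transpose(w, (1, 0)))
    if b is not None:
        out = add(out, b)
    return out


def maxpool2d(x, kernel=3, stride=2, padding=1):
    x = astensor(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    N, C, H, W = x.shape
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    neg = np.finfo(x.dtype).min if np.issubdtype(x.dtype, np.floating) else -(10 ** 9)
    xp = np.full((N, C, H + 2 * ph, W + 2 * pw), neg, dtype=x.dtype)
    xp[:, :, ph:ph + H, pw:pw + W] = x.data
    stackv = np.empty((kh * kw, N, C, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            stackv[i * kw + j] = xp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw]
    arg = stackv.argmax(axis=0)
    out = np.take_along_axis(stackv, arg[None], axis=0)[0]

    def backward(g):
        gxp = np.zeros_like(xp)
        for k in range(kh * kw):
            i, j = divmod(k, kw)
            mask = arg == k
            gxp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += g * mask
        _accum(x, gxp[:, :, ph:ph + H, pw:pw + W])

    return _make(out, (x,), backward)


def group_norm(x, gamma, beta, groups, eps=1e-5):
    """Group normalization over (C/G, H, W) groups of an NCHW tensor."""
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    N, C, H, W = x.shape
    G = groups
    if C % G:
        raise ValueError(f"channels {C} not divisible by groups {G}")
    xg = x.data.reshape(N, G, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = np.einsum("ngs,ngs->ng", xg, xg)[..., None] / xg.shape[2] - mu * mu
    inv = 1.0 / np.sqrt(np.maximum(var, 0.0) + eps)
    y = (xg - mu) * inv                       # normalized, (N, G, C//G*H*W)
    ybc = y.reshape(N, C, H, W)
    out = ybc * gamma.data.reshape(1, C, 1, 1) + beta.data.reshape(1, C, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            _accum(gamma, (g * ybc).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gy = (g * gamma.data.reshape(1, C, 1, 1)).reshape(N, G, -1)
            m = gy.shape[2]
            gy_mean = gy.mean(axis=2, keepdims=True)
            gyy_mean = (gy * y).mean(axis=2, keepdims=True)
            gx = (gy - gy_mean - y * gyy_mean) * inv
            _accum(x, gx.reshape(N, C, H, W))
        del m  # noqa: F841 - clarity only

    return _make(out, (x, gamma, beta), backward)


def group_norm_masked(x, gamma, beta, groups, mask, area, eps=1e-5):
    """Group normalization over a masked sub-region of each sample.

    ``mask`` is (N, 1, H, W) of {0, 1}; ``area`` (N,) its per-sample pixel
    count.  Statistics are computed over the masked pixels only and the
    output is zero outside the mask — so a batch of zero-padded feature
    maps normalizes exactly as the unpadded maps would.
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    N, C, H, W = x.shape
    G = groups
    cpg = C // G
    m3 = mask.reshape(N, 1, H * W)
    count = (np.asarray(area, dtype=x.dtype) * cpg).reshape(N, 1, 1)
    xm = (x.data.reshape(N, C, H * W) * m3).reshape(N, G, -1)
    s1 = xm.sum(axis=2, keepdims=True)
    mu = s1 / count
    var = np.einsum("ngs,ngs->ng", xm, xm)[..., None] / count - mu * mu
    inv = 1.0 / np.sqrt(np.maximum(var, 0.0) + eps)
    y = (x.data.reshape(N, G, -1) - mu) * inv
    ybc = y.reshape(N, C, H, W)
    mask4 = mask.reshape(N, 1, H, W)
    out = (ybc * gamma.data.reshape(1, C, 1, 1)
           + beta.data.reshape(1, C, 1, 1)) * mask4

    def backward(g):
        gm4 = g * mask4
        if gamma.requires_grad:
            _accum(gamma, (gm4 * ybc).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accum(beta, gm4.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gy = (gm4 * gamma.data.reshape(1, C, 1, 1)).reshape(N, G, -1)
            ym = (ybc * mask4).reshape(N, G, -1)
            gy_mean = gy.sum(axis=2, keepdims=True) / count
            gyy_mean = np.einsum("ngs,ngs->ng", gy, ym)[..., None] / count
            mg = np.broadcast_to(m3, (N, C, H * W)).reshape(N, G, -1)
            gx = (gy - mg * (gy_mean + ym * gyy_mean)) * inv
            _accum(x, gx.reshape(N, C, H, W))

    return _make(out, (x, gamma, beta), backward)


def _nearest_matrix(n_out, n_in, dtype):
    R = np.zeros((n_out, n_in), dtype=dtype)
    idx = np.minimum(np.arange(n_out) * n_in // n_out, n_in - 1)
    R[np.arange(n_out), idx] = 1.0
    return R


def _bilinear_matrix(n_out, n_in, dtype):
    """Row-stochastic interpolation matrix (align_corners=False, clamped)."""
    R = np.zeros((n_out, n_in), dtype=dtype)
    f = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(f).astype(np.int64), 0, n_in - 1)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w = np.clip(f - np.floor(f), 0.0, 1.0)
    w[f < 0] = 0.0
    np.add.at(R, (np.arange(n_out), i0), 1.0 - w)
    np.add.at(R, (np.arange(n_out), i1), w)
    return R


def _resize_with(x, out_hw, matrix_fn):
    """Separable resize out = Ry @ x @ Rx^T; backward is the transpose."""
    x = astensor(x)
    N, C, H, W = x.shape
    Ho, Wo = out_hw
    dt = x.dtype if np.issubdtype(x.dtype, np.floating) else np.float64
    Ry = matrix_fn(Ho, H, dt)
    RxT = matrix_fn(Wo, W, dt).T
    out = (Ry @ x.data) @ RxT

    def backward(g):
        _accum(x, (Ry.T @ g) @ RxT.T)

    return _make(out, (x,), backward)


def resize_nearest(x, out_hw):
    return _resize_with(x, out_hw, _nearest_matrix)


def resize_bilinear(x, out_hw):
    """Bilinear resize (align_corners=False, edges clamped)."""
    return _resize_with(x, out_hw, _bilinear_matrix)


# ---------------------------------------------------------------------------
# Modulated deformable convolution
# ---------------------------------------------------------------------------

try:  # compiled bilinear gather/scatter kernels (channels-last inner loops)
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _deform_gather(xt, py, px, m):
        """Modulated bilinear gather.

        xt: (N, H, W, C); py/px/m: (N, K2, S).
        Returns cols (N, S, K2, C): cols[n,s,p,:] = m * bilinear(x, p_pos).
        """
        N, H, W, C = xt.shape
        K2, S = py.shape[1], py.shape[2]
        cols = np.zeros((N, S, K2, C), dtype=xt.dtype)
        for n in range(N):
            for p in range(K2):
                for s in range(S):
                    fy = py[n, p, s]
                    fx = px[n, p, s]
                    mm = m[n, p, s]
                    y0 = int(np.floor(fy))
                    x0 = int(np.floor(fx))
                    wy = fy - y0
                    wx = fx - x0
                    for dy in range(2):
                        yy = y0 + dy
                        if yy < 0 or yy >= H:
                            continue
                        wyc = wy if dy == 1 else 1.0 - wy
                        for dx in range(2):
                            xx = x0 + dx
                            if xx < 0 or xx >= W:
                                continue
                            wc = mm * wyc * (wx if dx == 1 else 1.0 - wx)
                            if wc == 0.0:
                                continue
                            for c in range(C):
                                cols[n, s, p, c] += wc * xt[n, yy, xx, c]
        return cols

    @_njit(cache=True, fastmath=True)
    def _deform_backward(gcols, xt, py, px, m, need_gx, need_goff, need_gm):
        """Backward of the modulated gather.

        gcols: (N, S, K2, C) gradient on the modulated columns.
        Returns gxt (N, H, W, C), gpy, gpx, gm (each (N, K2, S)).
        """
        N, H, W, C = xt.shape
        K2, S = py.shape[1], py.shape[2]
        gxt = np.zeros((N, H, W, C), dtype=xt.dtype)
        gpy = np.zeros((N, K2, S), dtype=xt.dtype)
        gpx = np.zeros((N, K2, S), dtype=xt.dtype)
        gm = np.zeros((N, K2, S), dtype=xt.dtype)
        for n in range(N):
            for p in range(K2):
                for s in range(S):
                    fy = py[n, p, s]
                    fx = px[n, p, s]
                    mm = m[n, p, s]
                    y0 = int(np.floor(fy))
                    x0 = int(np.floor(fx))
                    wy = fy - y0
                    wx = fx - x0
                    acc_y = 0.0
                    acc_x = 0.0
                    acc_m = 0.0
                    for dy in range(2):
                        yy = y0 + dy
                        if yy < 0 or yy >= H:
                            continue
                        wyc = wy if dy == 1 else 1.0 - wy
                        sy = 1.0 if dy == 1 else -1.0
                        for dx in range(2):
                            xx = x0 + dx
                            if xx < 0 or xx >= W:
                                continue
                            wxc = wx if dx == 1 else 1.0 - wx
                            sx = 1.0 if dx == 1 else -1.0
                            wc = wyc * wxc
                            dotv = 0.0
                            if need_gx:
                                for c in range(C):
                                    g = gcols[n, s, p, c]
                                    gxt[n, yy, xx, c] += mm * wc * g
                                    dotv += g * xt[n, yy, xx, c]
                            else:
                                for c in range(C):
                                    dotv += gcols[n, s, p, c] * xt[n, yy, xx, c]
                            acc_m += wc * dotv
                            acc_y += mm * sy * wxc * dotv
                            acc_x += mm * sx * wyc * dotv
                    if need_goff:
                        gpy[n, p, s] = acc_y
                        gpx[n, p, s] = acc_x
                    if need_gm:
                        gm[n, p, s] = acc_m
        return gxt, gpy, gpx, gm

    @_njit(cache=True, fastmath=True)
    def _im2col_nb(x, kh, kw, sh, sw, ph, pw, Ho, Wo):
        N, C, H, W = x.shape
        cols = np.zeros((N, C, kh * kw, Ho * Wo), dtype=x.dtype)
        for n in range(N):
            for c in range(C):
                for i in range(kh):
                    for j in range(kw):
                        p = i * kw + j
                        # hoisted bounds: ox*sw - pw + j in [0, W)
                        lo = (pw - j + sw - 1) // sw
                        if lo < 0:
                            lo = 0
                        hi = (W - 1 + pw - j) // sw + 1
                        if hi > Wo:
                            hi = Wo
                        for oy in range(Ho):
                            y = oy * sh - ph + i
                            if y < 0 or y >= H:
                                continue
                            row = oy * Wo
                            xx = lo * sw - pw + j
                            for ox in range(lo, hi):
                                cols[n, c, p, row + ox] = x[n, c, y, xx]
                                xx += sw
        return cols.reshape(N, C * kh * kw, Ho * Wo)

    @_njit(cache=True, fastmath=True)
    def _col2im_nb(gcols6, kh, kw, sh, sw, ph, pw, Ho, Wo, H, W):
        N, C = gcols6.shape[0], gcols6.shape[1]
        gx = np.zeros((N, C, H, W), dtype=gcols6.dtype)
        for n in range(N):
            for c in range(C):
                for i in range(kh):
                    for j in range(kw):
                        p = i * kw + j
                        lo = (pw - j + sw - 1) // sw
                        if lo < 0:
                            lo = 0
                        hi = (W - 1 + pw - j) // sw + 1
                        if hi > Wo:
                            hi = Wo
                        for oy in range(Ho):
                            y = oy * sh - ph + i
                            if y < 0 or y >= H:
                                continue
                            row = oy * Wo
                            xx = lo * sw - pw + j
                            for ox in range(lo, hi):
                                gx[n, c, y, xx] += gcols6[n, c, p, row + ox]
                                xx += sw
        return gx

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is expected to be present
    _HAVE_NUMBA = False

def deformable_conv2d(x, w, b, offsets, modulation, stride=1, padding=1):
    """Modulated deformable 3x3 (or KxK) convolution.

    Each kernel point ``n`` samples the input at ``p + p_n + Δp_n`` by
    bilinear interpolation (zero outside the map) and is scaled by the
    per-location coefficient ``Δm_n`` before the filter weights are
    applied.  With ``Δp ≡ 0`` and ``Δm ≡ 1`` the operator reduces exactly
    to a standard convolution of the same stride/padding.

    Parameters
    ----------
    x : (N, Ci, H, W)
    w : (Co, Ci, K, K)
    b : (Co,) or None
    offsets : (N, 2*K*K, Ho, Wo) — (dy, dx) pairs per kernel point,
        shared across channels.
    modulation : (N, K*K, Ho, Wo) — coefficients in [0, 1].
    """
    x, w = astensor(x), astensor(w)
    offsets = astensor(offsets)
    modulation = astensor(modulation)
    if b is not None:
        b = astensor(b)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    N, C, H, W = x.shape
    Co, Ci, kh, kw = w.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input has {C}, weight expects {Ci}")
    K2 = kh * kw
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    S = Ho * Wo
    if offsets.shape != (N, 2 * K2, Ho, Wo):
        raise ValueError(f"offset field must have {2 * K2} channels at {Ho}x{Wo}")
    if modulation.shape != (N, K2, Ho, Wo):
        raise ValueError(f"modulation field must have {K2} channels at {Ho}x{Wo}")

    dt = x.dtype
    oy, ox = np.meshgrid(np.arange(Ho), np.arange(Wo), indexing="ij")
    base_y = (oy * sh - ph).reshape(-1).astype(dt)          # (S,)
    base_x = (ox * sw - pw).reshape(-1).astype(dt)
    ky, kx = np.meshgrid(np.arange(kh), np.arange(kw), indexing="ij")
    off = offsets.data.reshape(N, K2, 2, S)
    py = np.ascontiguousarray(
        base_y[None, None] + ky.reshape(-1)[None, :, None] + off[:, :, 0])
    px = np.ascontiguousarray(
        base_x[None, None] + kx.reshape(-1)[None, :, None] + off[:, :, 1])

    xt = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1))   # (N, H, W, C)
    mflat = np.ascontiguousarray(modulation.data.reshape(N, K2, S))
    gather = _deform_gather if _HAVE_NUMBA else _deform_gather_py
    back = _deform_backward if _HAVE_NUMBA else _deform_backward_py
    cols = gather(xt, py, px, mflat)                          # (N, S, K2, C)
    cols2 = cols.reshape(N, S, K2 * C)
    # weight in (kernel-point, channel) column order to match the gather
    wt = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0)).reshape(K2 * C, Co)
    out_t = cols2 @ wt                                        # (N, S, Co)
    if b is not None:
        out_t = out_t + b.data
    out = np.ascontiguousarray(out_t.transpose(0, 2, 1)).reshape(N, Co, Ho, Wo)

    def backward(g):
        g2t = np.ascontiguousarray(g.reshape(N, Co, S).transpose(0, 2, 1))
        if w.requires_grad:
            gwt = np.matmul(cols2.transpose(0, 2, 1), g2t).sum(axis=0)
            gw = gwt.reshape(kh, kw, C, Co).transpose(3, 2, 0, 1)
            _accum(w, np.ascontiguousarray(gw))
        if b is not None and b.requires_grad:
            _accum(b, g2t.sum(axis=(0, 1)))
        need_gx = x.requires_grad
        need_goff = offsets.requires_grad
        need_gm = modulation.requires_grad
        if not (need_gx or need_goff or need_gm):
            return
        gcols = (g2t @ wt.T).reshape(N, S, K2, C)
        gxt, gpy, gpx, gm = back(gcols, xt, py, px, mflat,
                                 need_gx, need_goff, need_gm)
        if need_gx:
            _accum(x, np.ascontiguousarray(gxt.transpose(0, 3, 1, 2)))
        if need_goff:
            goff = np.stack([gpy, gpx], axis=2)               # (N, K2, 2, S)
            _accum(offsets, goff.reshape(N, 2 * K2, Ho, Wo))
        if need_gm:
            _accum(modulation, gm.reshape(N, K2, Ho, Wo))

    parents = [x, w, offsets, modulation] + ([b] if b is not None else [])
    return _make(out, tuple(parents), backward)


def _corner_iter(py, px, H, W):
    y0 = np.floor(py).astype(np.int64)
    x0 = np.floor(px).astype(np.int64)
    wy, wx = py - y0, px - x0
    for yy, xx, cw, sy_wxc, sx_wyc in (
        (y0, x0, (1 - wy) * (1 - wx), -(1 - wx), -(1 - wy)),
        (y0, x0 + 1, (1 - wy) * wx, -wx, (1 - wy)),
        (y0 + 1, x0, wy * (1 - wx), (1 - wx), -wy),
        (y0 + 1, x0 + 1, wy * wx, wx, wy),
    ):
        valid = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        yield np.where(valid, yy * W + xx, 0), valid, cw, sy_wxc, sx_wyc


def _deform_gather_py(xt, py, px, m):  # numpy fallback, same contract
    N, H, W, C = xt.shape
    K2, S = py.shape[1], py.shape[2]
    xf = xt.reshape(N, H * W, C)
    bidx = np.arange(N)[:, None, None]
    cols = np.zeros((N, K2, S, C), dtype=xt.dtype)
    for flat, valid, cw, _, _ in _corner_iter(py, px, H, W):
        cols += (m * cw * valid)[..., None] * xf[bidx, flat]
    return np.ascontiguousarray(cols.transpose(0, 2, 1, 3))


def _deform_backward_py(gcols, xt, py, px, m, need_gx, need_goff, need_gm):
    N, H, W, C = xt.shape
    K2, S = py.shape[1], py.shape[2]
    xf = xt.reshape(N, H * W, C)
    bidx = np.arange(N)[:, None, None]
    gc = np.ascontiguousarray(gcols.transpose(0, 2, 1, 3))    # (N, K2, S, C)
    gxf = np.zeros_like(xf)
    gpy = np.zeros((N, K2, S), dtype=xt.dtype)
    gpx = np.zeros((N, K2, S), dtype=xt.dtype)
    gm = np.zeros((N, K2, S), dtype=xt.dtype)
    for flat, valid, cw, sy_wxc, sx_wyc in _corner_iter(py, px, H, W):
        v = xf[bidx, flat] * valid[..., None]
        dotv = (gc * v).sum(axis=3)
        gm += cw * dotv
        gpy += m * sy_wxc * dotv * valid
        gpx += m * sx_wyc * dotv * valid
        if need_gx:
            np.add.at(gxf, (bidx, flat), (m * cw * valid)[..., None] * gc)
    return (gxf.reshape(N, H, W, C), gpy, gpx, gm)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Lightweight container; discovers parameters through attributes."""

    @staticmethod
    def _children(container):
        """Yield (name, Module-or-Parameter) pairs, recursing nested lists."""
        for k, v in container:
            if isinstance(v, (Parameter, Module)):
                yield k, v
            elif isinstance(v, (list, tuple)):
                yield from Module._children(
                    (f"{k}.{i}", item) for i, item in enumerate(v))

    def parameters(self):
        out = []
        seen = set()
        stack = [self]
        while stack:
            mod = stack.pop()
            if id(mod) in seen:
                continue
            seen.add(id(mod))
            for _, v in Module._children(vars(mod).items()):
                if isinstance(v, Parameter):
                    out.append(v)
                else:
                    stack.append(v)
        return out

    def named_modules(self, prefix=""):
        yield prefix, self
        for k, v in Module._children(vars(self).items()):
            if isinstance(v, Module):
                name = f"{prefix}.{k}" if prefix else k
                yield from v.named_modules(name)

    def param_count(self):
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        state = {}
        for name, mod in self.named_modules():
            for k, v in vars(mod).items():
                if isinstance(v, Parameter):
                    state[f"{name}.{k}" if name else k] = v.data
        return state

    def load_state_dict(self, state):
        own = {}
        for name, mod in self.named_modules():
            for k, v in vars(mod).items():
                if isinstance(v, Parameter):
                    own[f"{name}.{k}" if name else k] = v
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)[:5]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float32)

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


def he_normal(rng, shape, fan_in):
    std = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride=1, padding=None, bias=True,
                 rng=None, zero_init=False, bias_init=0.0):
        kh, kw = _pair(kernel)
        self.c_in, self.c_out = c_in, c_out
        self.kernel = (kh, kw)
        self.stride = stride
        self.padding = kh // 2 if padding is None else padding
        if zero_init or rng is None:
            w = np.zeros((c_out, c_in, kh, kw), dtype=np.float32)
        else:
            w = he_normal(rng, (c_out, c_in, kh, kw), c_in * kh * kw)
        self.weight = Parameter(w)
        self.bias = Parameter(np.full(c_out, bias_init, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)

    def macs(self, out_h, out_w):
        kh, kw = self.kernel
        return kh * kw * self.c_in * self.c_out * out_h * out_w

    def out_hw(self, h, w):
        kh, kw = self.kernel
        sh, sw = _pair(self.stride)
        ph, pw = _pair(self.padding)
        return (h + 2 * ph - kh) // sh + 1, (w + 2 * pw - kw) // sw + 1


class Linear(Module):
    def __init__(self, c_in, c_out, rng=None, zero_init=False):
        self.c_in, self.c_out = c_in, c_out
        if zero_init or rng is None:
            w = np.zeros((c_out, c_in), dtype=np.float32)
        else:
            w = he_normal(rng, (c_out, c_in), c_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))

    def forward(self, x):
        return linear(x, self.weight, self.bias)

    def macs(self):
        return self.c_in * self.c_out


def gn_groups(channels, preferred=32):
    """Largest group count <= preferred keeping >= 4 channels per group."""
    g = max(min(preferred, channels // 4), 1)
    while channels % g:
        g -= 1
    return g


class GroupNorm(Module):
    def __init__(self, channels, groups=None, eps=1e-5):
        self.groups = gn_groups(channels) if groups is None else groups
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x):
        return group_norm(x, self.weight, self.bias, self.groups, self.eps)


class Scale(Module):
    """Per-level learnable scalar multiplier."""

    def __init__(self, init=1.0):
        self.scale = Parameter(np.array([init], dtype=np.float32))

    def forward(self, x):
        return mul(x, reshape(self.scale, (1,) * 1))


class SGD:
    """SGD with momentum and (coupled) weight decay."""

    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr=None):
        lr = self.lr if lr is None else lr
        for p, v in zip(self.params, self.buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
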