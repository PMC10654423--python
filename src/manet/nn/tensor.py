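"""Reverse-mode automatic differentiation over numpy arrays.

A small define-by-run autodiff engine: every operation returns a
:class:`Tensor` holding the result plus a closure that propagates the
upstream gradient to its parents.  Only the operations the segmentation
network needs are implemented (2-D convolution and its transpose, batch
normalization, pooling reductions, element-wise arithmetic, bilinear
upsampling, concatenation).  Convolutions are evaluated as an im2col
GEMM with a channel-major column layout (see ``_conv_kernels``); batch
norm runs through fused single-pass kernels (``_bn_kernels``).  Interior
graph buffers are released as backward propagation consumes them, so the
peak memory of a training step stays close to the live activations.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (cheap inference passes)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph traversal -------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this node (defaults to d(self)/d(self)=1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
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
        _accum(self, np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
                # free the closure caches and this interior node's gradient:
                # both are dead weight once the node has propagated
                t._backward = None
                t.grad = None
                t._parents = ()

    def zero_grad(self):
        self.grad = None

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x, dtype=None):
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _accum(t: Tensor, g: np.ndarray, owned: bool = False):
    """Accumulate a gradient; ``owned`` marks ``g`` as a fresh array that may
    be adopted without a defensive copy."""
    if not t.requires_grad:
        return
    if t.grad is None:
        if owned and g.base is None and g.dtype == t.data.dtype:
            t.grad = g
        else:
            t.grad = np.array(g, dtype=t.data.dtype)  # owned copy, never a view
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == tuple(shape):
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _node(data, parents, backward):
    req = _GRAD_ENABLED and any(isinstance(p, Tensor) and p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req,
                  parents=tuple(p for p in parents if isinstance(p, Tensor)),
                  backward=backward if req else None)


# ---------------------------------------------------------------------------
# element-wise ops
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _node(out_data, (a, b), bwd)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), bwd)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def bwd(g):
        _accum(a, _unbroadcast(g / b.data, a.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _node(out_data, (a, b), bwd)


def relu(x):
    x = as_tensor(x)
    out_data = np.maximum(x.data, 0)

    def bwd(g):
        _accum(x, g * (out_data > 0), owned=True)

    return _node(out_data, (x,), bwd)


def sigmoid(x):
    x = as_tensor(x)
    # exp overflow for very negative inputs saturates cleanly to 0
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        _accum(x, g * s * (1.0 - s), owned=True)

    return _node(s, (x,), bwd)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def bwd(g):
        _accum(a, g @ b.data.swapaxes(-1, -2))
        _accum(b, a.data.swapaxes(-1, -2) @ g)

    return _node(out_data, (a, b), bwd)


# ---------------------------------------------------------------------------
# reductions and pooling
# ---------------------------------------------------------------------------

def _max_reduce(x: Tensor, axes):
    m = x.data.max(axis=axes, keepdims=True)
    # gradient routed to the (first-equal) argmax positions, split on ties
    mask = (x.data == m)
    counts = mask.sum(axis=axes, keepdims=True)

    def bwd(g):
        _accum(x, mask * (g / counts))

    return _node(m, (x,), bwd)


def _mean_reduce(x: Tensor, axes):
    n = np.prod([x.shape[a] for a in axes])
    m = x.data.mean(axis=axes, keepdims=True)

    def bwd(g):
        _accum(x, np.broadcast_to(g / n, x.shape).astype(x.dtype, copy=False))

    return _node(m, (x,), bwd)


def global_max_pool(x):
    """[b,c,h,w] -> [b,c,1,1] max over the full spatial extent."""
    return _max_reduce(as_tensor(x), (2, 3))


def global_avg_pool(x):
    """[b,c,h,w] -> [b,c,1,1] mean over the full spatial extent."""
    return _mean_reduce(as_tensor(x), (2, 3))


def channel_max(x):
    """[b,c,h,w] -> [b,1,h,w] per-pixel max across channels."""
    return _max_reduce(as_tensor(x), (1,))


def channel_mean(x):
    """[b,c,h,w] -> [b,1,h,w] per-pixel mean across channels."""
    return _mean_reduce(as_tensor(x), (1,))


def tsum(x):
    x = as_tensor(x)
    out_data = np.asarray(x.data.sum())

    def bwd(g):
        _accum(x, np.broadcast_to(g, x.shape).astype(x.dtype, copy=False))

    return _node(out_data, (x,), bwd)


def tmean(x):
    x = as_tensor(x)
    out_data = np.asarray(x.data.mean())

    def bwd(g):
        _accum(x, np.broadcast_to(g / x.data.size, x.shape).astype(x.dtype, copy=False))

    return _node(out_data, (x,), bwd)


def sum_spatial(x):
    """[b,c,h,w] -> [b,c] sum over the spatial extent (for soft Dice)."""
    x = as_tensor(x)
    out_data = x.data.sum(axis=(2, 3))

    def bwd(g):
        _accum(x, np.broadcast_to(g[:, :, None, None], x.shape).astype(x.dtype, copy=False))

    return _node(out_data, (x,), bwd)


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _node(out_data, tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

from ._conv_kernels import col2im, im2col  # noqa: E402
from ._bn_kernels import (  # noqa: E402
    _bwd_jit as _bn_bwd_jit,
    _bwd_sums_jit as _bn_sums_jit,
    _fwd_jit as _bn_fwd_jit,
    _stats_jit as _bn_stats_jit,
    have_numba as _have_numba,
)


def _bn_stats(x, mean, var):
    if _have_numba():
        _bn_stats_jit(x, mean, var)
    else:
        mean[:] = x.mean(axis=(0, 2, 3), dtype=np.float64)
        xc = x - mean[None, :, None, None].astype(x.dtype)
        var[:] = (xc * xc).mean(axis=(0, 2, 3), dtype=np.float64)


def _bn_fwd(x, mean, invstd, gamma, beta, xhat, out):
    if _have_numba():
        _bn_fwd_jit(x, mean, invstd, gamma, beta, xhat, out)
    else:
        xhat[:] = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        out[:] = xhat * gamma[None, :, None, None] + beta[None, :, None, None]


def _bn_sums(g, xhat, s1, s2):
    if _have_numba():
        _bn_sums_jit(np.ascontiguousarray(g), xhat, s1, s2)
    else:
        s1[:] = (g * xhat).sum(axis=(0, 2, 3), dtype=np.float64)
        s2[:] = g.sum(axis=(0, 2, 3), dtype=np.float64)


def _bn_bwd(g, xhat, scale, s1n, s2n, gx, training):
    if _have_numba():
        _bn_bwd_jit(g, xhat, scale, s1n, s2n, gx, training)
    else:
        sc = scale[None, :, None, None]
        if training:
            gx[:] = (g - s2n[None, :, None, None] - xhat * s1n[None, :, None, None]) * sc
        else:
            gx[:] = g * sc

# above this many scalars the im2col buffer is not materialized and a
# memory-light per-tap loop is used instead
_IM2COL_LIMIT = 1 << 26


def conv2d(x, w, b=None, stride=1, padding=0):
    """2-D cross-correlation, NCHW layout, weight [co, ci, kh, kw].

    Evaluated as one im2col GEMM when the unrolled buffer is small enough,
    otherwise as a sum of per-kernel-tap GEMMs.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    s, p = int(stride), int(padding)
    B, C, H, W = x.shape
    CO, CI, KH, KW = w.shape
    if CI != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {CI}")
    OH = (H + 2 * p - KH) // s + 1
    OW = (W + 2 * p - KW) // s + 1
    K = C * KH * KW
    N = B * OH * OW

    if KH == 1 and KW == 1 and p == 0:
        return _conv1x1(x, w, b, x.data, s, OH, OW)

    use_gemm = K * N <= _IM2COL_LIMIT
    w2d = w.data.reshape(CO, K)
    if use_gemm:
        x_shape = x.shape
        cols = im2col(x.data, s, KH, KW, p, OH, OW)  # (K, N); padding folded in
        out_data = np.ascontiguousarray(
            (w2d @ cols).reshape(CO, B, OH, OW).transpose(1, 0, 2, 3)
        )
        if b is not None:
            out_data += b.data[None, :, None, None]

        def bwd(g):
            g2d = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(CO, N)
            if w.requires_grad:
                _accum(w, (g2d @ cols.T).reshape(w.shape))
            if x.requires_grad:
                gx = col2im(w2d.T @ g2d, x_shape, s, KH, KW, p, OH, OW)
                _accum(x, gx, owned=True)
            if b is not None:
                _accum(b, g.sum(axis=(0, 2, 3)))

    else:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
        acc = np.zeros((CO, B, OH, OW), dtype=xp.dtype)
        for ki in range(KH):
            for kj in range(KW):
                xs = xp[:, :, ki:ki + s * (OH - 1) + 1:s, kj:kj + s * (OW - 1) + 1:s]
                acc += np.tensordot(w.data[:, :, ki, kj], xs, axes=(1, 1))
        out_data = np.ascontiguousarray(acc.transpose(1, 0, 2, 3))
        if b is not None:
            out_data += b.data[None, :, None, None]

        def bwd(g):
            gt = np.ascontiguousarray(g)
            if w.requires_grad:
                gw = np.empty_like(w.data)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
            for ki in range(KH):
                for kj in range(KW):
                    xs = xp[:, :, ki:ki + s * (OH - 1) + 1:s, kj:kj + s * (OW - 1) + 1:s]
                    if w.requires_grad:
                        gw[:, :, ki, kj] = np.tensordot(gt, xs, axes=([0, 2, 3], [0, 2, 3]))
                    if x.requires_grad:
                        t = np.tensordot(gt, w.data[:, :, ki, kj], axes=(1, 0))  # (B,OH,OW,C)
                        gxp[:, :, ki:ki + s * (OH - 1) + 1:s,
                            kj:kj + s * (OW - 1) + 1:s] += t.transpose(0, 3, 1, 2)
            if w.requires_grad:
                _accum(w, gw)
            if x.requires_grad:
                _accum(x, gxp[:, :, p:p + x.shape[2], p:p + x.shape[3]] if p else gxp)
            if b is not None:
                _accum(b, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, bwd)


def _conv1x1(x, w, b, xp, s, OH, OW):
    """Pointwise convolution: a channel-mixing GEMM, no window gather."""
    xs = xp[:, :, ::s, ::s] if s != 1 else xp
    w2 = w.data[:, :, 0, 0]
    out_data = np.ascontiguousarray(np.tensordot(w2, xs, axes=(1, 1)).transpose(1, 0, 2, 3))
    if b is not None:
        out_data += b.data[None, :, None, None]

    def bwd(g):
        if w.requires_grad:
            gw = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
            _accum(w, gw[:, :, None, None])
        if x.requires_grad:
            t = np.tensordot(w2, g, axes=(0, 1))  # (C, B, OH, OW)
            if s == 1:
                _accum(x, np.ascontiguousarray(t.transpose(1, 0, 2, 3)), owned=True)
            else:
                gx = np.zeros_like(x.data)
                gx[:, :, ::s, ::s] = t.transpose(1, 0, 2, 3)
                _accum(x, gx)
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, bwd)


def conv_transpose2d(x, w, b=None, stride=2):
    """Transposed 2-D convolution, weight [ci, co, k, k] with k == stride.

    With kernel size equal to the stride the output taps do not overlap:
    each input pixel paints one k x k patch, which keeps both directions a
    plain per-offset GEMM.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    CI, CO, KH, KW = w.shape
    s = int(stride)
    if (KH, KW) != (s, s):
        raise NotImplementedError("conv_transpose2d supports kernel == stride only")
    B, C, H, W = x.shape
    if C != CI:
        raise ValueError(f"conv_transpose2d channel mismatch: input {C}, weight expects {CI}")
    out_data = np.empty((B, CO, H * s, W * s), dtype=x.dtype)
    for ki in range(KH):
        for kj in range(KW):
            t = np.tensordot(x.data, w.data[:, :, ki, kj], axes=(1, 0))  # (B,H,W,CO)
            out_data[:, :, ki::s, kj::s] = t.transpose(0, 3, 1, 2)
    if b is not None:
        out_data += b.data[None, :, None, None]

    def bwd(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
        for ki in range(KH):
            for kj in range(KW):
                gs = g[:, :, ki::s, kj::s]
                if w.requires_grad:
                    gw[:, :, ki, kj] = np.tensordot(x.data, gs, axes=([0, 2, 3], [0, 2, 3]))
                if x.requires_grad:
                    gx += np.tensordot(gs, w.data[:, :, ki, kj], axes=(1, 1)).transpose(0, 3, 1, 2)
        if w.requires_grad:
            _accum(w, gw)
        if x.requires_grad:
            _accum(x, gx, owned=True)
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, bwd)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batch_norm2d(x, gamma, beta, running_mean, running_var, training, momentum=0.1, eps=1e-5):
    """Per-channel batch normalization with affine terms.

    ``running_mean``/``running_var`` are plain numpy arrays updated in place
    during training (they carry no gradient).
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    xd = np.ascontiguousarray(x.data)
    n = xd.size / xd.shape[1]
    if training:
        mean = np.empty(xd.shape[1], dtype=np.float64)
        var = np.empty(xd.shape[1], dtype=np.float64)
        _bn_stats(xd, mean, var)
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * (var * n / max(n - 1, 1))  # unbiased for the running stat
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = np.empty_like(xd)
    out_data = np.empty_like(xd)
    _bn_fwd(xd, mean.astype(xd.dtype), invstd.astype(xd.dtype),
            gamma.data, beta.data, xhat, out_data)

    def bwd(g):
        s1 = np.empty(xd.shape[1], dtype=np.float64)
        s2 = np.empty(xd.shape[1], dtype=np.float64)
        _bn_sums(g, xhat, s1, s2)
        _accum(gamma, s1.astype(gamma.data.dtype))
        _accum(beta, s2.astype(beta.data.dtype))
        if not x.requires_grad:
            return
        scale = (gamma.data * invstd).astype(xd.dtype)
        gx = np.empty_like(xd)
        _bn_bwd(np.ascontiguousarray(g), xhat, scale,
                (s1 / n).astype(xd.dtype), (s2 / n).astype(xd.dtype), gx, training)
        _accum(x, gx, owned=True)

    return _node(out_data, (x, gamma, beta), bwd)


# ---------------------------------------------------------------------------
# bilinear upsampling
# ---------------------------------------------------------------------------

def _linear_coords(n_out, n_in, scale):
    src = (np.arange(n_out) + 0.5) / scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(np.intp)
    frac = src - i0
    i1 = np.minimum(i0 + 1, n_in - 1)
    return i0, i1, frac


def upsample_bilinear(x, scale=2):
    """Bilinear interpolation by an integer factor (half-pixel centers)."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    OH, OW = H * scale, W * scale
    r0, r1, fr = _linear_coords(OH, H, scale)
    c0, c1, fc = _linear_coords(OW, W, scale)
    fr_ = fr.astype(x.dtype)[None, None, :, None]
    fc_ = fc.astype(x.dtype)[None, None, None, :]
    rows = x.data[:, :, r0, :] * (1 - fr_) + x.data[:, :, r1, :] * fr_
    out_data = rows[:, :, :, c0] * (1 - fc_) + rows[:, :, :, c1] * fc_

    def bwd(g):
        grows = np.zeros((B, C, OH, W), dtype=g.dtype)
        np.add.at(grows, (slice(None), slice(None), slice(None), c0), g * (1 - fc_))
        np.add.at(grows, (slice(None), slice(None), slice(None), c1), g * fc_)
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), r0, slice(None)), grows * (1 - fr_))
        np.add.at(gx, (slice(None), slice(None), r1, slice(None)), grows * fr_)
        _accum(x, gx)

    return _node(out_data, (x,), bwd)
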