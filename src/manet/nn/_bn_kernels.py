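"""Fused batch-normalization passes (numba-compiled with numpy fallback).

Batch norm touches every activation several times; fusing the statistics,
normalization and backward reductions into single passes keeps the layer
memory-bandwidth-friendly on a single core.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


@njit(fastmath=False)
def _stats_jit(x, mean, var):  # pragma: no cover - compiled
    B, C, H, W = x.shape
    n = B * H * W
    for c in range(C):
        s = 0.0
        for b in range(B):
            for i in range(H):
                row = x[b, c, i]
                for j in range(W):
                    s += row[j]
        m = s / n
        v = 0.0
        for b in range(B):
            for i in range(H):
                row = x[b, c, i]
                for j in range(W):
                    d = row[j] - m
                    v += d * d
        mean[c] = m
        var[c] = v / n


@njit(fastmath=False)
def _fwd_jit(x, mean, invstd, gamma, beta, xhat, out):  # pragma: no cover - compiled
    B, C, H, W = x.shape
    for b in range(B):
        for c in range(C):
            m = mean[c]
            isd = invstd[c]
            g = gamma[c]
            bt = beta[c]
            for i in range(H):
                xr = x[b, c, i]
                hr = xhat[b, c, i]
                orow = out[b, c, i]
                for j in range(W):
                    h = (xr[j] - m) * isd
                    hr[j] = h
                    orow[j] = h * g + bt


@njit(fastmath=False)
def _bwd_jit(g, xhat, scale, s1n, s2n, gx, training):  # pragma: no cover - compiled
    """gx = (g - s2/n - xhat * s1/n) * gamma * invstd (training mode)."""
    B, C, H, W = g.shape
    for b in range(B):
        for c in range(C):
            sc = scale[c]
            a1 = s1n[c]
            a2 = s2n[c]
            for i in range(H):
                gr = g[b, c, i]
                hr = xhat[b, c, i]
                orow = gx[b, c, i]
                for j in range(W):
                    if training:
                        orow[j] = (gr[j] - a2 - hr[j] * a1) * sc
                    else:
                        orow[j] = gr[j] * sc


@njit(fastmath=False)
def _bwd_sums_jit(g, xhat, s1, s2):  # pragma: no cover - compiled
    B, C, H, W = g.shape
    for c in range(C):
        a1 = 0.0
        a2 = 0.0
        for b in range(B):
            for i in range(H):
                gr = g[b, c, i]
                hr = xhat[b, c, i]
                for j in range(W):
                    a1 += gr[j] * hr[j]
                    a2 += gr[j]
        s1[c] = a1
        s2[c] = a2


def have_numba() -> bool:
    return _HAVE_NUMBA
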