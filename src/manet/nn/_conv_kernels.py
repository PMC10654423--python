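"""Compiled im2col / col2im gathers for the convolution ops.

Columns are laid out (K, N) with K = C*KH*KW (channel-major) and
N = B*OH*OW, which makes both the gather reads and writes contiguous per
kernel tap and feeds the GEMM without further transposes.  Zero-padding
is folded into the gather (out-of-range taps read as zero) so a padded
copy of the input is never materialized.  The flat-index loops are
JIT-compiled with numba when it is importable; a numpy slice-loop
fallback covers environments without it.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


@njit(fastmath=False)
def _im2col_jit(xf, B, C, H, W, s, KH, KW, p, OH, OW, cf):  # pragma: no cover - compiled
    N = B * OH * OW
    for c in range(C):
        for ki in range(KH):
            for kj in range(KW):
                k = (c * KH + ki) * KW + kj
                # valid output-column range for this tap
                ow0 = 0 if p <= kj else (p - kj + s - 1) // s
                ow1 = (W - 1 + p - kj) // s + 1
                if ow1 > OW:
                    ow1 = OW
                kbase = k * N
                for b in range(B):
                    pbase = (b * C + c) * H
                    for oh in range(OH):
                        d0 = kbase + (b * OH + oh) * OW
                        ih = oh * s + ki - p
                        if ih < 0 or ih >= H:
                            for ow in range(OW):
                                cf[d0 + ow] = 0.0
                            continue
                        for ow in range(ow0):
                            cf[d0 + ow] = 0.0
                        for ow in range(ow1, OW):
                            cf[d0 + ow] = 0.0
                        s0 = (pbase + ih) * W + kj - p
                        if s == 1:
                            for ow in range(ow0, ow1):
                                cf[d0 + ow] = xf[s0 + ow]
                        else:
                            for ow in range(ow0, ow1):
                                cf[d0 + ow] = xf[s0 + ow * s]


@njit(fastmath=False)
def _col2im_jit(cf, B, C, H, W, s, KH, KW, p, OH, OW, gf):  # pragma: no cover - compiled
    N = B * OH * OW
    for c in range(C):
        for ki in range(KH):
            for kj in range(KW):
                k = (c * KH + ki) * KW + kj
                ow0 = 0 if p <= kj else (p - kj + s - 1) // s
                ow1 = (W - 1 + p - kj) // s + 1
                if ow1 > OW:
                    ow1 = OW
                kbase = k * N
                for b in range(B):
                    pbase = (b * C + c) * H
                    for oh in range(OH):
                        ih = oh * s + ki - p
                        if ih < 0 or ih >= H:
                            continue
                        d0 = kbase + (b * OH + oh) * OW
                        s0 = (pbase + ih) * W + kj - p
                        if s == 1:
                            for ow in range(ow0, ow1):
                                gf[s0 + ow] += cf[d0 + ow]
                        else:
                            for ow in range(ow0, ow1):
                                gf[s0 + ow * s] += cf[d0 + ow]


def im2col(x: np.ndarray, s: int, KH: int, KW: int, p: int, OH: int, OW: int) -> np.ndarray:
    """Unroll (zero-padded) windows of an NCHW input into (C*KH*KW, B*OH*OW)."""
    B, C, H, W = x.shape
    cols = np.empty((C * KH * KW, B * OH * OW), dtype=x.dtype)
    if _HAVE_NUMBA:
        xc = np.ascontiguousarray(x)
        _im2col_jit(xc.reshape(-1), B, C, H, W, s, KH, KW, p, OH, OW, cols.reshape(-1))
        return cols
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    hi = s * (OH - 1) + 1
    wi = s * (OW - 1) + 1
    k = 0
    for c in range(C):
        for ki in range(KH):
            for kj in range(KW):
                cols[k] = xp[:, c, ki:ki + hi:s, kj:kj + wi:s].ravel()
                k += 1
    return cols


def col2im(gcols: np.ndarray, shape, s: int, KH: int, KW: int, p: int, OH: int, OW: int) -> np.ndarray:
    """Scatter-add (C*KH*KW, B*OH*OW) column gradients back onto the input layout."""
    B, C, H, W = shape
    gx = np.zeros(shape, dtype=gcols.dtype)
    if _HAVE_NUMBA:
        _col2im_jit(np.ascontiguousarray(gcols).reshape(-1), B, C, H, W,
                    s, KH, KW, p, OH, OW, gx.reshape(-1))
        return gx
    gxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=gcols.dtype) if p else gx
    hi = s * (OH - 1) + 1
    wi = s * (OW - 1) + 1
    g6 = gcols.reshape(C, KH, KW, B, OH, OW)
    for c in range(C):
        for ki in range(KH):
            for kj in range(KW):
                gxp[:, c, ki:ki + hi:s, kj:kj + wi:s] += g6[c, ki, kj]
    if p:
        gx[:] = gxp[:, :, p:p + H, p:p + W]
    return gx
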