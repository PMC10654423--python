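"""Attention operators against independent scalar-loop oracles and their
algebraic properties (sigmoid range, shape preservation, zero-parameter
neutrality, sequential composition)."""

import numpy as np
import pytest

from manet import nn
from manet.attention import (CBAM, ChannelAttention, SkipConnectionAttentionGate,
                             SpatialAttention)
from manet.errors import ConfigurationError, ShapeContractError
from manet.nn.tensor import no_grad


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# scalar-loop oracles (independent of the package's tensor ops)
# ---------------------------------------------------------------------------

def channel_attention_oracle(x, w1, w2):
    """Eqs. for the channel gate, evaluated loop-wise on [b,c,h,w]."""
    b, c, h, w = x.shape
    att = np.zeros((b, c))
    for bi in range(b):
        mp = np.array([x[bi, ci].max() for ci in range(c)])
        ap = np.array([x[bi, ci].mean() for ci in range(c)])

        def mlp(d):
            hdn = np.maximum(w1 @ d, 0.0)
            return w2 @ hdn

        att[bi] = sigmoid(mlp(mp) + mlp(ap))
    return att[:, :, None, None]


def spatial_attention_oracle(x, kernel):
    """7x7 conv over [max_c, mean_c] maps, zero-padded, then sigmoid."""
    b, c, h, w = x.shape
    k = kernel.shape[-1]
    p = k // 2
    att = np.zeros((b, 1, h, w))
    for bi in range(b):
        desc = np.stack([x[bi].max(axis=0), x[bi].mean(axis=0)])  # (2, h, w)
        padded = np.pad(desc, ((0, 0), (p, p), (p, p)))
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for ch in range(2):
                    for ki in range(k):
                        for kj in range(k):
                            acc += kernel[0, ch, ki, kj] * padded[ch, i + ki, j + kj]
                att[bi, 0, i, j] = sigmoid(acc)
    return att


def scag_oracle(x_sf, x_df, wx, wg, bg, wphi, bphi):
    """Additive gate with stride-2 shallow projection and bilinear upsampling."""
    b, cx, hx, wx_ = x_sf.shape
    _, cg, hg, wg_ = x_df.shape
    inter = wx.shape[0]
    low = np.zeros((b, 1, hg, wg_))
    for bi in range(b):
        px = np.zeros((inter, hg, wg_))
        pg = np.zeros((inter, hg, wg_))
        for i in range(hg):
            for j in range(wg_):
                px[:, i, j] = wx @ x_sf[bi, :, 2 * i, 2 * j]
                pg[:, i, j] = wg @ x_df[bi, :, i, j] + bg
        act = np.maximum(px + pg, 0.0)
        for i in range(hg):
            for j in range(wg_):
                low[bi, 0, i, j] = sigmoid((wphi @ act[:, i, j]).item() + bphi[0].item())
    # bilinear x2, half-pixel centers
    att = np.zeros((b, 1, hx, wx_))
    for i in range(hx):
        si = np.clip((i + 0.5) / 2 - 0.5, 0, hg - 1)
        i0, fi = int(np.floor(si)), si - np.floor(si)
        i1 = min(i0 + 1, hg - 1)
        for j in range(wx_):
            sj = np.clip((j + 0.5) / 2 - 0.5, 0, wg_ - 1)
            j0, fj = int(np.floor(sj)), sj - np.floor(sj)
            j1 = min(j0 + 1, wg_ - 1)
            att[:, 0, i, j] = ((1 - fi) * (1 - fj) * low[:, 0, i0, j0]
                               + (1 - fi) * fj * low[:, 0, i0, j1]
                               + fi * (1 - fj) * low[:, 0, i1, j0]
                               + fi * fj * low[:, 0, i1, j1])
    return att


# ---------------------------------------------------------------------------
# oracle equivalence on small integer-weight problems
# ---------------------------------------------------------------------------

def test_channel_attention_matches_oracle(rng):
    x = rng.normal(size=(2, 4, 3, 3)).astype(np.float32)
    x[:, 1] = 0.0  # an identically-zero channel exercises the pooled descriptors
    ca = ChannelAttention(4, rng=rng)
    w1 = np.arange(8).reshape(2, 4).astype(np.float32) - 3  # small integers
    w2 = (np.arange(8).reshape(4, 2).astype(np.float32) - 4) / 2
    ca.fc1.weight.data = w1.reshape(2, 4, 1, 1)
    ca.fc2.weight.data = w2.reshape(4, 2, 1, 1)
    att, x_ca = ca(nn.as_tensor(x))
    want = channel_attention_oracle(x.astype(np.float64), w1, w2)
    np.testing.assert_allclose(att.data, want, atol=1e-6)
    np.testing.assert_allclose(x_ca.data, x * att.data, atol=1e-6)


def test_spatial_attention_matches_oracle(rng):
    x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
    sa = SpatialAttention(rng=rng)
    kernel = np.zeros((1, 2, 7, 7), dtype=np.float32)
    kernel[0, :, 3, 3] = 1.0  # identity-like center taps on both descriptors
    kernel[0, 0, 2, 3] = -1.0
    sa.conv.weight.data = kernel
    att, x_sa = sa(nn.as_tensor(x))
    want = spatial_attention_oracle(x.astype(np.float64), kernel)
    np.testing.assert_allclose(att.data, want, atol=1e-6)
    np.testing.assert_allclose(x_sa.data, x * att.data, atol=1e-6)


def test_spatial_attention_hot_pixel_identity_kernel():
    """One hot pixel, center-tap kernel: att = sigmoid(2 * descriptor) per pixel."""
    x = np.zeros((1, 1, 4, 4), dtype=np.float32)
    x[0, 0, 1, 2] = 3.0
    sa = SpatialAttention()
    kernel = np.zeros((1, 2, 7, 7), dtype=np.float32)
    kernel[0, :, 3, 3] = 1.0
    sa.conv.weight.data = kernel
    att, _ = sa(nn.as_tensor(x))
    # single channel: max map == mean map == x, so the response is 2x
    np.testing.assert_allclose(att.data[0, 0], sigmoid(2.0 * x[0, 0]), atol=1e-6)


def test_scag_matches_oracle_on_toy_grid(rng):
    x_sf = rng.integers(-3, 4, size=(1, 2, 4, 4)).astype(np.float32)
    x_df = rng.integers(-3, 4, size=(1, 2, 2, 2)).astype(np.float32)
    gate = SkipConnectionAttentionGate(2, 2, rng=rng)
    wx = np.array([[1.0, -1.0]], dtype=np.float32)
    wg = np.array([[2.0, 1.0]], dtype=np.float32)
    bg = np.array([0.5], dtype=np.float32)
    wphi = np.array([[1.5]], dtype=np.float32)
    bphi = np.array([-0.25], dtype=np.float32)
    gate.theta_x.weight.data = wx.reshape(1, 2, 1, 1)
    gate.phi_g.weight.data = wg.reshape(1, 2, 1, 1)
    gate.phi_g.bias.data = bg
    gate.psi.weight.data = wphi.reshape(1, 1, 1, 1)
    gate.psi.bias.data = bphi
    att, x_scag = gate(nn.as_tensor(x_sf), nn.as_tensor(x_df))
    want = scag_oracle(x_sf.astype(np.float64), x_df.astype(np.float64),
                       wx, wg, bg, wphi, bphi)
    np.testing.assert_allclose(att.data, want, atol=1e-6)
    np.testing.assert_allclose(x_scag.data, x_sf * want, atol=1e-5)
    assert x_scag.shape == x_sf.shape


# ---------------------------------------------------------------------------
# neutrality, composition, invariants
# ---------------------------------------------------------------------------

def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


def test_zero_parameter_neutrality(rng):
    x = rng.normal(size=(2, 4, 6, 6)).astype(np.float32)
    ca = ChannelAttention(4, rng=rng); _zero_params(ca)
    sa = SpatialAttention(rng=rng); _zero_params(sa)
    gate = SkipConnectionAttentionGate(4, 8, rng=rng); _zero_params(gate)
    cb = CBAM(4, rng=rng); _zero_params(cb)
    att, x_ca = ca(nn.as_tensor(x))
    assert np.all(att.data == np.float32(0.5)) and np.array_equal(x_ca.data, 0.5 * x)
    att, x_sa = sa(nn.as_tensor(x))
    assert np.all(att.data == np.float32(0.5)) and np.array_equal(x_sa.data, 0.5 * x)
    g = rng.normal(size=(2, 8, 3, 3)).astype(np.float32)
    att, x_sc = gate(nn.as_tensor(x), nn.as_tensor(g))
    assert np.all(att.data == np.float32(0.5)) and np.array_equal(x_sc.data, 0.5 * x)
    out = cb(nn.as_tensor(x))
    assert np.array_equal(out.data, 0.25 * x)


def test_cbam_is_exact_composition(rng):
    x = rng.normal(size=(2, 6, 5, 5)).astype(np.float32)
    cb = CBAM(6, rng=np.random.default_rng(7))
    _, x_ca = cb.channel(nn.as_tensor(x))
    _, x_sa = cb.spatial(x_ca)
    out = cb(nn.as_tensor(x))
    assert np.array_equal(out.data, x_sa.data)  # bit-identical


def test_attention_maps_strictly_in_unit_interval(rng):
    # moderate activations: strict (0,1) holds until float32 saturates
    x = rng.normal(size=(1, 8, 7, 7)).astype(np.float32)
    ca = ChannelAttention(8, rng=rng)
    sa = SpatialAttention(rng=rng)
    for att in (ca(nn.as_tensor(x))[0], sa(nn.as_tensor(x))[0]):
        assert np.all(att.data > 0.0) and np.all(att.data < 1.0)


def test_channel_attention_permutation_equivariance(rng):
    x = rng.normal(size=(1, 6, 4, 4)).astype(np.float32)
    perm = np.array([3, 0, 5, 1, 4, 2])
    ca = ChannelAttention(6, rng=np.random.default_rng(3))
    att, _ = ca(nn.as_tensor(x))
    ca_p = ChannelAttention(6, rng=np.random.default_rng(4))
    ca_p.fc1.weight.data = ca.fc1.weight.data[:, perm]      # permute input side
    ca_p.fc2.weight.data = ca.fc2.weight.data[perm]         # permute output side
    att_p, _ = ca_p(nn.as_tensor(x[:, perm]))
    np.testing.assert_allclose(att_p.data[:, :, 0, 0], att.data[:, perm, 0, 0], atol=1e-6)


def test_shape_preservation_at_published_extents():
    """Channel/CBAM/SCAG at the full-size layer extents keep shapes exactly."""
    rng = np.random.default_rng(0)
    with no_grad():
        x = rng.normal(size=(2, 68, 512, 512)).astype(np.float32)
        att, x_ca = ChannelAttention(68, rng=rng)(nn.Tensor(x))
        assert att.shape == (2, 68, 1, 1) and x_ca.shape == (2, 68, 512, 512)
        del x, x_ca
        xb = rng.normal(size=(1, 544, 64, 64)).astype(np.float32)
        out = CBAM(544, rng=rng)(nn.Tensor(xb))
        assert out.shape == (1, 544, 64, 64)
        del xb, out
        sf = rng.normal(size=(1, 272, 128, 128)).astype(np.float32)
        df = rng.normal(size=(1, 544, 64, 64)).astype(np.float32)
        att, gated = SkipConnectionAttentionGate(272, 544, rng=rng)(nn.Tensor(sf), nn.Tensor(df))
        assert gated.shape == (1, 272, 128, 128)
        assert att.shape == (1, 1, 128, 128)


# ---------------------------------------------------------------------------
# error contracts
# ---------------------------------------------------------------------------

def test_odd_channel_count_rejected():
    with pytest.raises(ConfigurationError, match="c=5"):
        ChannelAttention(5)
    with pytest.raises(ConfigurationError, match="c=7"):
        SkipConnectionAttentionGate(7, 4)
    # explicit hidden width lifts the restriction
    assert ChannelAttention(5, hidden=2).hidden == 2


def test_non_finite_input_raises():
    x = np.ones((1, 4, 3, 3), dtype=np.float32)
    x[0, 0, 0, 0] = np.nan
    with pytest.raises(FloatingPointError):
        ChannelAttention(4)(nn.as_tensor(x))


def test_scag_extent_mismatch_reports_both_extents():
    gate = SkipConnectionAttentionGate(4, 8)
    sf = np.zeros((1, 4, 8, 8), dtype=np.float32)
    df = np.zeros((1, 8, 2, 2), dtype=np.float32)  # wrong: should be 4x4
    with pytest.raises(ShapeContractError, match=r"\(4, 4\).*\(2, 2\)"):
        gate(nn.as_tensor(sf), nn.as_tensor(df))
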