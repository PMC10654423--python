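"""Attention operators for feature recalibration in the segmentation network.

Four mechanisms are provided, all shape-preserving:

* :class:`ChannelAttention` — per-channel gating.  Global max- and
  average-pooled descriptors are passed through a *shared* two-layer
  perceptron (hidden width ``c/2``, no biases, ReLU between the layers);
  the sigmoid of the summed branch outputs gates each channel.
* :class:`SpatialAttention` — per-pixel gating.  Channel-wise max and mean
  maps are concatenated (2 channels) and convolved with a single 7x7
  kernel; the sigmoid of the response gates every spatial location.
* :class:`CBAM` — the sequential composition: channel attention first,
  spatial attention on the recalibrated result.
* :class:`SkipConnectionAttentionGate` (SCAG) — an additive attention gate
  on the encoder-to-decoder skip path.  Shallow features (the skip) and a
  deep gating signal are each projected to ``c_x/2`` channels by 1x1
  convolutions — the shallow path bias-free and stride-2 so both land at
  the gate resolution — summed, passed through ReLU, reduced to a single
  channel (with bias), and squashed by a sigmoid.  The resulting map is
  upsampled bilinearly back to the skip resolution and multiplies the
  shallow features.

Every attention map is a sigmoid output, hence strictly inside (0, 1) for
finite inputs, and zero-valued parameters make each gate exactly 0.5.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeContractError


def _check_finite_descriptor(arr: np.ndarray, where: str):
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"non-finite activations entering {where}")


def _require_even(c: int, what: str) -> int:
    if c % 2:
        raise ConfigurationError(
            f"{what} requires an even channel count so the hidden width c/2 is exact; got c={c}"
        )
    return c // 2


class ChannelAttention(nn.Module):
    """Channel gate from globally pooled descriptors through a shared MLP.

    Parameters
    ----------
    channels : input channel count ``c``.
    hidden : hidden width of the shared MLP.  Defaults to ``c // 2``, in
        which case ``c`` must be even.
    """

    def __init__(self, channels, hidden=None, rng=None):
        super().__init__()
        self.channels = int(channels)
        if hidden is None:
            hidden = _require_even(self.channels, "channel attention")
        self.hidden = int(hidden)
        rng = rng or np.random.default_rng(0)
        # shared MLP realised as 1x1 convolutions on [b, c, 1, 1] descriptors
        self.fc1 = nn.Conv2d(self.channels, self.hidden, 1, bias=False, rng=rng)
        self.fc2 = nn.Conv2d(self.hidden, self.channels, 1, bias=False, rng=rng)

    def _mlp(self, d):
        return self.fc2(nn.relu(self.fc1(d)))

    def attention(self, x):
        c_mp = nn.global_max_pool(x)
        c_ap = nn.global_avg_pool(x)
        _check_finite_descriptor(c_mp.data, "channel attention")
        return nn.sigmoid(nn.add(self._mlp(c_mp), self._mlp(c_ap)))

    def forward(self, x):
        att = self.attention(x)
        return att, nn.mul(x, att)


class SpatialAttention(nn.Module):
    """Spatial gate from channel-pooled maps through one 7x7 convolution."""

    def __init__(self, kernel_size=7, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv = nn.Conv2d(2, 1, kernel_size, padding=kernel_size // 2, bias=False, rng=rng)

    def attention(self, x):
        s_mp = nn.channel_max(x)
        s_ap = nn.channel_mean(x)
        return nn.sigmoid(self.conv(nn.concat([s_mp, s_ap], axis=1)))

    def forward(self, x):
        att = self.attention(x)
        return att, nn.mul(x, att)


class CBAM(nn.Module):
    """Channel attention followed sequentially by spatial attention."""

    def __init__(self, channels, hidden=None, rng=None):
        super().__init__()
        self.channel = ChannelAttention(channels, hidden=hidden, rng=rng)
        self.spatial = SpatialAttention(rng=rng)

    def forward(self, x):
        _, x_ca = self.channel(x)
        _, x_sa = self.spatial(x_ca)
        return x_sa


class SkipConnectionAttentionGate(nn.Module):
    """Additive attention gate on the skip connection (SCAG).

    ``gate_stride=2`` (the default) matches the usual topology in which the
    deep gating signal lives one resolution level below the skip features:
    the shallow projection is a stride-2 1x1 convolution and the attention
    map is bilinearly upsampled back before gating.  ``gate_stride=1``
    supports same-resolution gating.
    """

    def __init__(self, skip_channels, gate_channels, inter_channels=None,
                 gate_stride=2, rng=None):
        super().__init__()
        self.skip_channels = int(skip_channels)
        self.gate_channels = int(gate_channels)
        if inter_channels is None:
            inter_channels = _require_even(self.skip_channels, "skip-connection attention gate")
        self.inter_channels = int(inter_channels)
        self.gate_stride = int(gate_stride)
        rng = rng or np.random.default_rng(0)
        # shallow path carries no bias; gate path and the reduction do
        self.theta_x = nn.Conv2d(self.skip_channels, self.inter_channels, 1,
                                 stride=self.gate_stride, padding=0, bias=False, rng=rng)
        self.phi_g = nn.Conv2d(self.gate_channels, self.inter_channels, 1,
                               padding=0, bias=True, rng=rng)
        self.psi = nn.Conv2d(self.inter_channels, 1, 1, padding=0, bias=True, rng=rng)

    def attention(self, x_sf, x_df):
        px = self.theta_x(x_sf)
        pg = self.phi_g(x_df)
        if px.shape[2:] != pg.shape[2:]:
            raise ShapeContractError(
                "projected skip and gate extents differ: "
                f"{px.shape[2:]} (skip after stride {self.gate_stride}) vs {pg.shape[2:]} (gate)"
            )
        att = nn.sigmoid(self.psi(nn.relu(nn.add(px, pg))))
        if self.gate_stride != 1:
            att = nn.upsample_bilinear(att, scale=self.gate_stride)
        if att.shape[2:] != x_sf.shape[2:]:
            raise ShapeContractError(
                f"attention map extent {att.shape[2:]} does not match skip extent {x_sf.shape[2:]}"
            )
        return att

    def forward(self, x_sf, x_df):
        att = self.attention(x_sf, x_df)
        return att, nn.mul(x_sf, att)


# -- functional views (thin wrappers over the modules) ----------------------

def channel_attention(x, params: ChannelAttention):
    """Return ``(attention_map, recalibrated)`` for a feature map ``x``."""
    return params(nn.as_tensor(x))


def spatial_attention(x, params: SpatialAttention):
    return params(nn.as_tensor(x))


def cbam(x, params: CBAM):
    return params(nn.as_tensor(x))


def scag(x_sf, x_df, params: SkipConnectionAttentionGate):
    return params(nn.as_tensor(x_sf), nn.as_tensor(x_df))
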