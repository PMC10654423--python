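"""Multi-attention residual encoder–decoder network (MANet) assembly.

Topology (defaults):

* Encoder of residual blocks with widths 68 / 136 / 272; every spatial
  downsampling is a stride-2 first convolution inside a block — there are
  no pooling layers on the encoder path.  Each encoder output passes
  through channel attention before feeding both the skip connection and
  the next block.
* Bridge: residual block to width 544 (stride 2) followed by CBAM.
* Decoder: each stage upsamples the deep features with a 2x2 stride-2
  transposed convolution (halving their channel count; the final stage
  keeps its 68 channels and the halving is deferred to the last 3x3
  convolution, 68 -> 34), applies spatial attention to the upsampled
  features, gates the corresponding encoder skip with a skip-connection
  attention gate driven by the pre-upsampling deep features, concatenates,
  and runs two 3x3 conv+BN+ReLU layers.
* Head: 1x1 convolution to ``out_channels`` followed by a sigmoid, so the
  output is a per-pixel probability field.

A variant factory covers the ablation grid: plain U-Net, residual blocks
only, and every single-attention / all-attention combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np

from . import nn
from .attention import CBAM, ChannelAttention, SkipConnectionAttentionGate, SpatialAttention
from .errors import ConfigurationError, ShapeContractError

VARIANTS = (
    "unet",
    "unet_rb",
    "unet_rb_scag",
    "unet_rb_ca",
    "unet_rb_sa",
    "unet_rb_cbam",
    "unet_all_attn",
    "manet",
)

_VARIANT_FLAGS = {
    # variant: (residual, scag, ca, sa, cbam)
    "unet": (False, False, False, False, False),
    "unet_rb": (True, False, False, False, False),
    "unet_rb_scag": (True, True, False, False, False),
    "unet_rb_ca": (True, False, True, False, False),
    "unet_rb_sa": (True, False, False, True, False),
    "unet_rb_cbam": (True, False, False, False, True),
    "unet_all_attn": (False, True, True, True, True),
    "manet": (True, True, True, True, True),
}


@dataclass
class ArchitectureConfig:
    """Widths, depth and variant flags defining one buildable network."""

    in_channels: int = 3
    out_channels: int = 3
    encoder_widths: Tuple[int, ...] = (68, 136, 272)
    bridge_width: int = 544
    decoder_widths: Tuple[int, ...] = (136, 68, 68)
    final_width: int = 34
    variant: str = "manet"
    strict_even: bool = True

    def __post_init__(self):
        self.encoder_widths = tuple(int(w) for w in self.encoder_widths)
        self.decoder_widths = tuple(int(w) for w in self.decoder_widths)
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if len(self.decoder_widths) != len(self.encoder_widths):
            raise ConfigurationError("decoder depth must equal encoder depth")
        if self.strict_even:
            for w in (*self.encoder_widths, self.bridge_width, *self.decoder_widths):
                if w % 2:
                    raise ConfigurationError(
                        f"odd channel width {w}: attention hidden widths c/2 would not be "
                        "integral (set strict_even=False to floor-halve)"
                    )

    @property
    def flags(self):
        return dict(zip(("residual", "scag", "ca", "sa", "cbam"), _VARIANT_FLAGS[self.variant]))

    @property
    def depth(self) -> int:
        """Number of stride-2 downsamplings (encoder stages beyond the first, plus bridge)."""
        return len(self.encoder_widths)

    @classmethod
    def reduced(cls, base_width=17, **overrides):
        """A scaled-down configuration for CPU-sized experiments.

        ``base_width=17`` is one quarter of the default widths:
        encoder [17, 34, 68], bridge 136, decoder [34, 17, 17].
        """
        b = int(base_width)
        cfg = dict(
            encoder_widths=(b, 2 * b, 4 * b),
            bridge_width=8 * b,
            decoder_widths=(2 * b, b, b),
            final_width=max(b // 2, 1),
            strict_even=b % 2 == 0,
        )
        cfg.update(overrides)
        return cls(**cfg)

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def _half(c: int, strict: bool, what: str) -> int:
    if c % 2 and strict:
        raise ConfigurationError(f"odd channel width {c} in {what}")
    return max(c // 2, 1)


class _ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, k, stride, rng):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return nn.relu(self.bn(self.conv(x)))


class EncoderBlock(nn.Module):
    """Two 3x3 convolutions, optionally with a projected residual connection.

    Downsampling happens via stride 2 on the first convolution.  On the
    residual path a 1x1 convolution (with batch norm, no ReLU before the
    addition) matches channels and stride; the final ReLU follows the sum.
    """

    def __init__(self, cin, cout, stride, residual, rng):
        super().__init__()
        self.residual = residual
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        if residual:
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, padding=0, rng=rng)
            self.bn_proj = nn.BatchNorm2d(cout)

    def forward(self, x):
        h = nn.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        if self.residual:
            h = nn.add(h, self.bn_proj(self.proj(x)))
            return nn.relu(h)
        return nn.relu(h)


class DecoderStage(nn.Module):
    """Upsample, attend, gate the skip, concatenate, and convolve twice."""

    def __init__(self, cin, up_c, skip_c, gate_c, w1, w2, flags, strict, rng):
        super().__init__()
        self.up = nn.ConvTranspose2d(cin, up_c, 2, 2, rng=rng)
        self.bn_up = nn.BatchNorm2d(up_c)
        self.sa = SpatialAttention(rng=rng) if flags["sa"] else None
        self.scag = (
            SkipConnectionAttentionGate(
                skip_c, gate_c, inter_channels=_half(skip_c, strict, "SCAG"), rng=rng
            )
            if flags["scag"]
            else None
        )
        self.conv1 = _ConvBNReLU(up_c + skip_c, w1, 3, 1, rng)
        self.conv2 = _ConvBNReLU(w1, w2, 3, 1, rng)

    def forward(self, deep, skip, cap=None, tag=""):
        up = nn.relu(self.bn_up(self.up(deep)))
        if cap is not None:
            cap[f"{tag}.up"] = up.data
        if self.sa is not None:
            _, up = self.sa(up)
            if cap is not None:
                cap[f"{tag}.sa"] = up.data
        if self.scag is not None:
            att, skip = self.scag(skip, deep)
            if cap is not None:
                cap[f"{tag}.scag_att"] = att.data
                cap[f"{tag}.scag"] = skip.data
        h = nn.concat([up, skip], axis=1)
        return self.conv2(self.conv1(h))


class MANet(nn.Module):
    """The assembled encoder–bridge–decoder network."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.capture = False      # when True, forward() records intermediates
        self.captured = {}
        rng = np.random.default_rng(seed)
        f = config.flags
        strict = config.strict_even
        enc = config.encoder_widths
        dec = config.decoder_widths

        self.encoders = []
        cin = config.in_channels
        for i, w in enumerate(enc):
            self.encoders.append(EncoderBlock(cin, w, 1 if i == 0 else 2, f["residual"], rng))
            cin = w
        self.channel_attn = (
            [ChannelAttention(w, hidden=_half(w, strict, "channel attention"), rng=rng) for w in enc]
            if f["ca"]
            else None
        )
        self.bridge = EncoderBlock(enc[-1], config.bridge_width, 2, f["residual"], rng)
        self.cbam = (
            CBAM(config.bridge_width, hidden=_half(config.bridge_width, strict, "CBAM"), rng=rng)
            if f["cbam"]
            else None
        )

        skips = tuple(reversed(enc))                      # encoder outputs, deep to shallow
        gates = (config.bridge_width,) + dec[:-1]         # deep features gating each stage
        prev = config.bridge_width
        self.decoders = []
        for k, (skip_c, gate_c) in enumerate(zip(skips, gates)):
            last = k == len(skips) - 1
            up_c = prev if last else _half(prev, strict, "transposed convolution")
            w1 = dec[k]
            w2 = config.final_width if last else dec[k]
            self.decoders.append(
                DecoderStage(prev, up_c, skip_c, gate_c, w1, w2, f, strict, rng)
            )
            prev = w2
        self.head = nn.Conv2d(config.final_width, config.out_channels, 1, padding=0, rng=rng)

    # ------------------------------------------------------------------
    def forward(self, x):
        x = nn.as_tensor(x)
        b, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ShapeContractError(
                f"input has {c} channels, network expects {self.config.in_channels}"
            )
        div = 2 ** self.config.depth
        if h % div or w % div:
            raise ShapeContractError(
                f"spatial extent {h}x{w} must be divisible by {div}"
            )
        cap = self.captured if self.capture else None
        skips = []
        for i, block in enumerate(self.encoders):
            x = block(x)
            if cap is not None:
                cap[f"encoder{i+1}"] = x.data
            if self.channel_attn is not None:
                _, x = self.channel_attn[i](x)
                if cap is not None:
                    cap[f"encoder{i+1}.ca"] = x.data
            skips.append(x)
        x = self.bridge(x)
        if cap is not None:
            cap["bridge"] = x.data
        if self.cbam is not None:
            x = self.cbam(x)
            if cap is not None:
                cap["bridge.cbam"] = x.data
        for k, (stage, skip) in enumerate(zip(self.decoders, reversed(skips))):
            x = stage(x, skip, cap=cap, tag=f"decoder{k+1}")
            if cap is not None:
                cap[f"decoder{k+1}"] = x.data
        out = nn.sigmoid(self.head(x))
        if cap is not None:
            cap["output"] = out.data
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass in evaluation mode (no graph), returning a probability field."""
        self.eval()
        from .nn.tensor import no_grad

        with no_grad():
            return self.forward(np.asarray(x, dtype=nn.DEFAULT_DTYPE)).data


def build_model(config: Optional[ArchitectureConfig] = None, seed: int = 0, **overrides) -> MANet:
    """Build a network from a configuration (defaults reproduce the full model)."""
    if config is None:
        config = ArchitectureConfig(**overrides)
    elif overrides:
        config = ArchitectureConfig(**{**config.to_dict(), **overrides})
    return MANet(config, seed=seed)


def count_parameters(net: MANet) -> int:
    """Exact count of trainable scalars (convolutions, attention, BN affine)."""
    return net.num_parameters()


# ---------------------------------------------------------------------------
# layer trace and MAC accounting
# ---------------------------------------------------------------------------

@dataclass
class TraceRow:
    block: str
    name: str
    kernel: Tuple[int, int]
    filters: int
    stride: int
    out_size: Tuple[int, int, int]  # (w, h, c)

    def astuple(self):
        return (self.block, self.name, self.kernel, self.filters, self.stride, self.out_size)


@dataclass
class LayerTrace:
    rows: List[TraceRow] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "block": r.block,
                    "operation": r.name,
                    "filter_size": f"{r.kernel[0]} x {r.kernel[1]}",
                    "filters": r.filters,
                    "stride": r.stride,
                    "output_size": f"{r.out_size[0]} x {r.out_size[1]} x {r.out_size[2]}",
                }
                for r in self.rows
            ]
        )


def trace_layers(net: MANet, input_extent: int = 512) -> LayerTrace:
    """Main-path convolution trace: one row per numbered convolution.

    Mirrors the published layer table: the two convolutions of each encoder
    block, the bridge, the decoder blocks, and the 1x1 output head, with
    their filter counts, strides and output extents.  Residual projections
    and attention-internal convolutions are not main-path rows.
    """
    cfg = net.config
    div = 2 ** cfg.depth
    if input_extent % div:
        raise ShapeContractError(f"input extent {input_extent} not divisible by {div}")
    rows: List[TraceRow] = []
    n = 1
    ext = input_extent
    for i, w in enumerate(cfg.encoder_widths):
        stride = 1 if i == 0 else 2
        ext //= stride
        rows.append(TraceRow(f"Encoder {i+1}", f"Conv {n}", (3, 3), w, stride, (ext, ext, w))); n += 1
        rows.append(TraceRow(f"Encoder {i+1}", f"Conv {n}", (3, 3), w, 1, (ext, ext, w))); n += 1
    ext //= 2
    bw = cfg.bridge_width
    rows.append(TraceRow("Bridge", f"Conv {n}", (3, 3), bw, 2, (ext, ext, bw))); n += 1
    rows.append(TraceRow("Bridge", f"Conv {n}", (3, 3), bw, 1, (ext, ext, bw))); n += 1
    for k, stage in enumerate(net.decoders):
        ext *= 2
        w1 = stage.conv1.conv.out_channels
        w2 = stage.conv2.conv.out_channels
        rows.append(TraceRow(f"Decoder {k+1}", f"Conv {n}", (3, 3), w1, 1, (ext, ext, w1))); n += 1
        rows.append(TraceRow(f"Decoder {k+1}", f"Conv {n}", (3, 3), w2, 1, (ext, ext, w2))); n += 1
    rows.append(TraceRow("Output", f"Conv {n}", (1, 1), cfg.out_channels, 1,
                         (ext, ext, cfg.out_channels)))
    return LayerTrace(rows)


def _mac_items(net: MANet, input_extent: int) -> List[Tuple[str, int]]:
    """Per-layer multiply–accumulate counts for conv / transposed-conv / linear maps.

    Convention: ``kernel_elements * c_in * c_out * output_positions`` per
    layer (transposed convolutions included, counted at their output
    resolution); normalization, activations and pooling are free.
    """
    cfg = net.config
    items: List[Tuple[str, int]] = []
    ext = input_extent

    def conv_macs(tag, cin, cout, k, pos):
        items.append((tag, k * k * cin * cout * pos))

    cin = cfg.in_channels
    for i, (block, w) in enumerate(zip(net.encoders, cfg.encoder_widths)):
        stride = 1 if i == 0 else 2
        ext //= stride
        pos = ext * ext
        conv_macs(f"enc{i+1}.conv1", cin, w, 3, pos)
        conv_macs(f"enc{i+1}.conv2", w, w, 3, pos)
        if block.residual:
            conv_macs(f"enc{i+1}.proj", cin, w, 1, pos)
        if net.channel_attn is not None:
            ca = net.channel_attn[i]
            items.append((f"enc{i+1}.ca", 2 * 2 * ca.channels * ca.hidden))
        cin = w
    ext //= 2
    pos = ext * ext
    conv_macs("bridge.conv1", cin, cfg.bridge_width, 3, pos)
    conv_macs("bridge.conv2", cfg.bridge_width, cfg.bridge_width, 3, pos)
    if net.bridge.residual:
        conv_macs("bridge.proj", cin, cfg.bridge_width, 1, pos)
    if net.cbam is not None:
        items.append(("bridge.cbam.ca", 2 * 2 * net.cbam.channel.channels * net.cbam.channel.hidden))
        conv_macs("bridge.cbam.sa", 2, 1, 7, pos)

    for k, stage in enumerate(net.decoders):
        gate_pos = ext * ext
        ext *= 2
        pos = ext * ext
        up = stage.up
        conv_macs(f"dec{k+1}.up", up.in_channels, up.out_channels, up.kernel_size, pos)
        if stage.sa is not None:
            conv_macs(f"dec{k+1}.sa", 2, 1, 7, pos)
        if stage.scag is not None:
            g = stage.scag
            conv_macs(f"dec{k+1}.scag.theta_x", g.skip_channels, g.inter_channels, 1, gate_pos)
            conv_macs(f"dec{k+1}.scag.phi_g", g.gate_channels, g.inter_channels, 1, gate_pos)
            conv_macs(f"dec{k+1}.scag.psi", g.inter_channels, 1, 1, gate_pos)
        c1, c2 = stage.conv1.conv, stage.conv2.conv
        conv_macs(f"dec{k+1}.conv1", c1.in_channels, c1.out_channels, 3, pos)
        conv_macs(f"dec{k+1}.conv2", c2.in_channels, c2.out_channels, 3, pos)
    conv_macs("head", cfg.final_width, cfg.out_channels, 1, ext * ext)
    return items


def count_macs(net: MANet, input_extent: int = 512) -> int:
    """Total multiply–accumulate operations for one forward pass (batch 1)."""
    return int(sum(m for _, m in _mac_items(net, input_extent)))
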