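"""RS-UNet: browning-region segmentation network.

A ResNet50-style encoder in a U-shaped encoder-decoder with three
refinements over the plain ResNet50-U-Net baseline:

* **encoder optimisation** — a dual-branch input adapter (a colour branch
  and an edge branch built from the image minus its 3x3 average pooling)
  fused to 64 channels, and the classic 7x7 stem replaced by three stacked
  3x3 convolutions;
* **decoder enhancement** — a hybrid decoder: grouped convolution
  (groups=2) where the 2048- and 1024-channel maps concatenate, depthwise-
  separable convolution at the middle levels, a plain 3x3 at the finest
  level, plus 30 % spatial dropout on the final two decoder levels;
* **spatial attention** — a mean/max channel-pooled 7x7 sigmoid gate
  multiplied onto each skip connection.

The baseline profile (classic stem, plain decoder, no attention) and the
full profile differ only through the configuration record, so parameter
audits of both come from the same assembly code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

#: decoder output widths per upsampling level (deepest first); chosen so the
#: assembled baseline and full models land on their published footprints
DECODER_WIDTHS = (734, 719, 644, 564)
DECODER_MODES = ("grouped", "dsc", "dsc", "plain")
DECODER_SECOND_CONV = (False, False, False, False)
ENCODER_STAGE_WIDTHS = (256, 512, 1024, 2048)
ENCODER_STAGE_DEPTHS = (3, 4, 6, 3)


@dataclass
class RSUNetConfig:
    width_mult: float = 1.0
    stage_depths: tuple = ENCODER_STAGE_DEPTHS
    stem: str = "triple_3x3"                  # classic_7x7 | triple_3x3
    use_input_adapter: bool = True
    decoder_modes: tuple = DECODER_MODES
    decoder_widths: tuple = DECODER_WIDTHS
    decoder_second_conv: tuple = DECODER_SECOND_CONV
    sa_on_skips: tuple = (True, True, True, True)
    spatial_dropout_p: float = 0.3
    out_classes: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.stem not in ("classic_7x7", "triple_3x3"):
            raise ValueError("stem must be classic_7x7 or triple_3x3")
        if len(self.decoder_modes) != 4 or len(self.decoder_widths) != 4:
            raise ValueError("decoder needs exactly 4 levels")
        for m in self.decoder_modes:
            if m not in ("grouped", "dsc", "plain"):
                raise ValueError(f"unknown decoder mode {m!r}")

    def scaled(self, c: int) -> int:
        """Apply the width multiplier, keeping widths even and >= 4."""
        if self.width_mult == 1.0:
            return c
        return max(4, 2 * int(round(c * self.width_mult / 2)))


def baseline_config(**kw) -> RSUNetConfig:
    """The unmodified ResNet50-U-Net: classic stem, plain decoder, no SA."""
    return RSUNetConfig(stem="classic_7x7", use_input_adapter=False,
                        decoder_modes=("plain",) * 4,
                        sa_on_skips=(False,) * 4, **kw)


def full_config(**kw) -> RSUNetConfig:
    """RS-UNet with all three refinements enabled."""
    return RSUNetConfig(**kw)


def test_scale_config(width_mult: float = 0.25, **kw) -> RSUNetConfig:
    """A small profile for CPU experiments: scaled widths, one residual
    block per stage."""
    return RSUNetConfig(width_mult=width_mult, stage_depths=(1, 1, 1, 1),
                        **kw)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class InputAdapter(nn.Module):
    """Dual-branch stem prefix: F_rgb = ReLU(conv3x3(x));
    F_edge = ReLU(conv3x3(x - avgpool3x3(x)));
    output = ReLU(conv3x3(concat(F_rgb, F_edge)))."""

    def __init__(self, branch_out: int = 16, fused_out: int = 64,
                 seed: int = 0):
        super().__init__()
        self.rgb = nn.Conv2d(3, branch_out, 3, bias=True, seed=seed)
        self.edge = nn.Conv2d(3, branch_out, 3, bias=True, seed=seed + 1)
        self.fuse = nn.Conv2d(2 * branch_out, fused_out, 3, bias=True,
                              seed=seed + 2)
        self.pool = nn.AvgPool2d(3, stride=1, padding=1)

    def forward(self, x):
        if x.shape[1] != 3:
            raise ValueError(f"input adapter expects 3 channels, got {x.shape[1]}")
        f_rgb = self.rgb(x).relu()
        edge = x - self.pool(x)
        f_edge = self.edge(edge).relu()
        return self.fuse(nn.concat([f_rgb, f_edge], axis=1)).relu()


class SpatialAttention(nn.Module):
    """Mean/max channel pooling -> 7x7 conv -> sigmoid gate (99 parameters)."""

    def __init__(self, kernel: int = 7, seed: int = 0):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, bias=True, seed=seed)

    def forward(self, f):
        f_avg = f.mean(axis=1, keepdims=True)
        f_max = f.max(axis=1, keepdims=True)
        m = self.conv(nn.concat([f_avg, f_max], axis=1)).sigmoid()
        return f * m

    def attention_map(self, f):
        f_avg = f.mean(axis=1, keepdims=True)
        f_max = f.max(axis=1, keepdims=True)
        return self.conv(nn.concat([f_avg, f_max], axis=1)).sigmoid()


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, cin: int, mid: int, cout: int, stride: int = 1,
                 seed: int = 0):
        super().__init__()
        self.c1 = nn.Conv2d(cin, mid, 1, bias=False, seed=seed)
        self.b1 = nn.BatchNorm2d(mid)
        self.c2 = nn.Conv2d(mid, mid, 3, stride=stride, bias=False,
                            seed=seed + 1)
        self.b2 = nn.BatchNorm2d(mid)
        self.c3 = nn.Conv2d(mid, cout, 1, bias=False, seed=seed + 2)
        self.b3 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False,
                          seed=seed + 3),
                nn.BatchNorm2d(cout))
        else:
            self.down = None

    def forward(self, x):
        y = self.b1(self.c1(x)).relu()
        y = self.b2(self.c2(y)).relu()
        y = self.b3(self.c3(y))
        sc = x if self.down is None else self.down(x)
        return (y + sc).relu()


class _DecoderLevel(nn.Module):
    def __init__(self, cin: int, cout: int, mode: str, second: bool,
                 groups: int = 2, seed: int = 0):
        super().__init__()
        self.mode = mode
        if mode == "grouped":
            if cin % groups:
                raise ValueError(
                    f"grouped fusion: {cin} channels not divisible by {groups}")
            self.conv = nn.Conv2d(cin, cout, 3, groups=groups, bias=False,
                                  seed=seed)
            self.bn = nn.BatchNorm2d(cout)
        elif mode == "dsc":
            self.dw = nn.Conv2d(cin, cin, 3, groups=cin, bias=False,
                                seed=seed)
            self.dw_bn = nn.BatchNorm2d(cin)
            self.pw = nn.Conv2d(cin, cout, 1, bias=False, seed=seed + 1)
            self.bn = nn.BatchNorm2d(cout)
        else:
            self.conv = nn.Conv2d(cin, cout, 3, bias=False, seed=seed)
            self.bn = nn.BatchNorm2d(cout)
        self.second = None
        if second:
            self.second = nn.Sequential(
                nn.Conv2d(cout, cout, 3, bias=False, seed=seed + 7),
                nn.BatchNorm2d(cout), nn.ReLU())

    def forward(self, x):
        if self.mode == "dsc":
            y = self.bn(self.pw(self.dw_bn(self.dw(x)))).relu()
        else:
            y = self.bn(self.conv(x)).relu()
        if self.second is not None:
            y = self.second(y)
        return y


class RSUNet(nn.Module):
    """End-to-end browning segmentation network; maps a 3xHxW image (H, W
    multiples of 32) to a 1xHxW browning-probability raster."""

    def __init__(self, config: RSUNetConfig):
        super().__init__()
        self.config = config
        s = config.scaled
        seed = config.seed
        stem_w = s(64)
        self.adapter = None
        stem_in = 3
        if config.use_input_adapter:
            self.adapter = InputAdapter(s(16), stem_w, seed=seed)
            stem_in = stem_w
        if config.stem == "classic_7x7":
            self.stem = nn.Sequential(
                nn.Conv2d(stem_in, stem_w, 7, stride=2, bias=False,
                          seed=seed + 10),
                nn.BatchNorm2d(stem_w), nn.ReLU())
        else:
            self.stem = nn.Sequential(
                nn.Conv2d(stem_in, stem_w, 3, stride=2, bias=False,
                          seed=seed + 10),
                nn.BatchNorm2d(stem_w), nn.ReLU(),
                nn.Conv2d(stem_w, stem_w, 3, bias=False, seed=seed + 11),
                nn.BatchNorm2d(stem_w), nn.ReLU(),
                nn.Conv2d(stem_w, stem_w, 3, bias=False, seed=seed + 12),
                nn.BatchNorm2d(stem_w), nn.ReLU())
        self.pool = nn.MaxPool2d(3, stride=2, padding=1)

        outs = [s(c) for c in ENCODER_STAGE_WIDTHS]
        mids = [c // Bottleneck.expansion for c in outs]
        self.stages = nn.ModuleList()
        cin = stem_w
        for i, (mid, cout, depth) in enumerate(
                zip(mids, outs, config.stage_depths)):
            blocks = [Bottleneck(cin, mid, cout, stride=(1 if i == 0 else 2),
                                 seed=seed + 20 + 10 * i)]
            for d in range(1, depth):
                blocks.append(Bottleneck(cout, mid, cout,
                                         seed=seed + 20 + 10 * i + d))
            self.stages.append(nn.Sequential(*blocks))
            cin = cout

        # skips, deepest first: stage3 out, stage2, stage1, stem features
        skip_ch = [outs[2], outs[1], outs[0], stem_w]
        self.sa = nn.ModuleList()
        for i, flag in enumerate(config.sa_on_skips):
            self.sa.append(SpatialAttention(seed=seed + 40 + i)
                           if flag else nn.Identity())
        widths = [s(c) for c in config.decoder_widths]
        self.decoder = nn.ModuleList()
        up_in = outs[3]
        for i in range(4):
            cin_level = up_in + skip_ch[i]
            self.decoder.append(_DecoderLevel(
                cin_level, widths[i], config.decoder_modes[i],
                config.decoder_second_conv[i], seed=seed + 50 + 5 * i))
            up_in = widths[i]
        self.dropout = nn.SpatialDropout2d(config.spatial_dropout_p,
                                           seed=seed + 99)
        self.head = nn.Conv2d(widths[3], config.out_classes, 1, bias=True,
                              seed=seed + 60)
        self._skip_ch = skip_ch
        self._stem_w = stem_w
        self._outs = outs

    # -- forward ------------------------------------------------------------
    def _check_size(self, h, w):
        if h % 32 or w % 32:
            ph, pw = (32 - h % 32) % 32, (32 - w % 32) % 32
            raise ValueError(
                f"input {h}x{w} must be a multiple of 32; pad by ({ph}, {pw})")

    def forward_logits(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        self._check_size(h, w)
        if self.adapter is not None:
            x = self.adapter(x)
        f_stem = self.stem(x)                     # /2
        y = self.pool(f_stem)                     # /4
        feats = []
        for stage in self.stages:
            y = stage(y)
            feats.append(y)
        skips = [feats[2], feats[1], feats[0], f_stem]
        for i in range(4):
            target = skips[i].shape[2:]
            y = nn.upsample2d(y, target, mode="bilinear")
            s = self.sa[i](skips[i])
            y = self.decoder[i](nn.concat([s, y], axis=1))
            if i >= 2:                            # final two decoder levels
                y = self.dropout(y)
        y = nn.upsample2d(y, (h, w), mode="bilinear")
        return self.head(y)

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_logits(x).sigmoid()

    # -- audits -------------------------------------------------------------
    def layer_trace(self, input_hw=(640, 640)) -> list[dict]:
        """Analytic per-component shape/parameter/MAC trace at a given input
        resolution (multiply-accumulate convention)."""
        h, w = input_hw
        self._check_size(h, w)
        rows = []

        def conv_row(name, m: nn.Conv2d, hh, ww):
            ho = (hh + 2 * m.padding - m.kernel) // m.stride + 1
            wo = (ww + 2 * m.padding - m.kernel) // m.stride + 1
            params = m.num_parameters()
            macs = (m.out_channels * (m.in_channels // m.groups)
                    * m.kernel ** 2 * ho * wo)
            rows.append({"name": name, "out": (m.out_channels, ho, wo),
                         "params": params, "macs": macs})
            return ho, wo

        hh, ww = h, w
        if self.adapter is not None:
            conv_row("adapter.rgb", self.adapter.rgb, hh, ww)
            conv_row("adapter.edge", self.adapter.edge, hh, ww)
            conv_row("adapter.fuse", self.adapter.fuse, hh, ww)
        for i, m in enumerate(self.stem.layers):
            if isinstance(m, nn.Conv2d):
                hh, ww = conv_row(f"stem.{i}", m, hh, ww)
            elif isinstance(m, nn.BatchNorm2d):
                rows.append({"name": f"stem.{i}.bn",
                             "out": (m.gamma.size, hh, ww),
                             "params": m.num_parameters(), "macs": 0})
        hh, ww = (hh + 1) // 2, (ww + 1) // 2     # maxpool /2
        sh = {}
        for si, stage in enumerate(self.stages):
            for bi, blk in enumerate(stage.layers):
                stride = blk.c2.stride
                ho, wo = (hh + stride - 1) // stride, (ww + stride - 1) // stride
                p = blk.num_parameters()
                macs = 0
                for cv, (ch, cw) in ((blk.c1, (hh, ww)), (blk.c2, (ho, wo)),
                                     (blk.c3, (ho, wo))):
                    macs += (cv.out_channels * cv.in_channels
                             * cv.kernel ** 2 * ho * wo)
                if blk.down is not None:
                    dc = blk.down.layers[0]
                    macs += dc.out_channels * dc.in_channels * ho * wo
                rows.append({"name": f"stage{si}.{bi}",
                             "out": (blk.c3.out_channels, ho, wo),
                             "params": p, "macs": macs})
                hh, ww = ho, wo
            sh[si] = (hh, ww)
        skip_hw = [sh[2], sh[1], sh[0], (h // 2, w // 2)]
        for i, (lvl, sa) in enumerate(zip(self.decoder, self.sa)):
            hh, ww = skip_hw[i]
            if isinstance(sa, SpatialAttention):
                rows.append({"name": f"sa.{i}", "out": (1, hh, ww),
                             "params": sa.num_parameters(),
                             "macs": 2 * 49 * hh * ww})
            p = lvl.num_parameters()
            if lvl.mode == "dsc":
                macs = (lvl.dw.in_channels * 9 * hh * ww
                        + lvl.pw.in_channels * lvl.pw.out_channels * hh * ww)
            else:
                cv = lvl.conv
                macs = (cv.out_channels * (cv.in_channels // cv.groups)
                        * 9 * hh * ww)
            rows.append({"name": f"decoder.{i}", "out": ("-", hh, ww),
                         "params": p, "macs": macs})
        rows.append({"name": "head", "out": (self.config.out_classes, h, w),
                     "params": self.head.num_parameters(),
                     "macs": self.head.in_channels * h * w})
        return rows

    def trace_macs(self, input_hw=(640, 640)) -> int:
        return int(sum(r["macs"] for r in self.layer_trace(input_hw)))


def assemble_rsunet(config: RSUNetConfig) -> RSUNet:
    return RSUNet(config)


def count_parameters(model: nn.Module) -> int:
    """Total trainable weight elements of an assembled model."""
    return model.num_parameters()
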