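"""VG-Stick-YOLO-style contour network: single-stage, anchor-free instance
segmentation of the stick silhouette with 3-way maturity-stage
classification.

The backbone is built from VanillaNet-style blocks (grouped convolution +
normalisation + a dynamic, channel-gated rectifier; no residual additions,
no attention, no feature pyramid inside the block), which stands in for the
heavier C3K-style stages and — together with the block's semantic fusion —
for the removed spatial-pyramid-pooling (SPPF) module.  The segmentation
head predicts, per feature-map cell, class logits, an ltrb box and mask
prototype coefficients; masks are composed from a shared prototype bank.
In the VG profile every 3x3 convolution in the head and prototype branch is
a GhostConv: a primary convolution producing 1/ratio of the output channels
and a cheap depthwise convolution generating the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .dataset import MaskRaster, Stage, StickImage
from .nn import Tensor


# ---------------------------------------------------------------------------
# layer specs
# ---------------------------------------------------------------------------

@dataclass
class GhostConvSpec:
    in_channels: int
    out_channels: int
    primary_kernel: int = 1
    ratio: int = 2
    cheap_kernel: int = 3
    stride: int = 1
    normalization: bool = False

    def __post_init__(self):
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.out_channels % self.ratio:
            raise ValueError(
                f"out_channels {self.out_channels} not divisible by "
                f"ratio {self.ratio}")


@dataclass
class VanillaBlockSpec:
    in_channels: int
    out_channels: int
    groups: int = 2
    downsample: bool = False
    activation: str = "dynamic_relu"          # dynamic_relu | relu

    def __post_init__(self):
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError(
                f"groups {self.groups} must divide both channel counts")
        if self.activation not in ("dynamic_relu", "relu"):
            raise ValueError("activation must be dynamic_relu or relu")


class GhostConv(nn.Module):
    """Primary convolution -> out/ratio channels; cheap depthwise convolution
    generates the remaining channels; outputs concatenated."""

    def __init__(self, spec: GhostConvSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        prim_out = spec.out_channels // spec.ratio
        bias = not spec.normalization
        self.primary = nn.Conv2d(spec.in_channels, prim_out,
                                 spec.primary_kernel, stride=spec.stride,
                                 bias=bias, seed=seed)
        self.cheap = None
        if spec.ratio > 1:
            cheap_out = spec.out_channels - prim_out
            # depth multiplier ratio-1: each primary channel spawns the rest
            self.cheap = nn.Conv2d(prim_out, cheap_out, spec.cheap_kernel,
                                   groups=prim_out, bias=bias, seed=seed + 1)
        self.norm = nn.BatchNorm2d(spec.out_channels) if spec.normalization \
            else None

    def forward(self, x):
        p = self.primary(x)
        y = p if self.cheap is None else nn.concat([p, self.cheap(p)], axis=1)
        if self.norm is not None:
            y = self.norm(y)
        return y


class VanillaBlock(nn.Module):
    """Shallow non-residual block: grouped 3x3 convolution + normalisation +
    (dynamic) ReLU, with optional 2x pooling downsample."""

    def __init__(self, spec: VanillaBlockSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        self.conv = nn.Conv2d(spec.in_channels, spec.out_channels, 3,
                              groups=spec.groups, bias=False, seed=seed)
        self.norm = nn.BatchNorm2d(spec.out_channels)
        self.act = nn.DynamicReLU(spec.out_channels) \
            if spec.activation == "dynamic_relu" else nn.ReLU()
        self.pool = nn.MaxPool2d(2, stride=2) if spec.downsample else None

    def forward(self, x):
        y = self.act(self.norm(self.conv(x)))
        if self.pool is not None:
            y = self.pool(y)
        return y


def build_ghost_conv(spec: GhostConvSpec, seed: int = 0) -> GhostConv:
    return GhostConv(spec, seed=seed)


def build_vanilla_block(spec: VanillaBlockSpec, seed: int = 0) -> VanillaBlock:
    return VanillaBlock(spec, seed=seed)


def standard_conv_params(cin: int, cout: int, kernel: int,
                         bias: bool = True) -> int:
    """Reference parameter count of a plain convolution."""
    return cout * cin * kernel * kernel + (cout if bias else 0)


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): 1x1 reduce, three chained 5x5 max
    pools, concatenation, 1x1 expand.  Present only in baseline profiles."""

    def __init__(self, channels: int, seed: int = 0):
        super().__init__()
        mid = channels // 2
        self.reduce = nn.Conv2d(channels, mid, 1, bias=False, seed=seed)
        self.rnorm = nn.BatchNorm2d(mid)
        self.expand = nn.Conv2d(mid * 4, channels, 1, bias=False,
                                seed=seed + 1)
        self.enorm = nn.BatchNorm2d(channels)
        self.pool = nn.MaxPool2d(5, stride=1, padding=2)

    def forward(self, x):
        y = self.rnorm(self.reduce(x)).relu()
        p1 = self.pool(y)
        p2 = self.pool(p1)
        p3 = self.pool(p2)
        return self.enorm(self.expand(nn.concat([y, p1, p2, p3],
                                                axis=1))).relu()


# ---------------------------------------------------------------------------
# model config
# ---------------------------------------------------------------------------

#: full-scale channel plan (stem, stage1..4); the head/neck widths below are
#: fixed by the published model footprints
BASE_WIDTHS = (24, 48, 96, 192, 320)
HEAD_WIDTH = 48
PROTO_CHANNELS = 64
NUM_PROTOTYPES = 32
STAGE_DEPTHS = (2, 2, 3, 1)


@dataclass
class ContourModelConfig:
    width_multiplier: float = 1.0
    stage_depths: tuple = STAGE_DEPTHS
    num_classes: int = 3
    mask_prototype_count: int = NUM_PROTOTYPES
    input_size: tuple = (640, 640)
    ghost_head: bool = True
    use_sppf: bool = False
    activation: str = "dynamic_relu"
    seed: int = 0

    def __post_init__(self):
        if self.num_classes != 3:
            raise ValueError("the stage classifier is 3-way")
        if self.width_multiplier <= 0:
            raise ValueError("width multiplier must be positive")

    def scaled(self, c: int) -> int:
        return max(4, 2 * int(round(c * self.width_multiplier / 2)))


def vg_config(**kw) -> ContourModelConfig:
    """The lightweight profile: VanillaNet backbone, Ghost head, no SPPF."""
    return ContourModelConfig(ghost_head=True, use_sppf=False, **kw)


def vanilla_config(**kw) -> ContourModelConfig:
    """VanillaNet backbone with the standard (non-Ghost) head, no SPPF."""
    return ContourModelConfig(ghost_head=False, use_sppf=False, **kw)


def test_scale_config(**kw) -> ContourModelConfig:
    kw.setdefault("width_multiplier", 0.25)
    kw.setdefault("activation", "relu")
    kw.setdefault("stage_depths", (1, 1, 1, 1))
    return ContourModelConfig(**kw)


class _HeadConv(nn.Module):
    """A 3x3 head convolution: GhostConv in the VG profile, standard
    convolution otherwise; BN + ReLU either way."""

    def __init__(self, cin: int, cout: int, ghost: bool, seed: int = 0):
        super().__init__()
        if ghost:
            self.conv = GhostConv(GhostConvSpec(
                cin, cout, primary_kernel=3, ratio=2, cheap_kernel=3,
                normalization=True), seed=seed)
        else:
            self.conv = nn.Conv2d(cin, cout, 3, bias=False, seed=seed)
            self.norm = nn.BatchNorm2d(cout)
        self.ghost = ghost

    def forward(self, x):
        y = self.conv(x)
        if not self.ghost:
            y = self.norm(y)
        return y.relu()


class _ScaleHead(nn.Module):
    """Decoupled per-scale head: a shared 3x3 stem (Ghost or standard) plus
    thin 1x1 branches for class logits, ltrb box and mask coefficients."""

    def __init__(self, cin: int, h: int, n_protos: int, n_classes: int,
                 ghost: bool, seed: int = 0):
        super().__init__()
        self.stem2 = _HeadConv(cin, h, ghost, seed=seed)
        self.refine = _HeadConv(h, h, ghost, seed=seed + 1)
        self.cls_out = nn.Conv2d(h, n_classes, 1, bias=True, seed=seed + 2)
        self.box_out = nn.Conv2d(h, 4, 1, bias=True, seed=seed + 3)
        self.coef_out = nn.Conv2d(h, n_protos, 1, bias=True, seed=seed + 4)

    def forward(self, feat):
        y = self.refine(self.stem2(feat))
        return {"cls": self.cls_out(y), "box": self.box_out(y),
                "coef": self.coef_out(y)}


class ContourNet(nn.Module):
    """Anchor-free instance segmenter with a prototype mask head.

    Outputs per scale (strides 8/16/32): class logits (3), ltrb box
    regression (4) and prototype coefficients; a shared prototype bank at
    stride 4 composes instance masks.
    """

    STRIDES = (8, 16, 32)

    def __init__(self, config: ContourModelConfig):
        super().__init__()
        self.config = config
        s = config.scaled
        w0, w1, w2, w3, w4 = (s(c) for c in BASE_WIDTHS)
        seed = config.seed
        act = config.activation
        self.stem = nn.Sequential(
            nn.Conv2d(3, w0, 3, stride=2, bias=False, seed=seed),
            nn.BatchNorm2d(w0), nn.ReLU())

        def stage(cin, cout, depth, idx):
            blocks = [VanillaBlock(VanillaBlockSpec(
                cin, cout, groups=2, downsample=True, activation=act),
                seed=seed + 10 * idx)]
            blocks += [VanillaBlock(VanillaBlockSpec(
                cout, cout, groups=2, activation=act),
                seed=seed + 10 * idx + d) for d in range(1, depth)]
            return nn.Sequential(*blocks)

        d1, d2, d3, d4 = config.stage_depths
        self.stage1 = stage(w0, w1, d1, 1)    # /4
        self.stage2 = stage(w1, w2, d2, 2)    # /8   -> P3
        self.stage3 = stage(w2, w3, d3, 3)    # /16  -> P4
        self.stage4 = stage(w3, w4, d4, 4)    # /32  -> P5
        self.sppf = SPPF(w4, seed=seed + 70) if config.use_sppf else None

        # light top-down neck: 1x1 laterals + 3x3 fusion after upsampling
        self.lat5 = nn.Conv2d(w4, w3, 1, bias=False, seed=seed + 80)
        self.lat5n = nn.BatchNorm2d(w3)
        self.fuse4 = nn.Sequential(
            nn.Conv2d(w3 * 2, w3, 3, groups=2, bias=False, seed=seed + 81),
            nn.BatchNorm2d(w3), nn.ReLU())
        self.lat4 = nn.Conv2d(w3, w2, 1, bias=False, seed=seed + 82)
        self.lat4n = nn.BatchNorm2d(w2)
        self.fuse3 = nn.Sequential(
            nn.Conv2d(w2 * 2, w2, 3, groups=2, bias=False, seed=seed + 83),
            nn.BatchNorm2d(w2), nn.ReLU())

        ghost = config.ghost_head
        h = s(HEAD_WIDTH)
        npro = config.mask_prototype_count
        self.heads = nn.ModuleList()
        for i, ch in enumerate((w2, w3, w4)):
            head = _ScaleHead(ch, h, npro, config.num_classes, ghost,
                              seed=seed + 100 + 7 * i)
            self.heads.append(head)

        pm = s(PROTO_CHANNELS)
        self.proto_conv1 = _HeadConv(w2, pm, ghost, seed=seed + 130)
        self.proto_conv2 = _HeadConv(pm, pm, ghost, seed=seed + 131)
        self.proto_out = nn.Conv2d(pm, npro, 1, bias=True, seed=seed + 132)

    # -- forward ------------------------------------------------------------
    def backbone(self, x):
        y = self.stem(x)
        c2 = self.stage1(y)
        p3 = self.stage2(c2)
        p4 = self.stage3(p3)
        p5 = self.stage4(p4)
        if self.sppf is not None:
            p5 = self.sppf(p5)
        return p3, p4, p5

    def forward(self, x: Tensor) -> dict:
        p3, p4, p5 = self.backbone(x)
        t5 = self.lat5n(self.lat5(p5)).relu()
        t5u = nn.upsample2d(t5, p4.shape[2:], mode="nearest")
        n4 = self.fuse4(nn.concat([t5u, p4], axis=1))
        t4 = self.lat4n(self.lat4(n4)).relu()
        t4u = nn.upsample2d(t4, p3.shape[2:], mode="nearest")
        n3 = self.fuse3(nn.concat([t4u, p3], axis=1))

        outs = [head(feat) for feat, head in zip((n3, n4, p5), self.heads)]
        pr = self.proto_conv1(n3)
        pr = nn.upsample2d(pr, (pr.shape[2] * 2, pr.shape[3] * 2),
                           mode="nearest")
        protos = self.proto_out(self.proto_conv2(pr))     # stride 4
        return {"scales": outs, "protos": protos}


@dataclass
class InstancePrediction:
    box: tuple                      # x1, y1, x2, y2 pixels
    class_id: Stage
    confidence: float
    mask: MaskRaster                # probability raster, image-sized


def assemble_contour_model(config: ContourModelConfig) -> ContourNet:
    return ContourNet(config)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _nms(boxes, scores, iou_thr):
    from .metrics import box_iou
    order = np.argsort(-np.asarray(scores), kind="stable")
    keep = []
    for i in order:
        if all(box_iou(boxes[i], boxes[j]) < iou_thr for j in keep):
            keep.append(i)
    return keep


def predict_instances(model: ContourNet, image: StickImage,
                      confidence_threshold: float = 0.25,
                      iou_nms: float = 0.7) -> list[InstancePrediction]:
    """Decode instances from a forward pass: per-cell class scores, ltrb
    boxes, prototype-composed masks; class-agnostic NMS; instances sorted by
    descending confidence."""
    if not (0 < confidence_threshold < 1 and 0 < iou_nms < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    h, w = image.shape
    x = Tensor(image.pixels.astype(np.float32).transpose(2, 0, 1)[None]
               / 255.0)
    model.eval()
    out = model(x)
    protos = out["protos"].data[0]                    # (np, h/4, w/4)
    cand = []
    for scale_out, stride in zip(out["scales"], ContourNet.STRIDES):
        cls = 1.0 / (1.0 + np.exp(-scale_out["cls"].data[0]))   # (3,gh,gw)
        box = scale_out["box"].data[0]
        coef = scale_out["coef"].data[0]
        gh, gw = cls.shape[1:]
        conf = cls.max(axis=0)
        cid = cls.argmax(axis=0)
        ys, xs = np.nonzero(conf >= confidence_threshold)
        for r, c in zip(ys, xs):
            cx, cy = (c + 0.5) * stride, (r + 0.5) * stride
            l, t, rr, b = np.exp(np.clip(box[:, r, c], -10, 10)) * stride
            x1 = float(np.clip(cx - l, 0, w - 1))
            y1 = float(np.clip(cy - t, 0, h - 1))
            x2 = float(np.clip(cx + rr, x1 + 1e-3, w))
            y2 = float(np.clip(cy + b, y1 + 1e-3, h))
            cand.append(((x1, y1, x2, y2), int(cid[r, c]),
                         float(conf[r, c]), coef[:, r, c]))
    if not cand:
        return []
    boxes = [c[0] for c in cand]
    scores = [c[2] for c in cand]
    keep = _nms(boxes, scores, iou_nms)
    results = []
    for i in keep:
        bx, cid, conf_i, coefs = cand[i]
        mlogit = np.tensordot(coefs, protos, axes=1)
        mprob = 1.0 / (1.0 + np.exp(-np.clip(mlogit, -60, 60)))
        full = _resize_bilinear(mprob, (h, w))
        crop = np.zeros_like(full)
        x1, y1, x2, y2 = (int(np.floor(bx[0])), int(np.floor(bx[1])),
                          int(np.ceil(bx[2])), int(np.ceil(bx[3])))
        crop[y1:y2, x1:x2] = full[y1:y2, x1:x2]
        results.append(InstancePrediction(
            box=bx, class_id=Stage(cid), confidence=conf_i,
            mask=MaskRaster(image.id, np.clip(crop, 0, 1),
                            kind="probability")))
    results.sort(key=lambda p: -p.confidence)
    return results


def _resize_bilinear(arr: np.ndarray, size) -> np.ndarray:
    from .nn.tensor import upsample2d
    t = Tensor(arr[None, None])
    return upsample2d(t, size, mode="bilinear").data[0, 0]


def extract_roi(image: StickImage, instance: InstancePrediction,
                threshold: float = 0.5):
    """Zero out pixels outside the instance mask and crop to its bounding
    box; returns the crop and its (row, col) origin in the source frame."""
    m = instance.mask.binarize(threshold).values.astype(bool)
    if not m.any():
        raise ValueError("no ROI: instance mask is empty after binarization")
    rows = np.nonzero(m.any(axis=1))[0]
    cols = np.nonzero(m.any(axis=0))[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    px = image.pixels.copy()
    px[~m] = 0
    crop = StickImage(id=f"{image.id}__roi", pixels=px[r0:r1, c0:c1],
                      stage=instance.class_id, background=image.background,
                      exposure_tag=image.exposure_tag)
    roi_mask = MaskRaster(crop.id, m[r0:r1, c0:c1].astype(np.uint8))
    return crop, roi_mask, (r0, c0)
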