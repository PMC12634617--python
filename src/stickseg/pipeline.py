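"""End-to-end orchestration: training entry points for both stages and the
two-stage inference path (contour -> ROI -> browning segmentation ->
browning report).

Stage-1 training uses a centre-cell assignment: the feature-map cell (at
each scale) containing the ground-truth box centre is the positive sample
for classification, ltrb regression and mask-coefficient supervision;
every other cell trains toward zero class scores.  Stage-2 trains with
binary cross-entropy plus Dice on the browning mask.  One stick per frame
is assumed throughout (the highest-confidence instance wins).
"""

from __future__ import annotations

import csv
import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import metrics, nn
from .contour import (ContourModelConfig, ContourNet, assemble_contour_model,
                      extract_roi, predict_instances, test_scale_config)
from .dataset import MaskRaster, Stage, StickImage, load_image, load_mask, \
    parse_polygon_annotation, polygon_to_mask
from .metrics import BrowningReport
from .nn import Tensor
from .rsunet import RSUNet, RSUNetConfig, assemble_rsunet
from .rsunet import test_scale_config as rsunet_test_config


# ---------------------------------------------------------------------------
# config & checkpoints
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    stage1: ContourModelConfig = field(default_factory=test_scale_config)
    stage2: RSUNetConfig = field(default_factory=rsunet_test_config)
    stage1_weights: str | None = None
    stage2_weights: str | None = None
    confidence: float = 0.25
    nms_iou: float = 0.7
    mask_binarize: float = 0.5
    stage2_input: tuple = (64, 64)
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps({"stage1": vars(self.stage1),
                           "stage2": vars(self.stage2),
                           "thresholds": [self.confidence, self.nms_iou,
                                          self.mask_binarize],
                           "stage2_input": list(self.stage2_input),
                           "seed": self.seed},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_checkpoint(model: nn.Module, config_digest: str, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"state": model.state_dict(),
                     "config_hash": config_digest, "version": 1}, fh)


def load_checkpoint(model: nn.Module, config_digest: str, path) -> None:
    with open(path, "rb") as fh:
        d = pickle.load(fh)
    if d["config_hash"] != config_digest:
        raise ValueError(
            f"checkpoint config hash {d['config_hash']} does not match "
            f"expected {config_digest}; refusing to load")
    model.load_state_dict(d["state"])


def _config_digest(cfg) -> str:
    return hashlib.sha256(json.dumps(vars(cfg), sort_keys=True,
                                     default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# resizing helpers
# ---------------------------------------------------------------------------

def _resize(arr: np.ndarray, size, mode="bilinear") -> np.ndarray:
    """Resize HxW or HxWxC to ``size`` via the network resampler."""
    if arr.ndim == 2:
        t = Tensor(arr.astype(np.float32)[None, None])
        return nn.upsample2d(t, size, mode=mode).data[0, 0]
    t = Tensor(arr.astype(np.float32).transpose(2, 0, 1)[None])
    return nn.upsample2d(t, size, mode=mode).data[0].transpose(1, 2, 0)


def letterbox(arr: np.ndarray, target_hw) -> tuple[np.ndarray, dict]:
    """Aspect-preserving resize plus zero padding to ``target_hw``; returns
    the canvas and the geometry needed to map rasters back."""
    th, tw = target_hw
    h, w = arr.shape[:2]
    scale = min(th / h, tw / w)
    nh, nw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    resized = _resize(arr, (nh, nw))
    if arr.ndim == 2:
        canvas = np.zeros((th, tw), dtype=resized.dtype)
        canvas[:nh, :nw] = resized
    else:
        canvas = np.zeros((th, tw, arr.shape[2]), dtype=resized.dtype)
        canvas[:nh, :nw] = resized
    return canvas, {"scale": scale, "nh": nh, "nw": nw, "orig": (h, w)}


def unletterbox(raster: np.ndarray, geom: dict) -> np.ndarray:
    return _resize(raster[:geom["nh"], :geom["nw"]], geom["orig"])


# ---------------------------------------------------------------------------
# stage-1 training
# ---------------------------------------------------------------------------

def _contour_targets(model: ContourNet, bundle, h, w):
    """Positive-cell supervision from a scene bundle."""
    m = bundle.stick_mask.values.astype(bool)
    rows = np.nonzero(m.any(axis=1))[0]
    cols = np.nonzero(m.any(axis=0))[0]
    y1, y2 = float(rows[0]), float(rows[-1] + 1)
    x1, x2 = float(cols[0]), float(cols[-1] + 1)
    cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
    return {"box": (x1, y1, x2, y2), "center": (cx, cy),
            "cls": int(bundle.image.stage), "mask": m.astype(np.float32)}


def contour_loss(model: ContourNet, x: Tensor, targets: list) -> Tensor:
    out = model(x)
    n = x.shape[0]
    h, w = x.shape[2], x.shape[3]
    protos = out["protos"]
    total = None
    for si, (scale_out, stride) in enumerate(zip(out["scales"],
                                                 ContourNet.STRIDES)):
        cls = scale_out["cls"]
        box = scale_out["box"]
        coef = scale_out["coef"]
        gh, gw = cls.shape[2], cls.shape[3]
        cls_t = np.zeros(cls.shape, dtype=np.float32)
        box_t = np.zeros(box.shape, dtype=np.float32)
        box_w = np.zeros(box.shape, dtype=np.float32)
        for bi, tgt in enumerate(targets):
            cx, cy = tgt["center"]
            gc = min(int(cx / stride), gw - 1)
            gr = min(int(cy / stride), gh - 1)
            cls_t[bi, tgt["cls"], gr, gc] = 1.0
            x1, y1, x2, y2 = tgt["box"]
            # ltrb about the assigned cell's center (the decode reference)
            ccx, ccy = (gc + 0.5) * stride, (gr + 0.5) * stride
            ltrb = np.array([ccx - x1, ccy - y1, x2 - ccx, y2 - ccy])
            box_t[bi, :, gr, gc] = np.log(np.maximum(ltrb, 1e-3) / stride)
            box_w[bi, :, gr, gc] = 1.0
        cls_loss = nn.bce_with_logits(cls, cls_t)
        diff = (box - Tensor(box_t)) * Tensor(box_w)
        box_loss = (diff * diff).sum() * (1.0 / max(box_w.sum(), 1.0))
        term = cls_loss + box_loss * 0.5
        # mask supervision at this scale's positive cells
        ph, pw = protos.shape[2], protos.shape[3]
        nc = coef.shape[1]
        for bi, tgt in enumerate(targets):
            cx, cy = tgt["center"]
            gc = min(int(cx / stride), gw - 1)
            gr = min(int(cy / stride), gh - 1)
            csel = coef[bi:bi + 1, :, gr, gc].reshape(1, nc)
            mlogit = (csel @ protos.reshape(n, nc, ph * pw)[bi]
                      ).reshape(1, 1, ph, pw)
            mt = _resize(tgt["mask"], (ph, pw))
            term = term + nn.bce_with_logits(mlogit, mt[None, None] > 0.5) \
                * (1.0 / len(targets))
        total = term if total is None else total + term
    return total


def train_contour(model: ContourNet, bundles, steps: int = 200,
                  lr: float = 1e-3, seed: int = 0, log=None) -> list[float]:
    """Fit the contour net on scene bundles (full-batch); returns the loss
    trajectory."""
    if not bundles:
        raise ValueError("empty corpus")
    x = Tensor(np.stack([b.image.pixels for b in bundles]).astype(np.float32)
               .transpose(0, 3, 1, 2) / 255.0)
    h, w = x.shape[2], x.shape[3]
    targets = [_contour_targets(model, b, h, w) for b in bundles]
    model.train()
    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=5e-4)
    losses = []
    for step in range(steps):
        opt.zero_grad()
        loss = contour_loss(model, x, targets)
        loss.backward()
        opt.step()
        losses.append(loss.item())
        if log and step % 25 == 0:
            log(f"contour step {step}: loss {loss.item():.4f}")
    model.eval()
    return losses


# ---------------------------------------------------------------------------
# stage-2 training
# ---------------------------------------------------------------------------

def dice_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    probs = logits.sigmoid()
    t = Tensor(target.astype(np.float32))
    inter = (probs * t).sum()
    denom = probs.sum() + t.sum() + 1.0
    return 1.0 - (inter * 2.0 + 1.0) / denom


def roi_training_arrays(bundles, size=(64, 64)):
    """Stage-2 training arrays from scene records: stick-masked ROI crops
    and browning masks, letterboxed to ``size``.

    Accepts anything carrying ``image``, ``stick_mask`` and
    ``browning_mask`` (scene bundles, corpus records)."""
    imgs, masks = [], []
    for b in bundles:
        m = b.stick_mask.values.astype(bool)
        px = b.image.pixels.copy()
        px[~m] = 0
        rows = np.nonzero(m.any(axis=1))[0]
        cols = np.nonzero(m.any(axis=0))[0]
        crop = px[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        bm = b.browning_mask.values[rows[0]:rows[-1] + 1,
                                    cols[0]:cols[-1] + 1].astype(np.float32)
        ci, _ = letterbox(crop, size)
        cm, _ = letterbox(bm, size)
        imgs.append(ci)
        masks.append(cm > 0.5)
    return np.stack(imgs), np.stack(masks)


def train_rsunet(model: RSUNet, images: np.ndarray, masks: np.ndarray,
                 steps: int = 300, lr: float = 1e-4, seed: int = 0,
                 log=None) -> list[float]:
    """Fit RS-UNet on (N,H,W,3) uint8 ROI images and (N,H,W) binary masks
    with BCE + Dice; returns the loss trajectory."""
    if len(images) == 0:
        raise ValueError("empty corpus")
    x = Tensor(np.asarray(images, dtype=np.float32)
               .transpose(0, 3, 1, 2) / 255.0)
    t = np.asarray(masks, dtype=np.float32)[:, None]
    model.train()
    model.dropout.reseed(seed)
    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=0.0)
    losses = []
    for step in range(steps):
        opt.zero_grad()
        logits = model.forward_logits(x)
        loss = nn.bce_with_logits(logits, t) + dice_loss(logits, t)
        loss.backward()
        opt.step()
        losses.append(loss.item())
        if log and step % 25 == 0:
            log(f"rsunet step {step}: loss {loss.item():.4f}")
    model.eval()
    return losses


# ---------------------------------------------------------------------------
# two-stage inference
# ---------------------------------------------------------------------------

def run_two_stage_models(stage1: ContourNet, stage2: RSUNet, images,
                         confidence: float = 0.25, nms_iou: float = 0.7,
                         mask_binarize: float = 0.5,
                         stage2_input=(64, 64),
                         with_heatmap: bool = True) -> list[BrowningReport]:
    """Run contour detection, ROI extraction, browning segmentation and
    ratio quantification on each image."""
    reports = []
    for img in images:
        insts = predict_instances(stage1, img, confidence, nms_iou)
        if not insts:
            reports.append(BrowningReport(
                image_id=img.id, roi_pixels=0, browning_pixels=0,
                ratio_percent=None, stage=Stage.UNKNOWN,
                flags=("no stick detected",)))
            continue
        inst = insts[0]
        flags = ("multiple sticks detected",) if len(insts) > 1 else ()
        roi_img, roi_mask, (r0, c0) = extract_roi(img, inst, mask_binarize)
        canvas, geom = letterbox(roi_img.pixels, stage2_input)
        x = Tensor(canvas.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
        stage2.eval()
        prob = stage2(x).data[0, 0]
        roi_prob = unletterbox(prob, geom)
        brown_roi = (roi_prob >= mask_binarize) & roi_mask.values.astype(bool)
        # map back into the original frame through the crop offset
        h, w = img.shape
        full_brown = np.zeros((h, w), dtype=np.uint8)
        full_brown[r0:r0 + brown_roi.shape[0],
                   c0:c0 + brown_roi.shape[1]] = brown_roi
        full_roi = np.zeros((h, w), dtype=np.uint8)
        full_roi[r0:r0 + roi_mask.values.shape[0],
                 c0:c0 + roi_mask.values.shape[1]] = roi_mask.values
        ratio, bpx, rpx = metrics.browning_ratio(
            MaskRaster(img.id, full_brown), MaskRaster(img.id, full_roi))
        heat = metrics.pigment_heatmap(img, MaskRaster(img.id, full_brown)) \
            if with_heatmap and full_brown.any() else None
        reports.append(BrowningReport(
            image_id=img.id, roi_pixels=rpx, browning_pixels=bpx,
            ratio_percent=ratio, stage=inst.class_id, heatmap=heat,
            flags=flags))
    return reports


def run_two_stage(config: PipelineConfig, images) -> list[BrowningReport]:
    """Load both stages from their checkpoints (validating config hashes)
    and run the inference path."""
    stage1 = assemble_contour_model(config.stage1)
    stage2 = assemble_rsunet(config.stage2)
    if config.stage1_weights:
        load_checkpoint(stage1, _config_digest(config.stage1),
                        config.stage1_weights)
    if config.stage2_weights:
        load_checkpoint(stage2, _config_digest(config.stage2),
                        config.stage2_weights)
    return run_two_stage_models(
        stage1, stage2, images, config.confidence, config.nms_iou,
        config.mask_binarize, config.stage2_input)


# ---------------------------------------------------------------------------
# corpus-directory training entry point
# ---------------------------------------------------------------------------

def load_corpus_dir(corpus_dir):
    """Read the on-disk corpus layout back into scene-like records."""
    from dataclasses import dataclass as _dc

    corpus = Path(corpus_dir)
    manifest = corpus / "manifest.csv"
    if not manifest.exists():
        raise ValueError(f"no manifest.csv under {corpus_dir}")

    @_dc
    class _Rec:
        image: StickImage
        stick_mask: MaskRaster
        browning_mask: MaskRaster

    out = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["id"]
            img = load_image(corpus / "images" / f"{sid}.png", id=sid,
                             stage=Stage(int(row["stage"])),
                             background=row.get("background", "unknown"),
                             exposure_tag=row.get("exposure", "unknown"))
            ann = parse_polygon_annotation(
                (corpus / "labels_contour" / f"{sid}.json").read_text())
            stick = polygon_to_mask(ann, *img.shape)
            brown = load_mask(corpus / "masks_browning" / f"{sid}.png", sid)
            out.append(_Rec(image=img, stick_mask=stick, browning_mask=brown))
    if not out:
        raise ValueError("empty corpus")
    return out


def train_stage(config: PipelineConfig, which: str, corpus_dir,
                out_dir, steps: int | None = None, log=None) -> Path:
    """Train one stage on a corpus directory; writes a checkpoint and a
    training-log CSV, returns the checkpoint path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recs = load_corpus_dir(corpus_dir)
    if which == "contour":
        model = assemble_contour_model(config.stage1)
        losses = train_contour(model, recs, steps=steps or 200,
                               lr=1e-3, seed=config.seed, log=log)
        ckpt = out / "contour.ckpt"
        save_checkpoint(model, _config_digest(config.stage1), ckpt)
    elif which == "browning":
        model = assemble_rsunet(config.stage2)
        imgs, masks = [], []
        for r in recs:
            canvas, _ = letterbox(r.image.pixels, config.stage2_input)
            mcanvas, _ = letterbox(r.browning_mask.values.astype(np.float32),
                                   config.stage2_input)
            imgs.append(canvas)
            masks.append(mcanvas > 0.5)
        losses = train_rsunet(model, np.stack(imgs), np.stack(masks),
                              steps=steps or 300, lr=1e-4,
                              seed=config.seed, log=log)
        ckpt = out / "browning.ckpt"
        save_checkpoint(model, _config_digest(config.stage2), ckpt)
    else:
        raise ValueError("which must be 'contour' or 'browning'")
    with open(out / f"{which}_train_log.csv", "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["step", "loss"])
        for i, l in enumerate(losses):
            wtr.writerow([i, f"{l:.6f}"])
    return ckpt


def reports_to_json(reports, config_digest: str, seed: int) -> str:
    return json.dumps({"config_hash": config_digest, "seed": seed,
                       "reports": [r.to_row() for r in reports]}, indent=1)
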