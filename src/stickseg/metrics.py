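"""Evaluation metrics, browning-ratio quantification, pigment heatmaps and
model-complexity audits.

Detection precision counts a prediction as a true positive when its best
still-unmatched ground-truth box has IoU >= 0.5 (greedy matching in
descending confidence; optimal Hungarian matching available behind a flag).
Segmentation scores are pixel-set operations: precision |P∩G|/|P|, recall
|P∩G|/|G|, IoU |P∩G|/|P∪G|.

Empty-denominator conventions (the formulas are silent): an empty
prediction set has precision 1 if the truth is also empty, else 0 — and
mirrored for recall; the IoU of two empty masks is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .dataset import MaskRaster, Stage, StickImage

MICRO, MACRO = "micro", "macro"


@dataclass
class SegmentationScore:
    precision: float
    recall: float
    f1: float
    iou: float
    averaging: str = MICRO


@dataclass
class BrowningReport:
    """Per-image browning quantification."""
    image_id: str
    roi_pixels: int
    browning_pixels: int
    ratio_percent: float | None
    stage: Stage
    heatmap: np.ndarray | None = None
    flags: tuple = ()

    def to_row(self) -> dict:
        return {"image_id": self.image_id, "roi_px": self.roi_pixels,
                "browning_px": self.browning_pixels,
                "ratio_percent": self.ratio_percent,
                "stage": int(self.stage),
                "flags": ";".join(self.flags)}


# ---------------------------------------------------------------------------
# boxes
# ---------------------------------------------------------------------------

def box_iou(a, b) -> float:
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def match_boxes(predictions, truths, iou_threshold: float = 0.5,
                confidences=None, method: str = "greedy"):
    """Match predicted boxes to ground-truth boxes one-to-one.

    Returns (tp, fp, fn).  ``greedy`` walks predictions in descending
    confidence and takes the best unmatched truth; ``hungarian`` maximises
    total matched IoU before thresholding.
    """
    preds = [tuple(map(float, p)) for p in predictions]
    gts = [tuple(map(float, t)) for t in truths]
    if confidences is None:
        confidences = [1.0] * len(preds)
    if method == "greedy":
        order = np.argsort(-np.asarray(confidences, dtype=float),
                           kind="stable")
        used = set()
        tp = 0
        for i in order:
            best_j, best_iou = -1, 0.0
            for j, g in enumerate(gts):
                if j in used:
                    continue
                v = box_iou(preds[i], g)
                if v > best_iou:
                    best_j, best_iou = j, v
            if best_j >= 0 and best_iou >= iou_threshold:
                used.add(best_j)
                tp += 1
        return tp, len(preds) - tp, len(gts) - tp
    if method == "hungarian":
        if not preds or not gts:
            return 0, len(preds), len(gts)
        cost = np.zeros((len(preds), len(gts)))
        for i, p in enumerate(preds):
            for j, g in enumerate(gts):
                cost[i, j] = -box_iou(p, g)
        ri, ci = linear_sum_assignment(cost)
        tp = int(np.sum(-cost[ri, ci] >= iou_threshold))
        return tp, len(preds) - tp, len(gts) - tp
    raise ValueError(f"unknown matching method {method!r}")


def box_precision(predictions, truths, iou_threshold: float = 0.5,
                  confidences=None, method: str = "greedy") -> float:
    """TP / (TP + FP); 1.0 when both lists are empty (vacuous convention)."""
    tp, fp, _ = match_boxes(predictions, truths, iou_threshold, confidences,
                            method)
    return tp / (tp + fp) if (tp + fp) else 1.0


def box_recall(predictions, truths, iou_threshold: float = 0.5,
               confidences=None, method: str = "greedy") -> float:
    tp, _, fn = match_boxes(predictions, truths, iou_threshold, confidences,
                            method)
    return tp / (tp + fn) if (tp + fn) else 1.0


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def _as_bool(m) -> np.ndarray:
    if isinstance(m, MaskRaster):
        m = m.binarize().values
    return np.asarray(m).astype(bool)


def mask_scores(P, G) -> SegmentationScore:
    """Pixel-level precision/recall/F1/IoU of prediction P against truth G."""
    p, g = _as_bool(P), _as_bool(G)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    inter = int(np.sum(p & g))
    np_, ng = int(p.sum()), int(g.sum())
    union = np_ + ng - inter
    precision = inter / np_ if np_ else (1.0 if ng == 0 else 0.0)
    recall = inter / ng if ng else (1.0 if np_ == 0 else 0.0)
    iou = inter / union if union else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return SegmentationScore(precision, recall, f1, iou, MICRO)


def macro_scores(pairs) -> SegmentationScore:
    """Average per-image scores over (P, G) pairs (per-image / macro mode)."""
    scores = [mask_scores(p, g) for p, g in pairs]
    if not scores:
        raise ValueError("no mask pairs")
    return SegmentationScore(
        float(np.mean([s.precision for s in scores])),
        float(np.mean([s.recall for s in scores])),
        float(np.mean([s.f1 for s in scores])),
        float(np.mean([s.iou for s in scores])), MACRO)


def mean_iou(per_class_ious) -> float:
    vals = list(per_class_ious)
    if not vals:
        raise ValueError("need at least one class IoU")
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError("IoU values must lie in [0, 1]")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# browning quantification
# ---------------------------------------------------------------------------

def browning_ratio(browning_mask, roi_mask) -> tuple[float, int, int]:
    """Percentage of ROI pixels that are browning.

    Browning pixels outside the ROI are clipped before counting.  Returns
    ``(ratio_percent, browning_pixels, roi_pixels)``.
    """
    b, r = _as_bool(browning_mask), _as_bool(roi_mask)
    if b.shape != r.shape:
        raise ValueError("masks are not aligned")
    roi_px = int(r.sum())
    if roi_px == 0:
        raise ValueError("no stick region: ROI mask is empty")
    brown_px = int((b & r).sum())
    return 100.0 * brown_px / roi_px, brown_px, roi_px


def pigment_heatmap(image_roi: StickImage, browning_mask) -> np.ndarray:
    """Pigment-intensity raster in [0, 1]: inverse normalized luminance,
    min-max rescaled inside the browning mask, zero elsewhere.

    This is a reconstruction of the visual read-out (darker pigment ->
    hotter), not a colorimetric calibration.
    """
    m = _as_bool(browning_mask)
    if m.shape != image_roi.shape:
        raise ValueError("image and mask are not aligned")
    heat = np.zeros(m.shape, dtype=np.float32)
    if not m.any():
        import warnings
        warnings.warn("empty browning mask: heatmap is all zero")
        return heat
    px = image_roi.pixels.astype(np.float32) / 255.0
    lum = 0.2126 * px[..., 0] + 0.7152 * px[..., 1] + 0.0722 * px[..., 2]
    intensity = 1.0 - lum
    vals = intensity[m]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-9:
        heat[m] = 0.5          # degenerate normalization guard
    else:
        heat[m] = (intensity[m] - lo) / (hi - lo)
    return heat


def save_heatmap_png(heat: np.ndarray, path, colormap: str = "jet") -> None:
    import matplotlib
    from PIL import Image
    rgba = matplotlib.colormaps[colormap](np.clip(heat, 0, 1))
    Image.fromarray((rgba[..., :3] * 255).astype(np.uint8)).save(str(path))


# ---------------------------------------------------------------------------
# complexity audit
# ---------------------------------------------------------------------------

def conv_macs(cin: int, cout: int, kernel: int, h_out: int, w_out: int,
              groups: int = 1) -> int:
    """Multiply-accumulate count of one convolution at a given output size."""
    return cout * (cin // groups) * kernel * kernel * h_out * w_out


def complexity_audit(model, input_hw: tuple[int, int] = (640, 640)) -> dict:
    """Parameters, traced FLOPs under both MAC and 2-op conventions, and the
    serialized checkpoint size of an assembled model."""
    import io
    import pickle

    params = model.num_parameters()
    macs = model.trace_macs(input_hw) if hasattr(model, "trace_macs") else None
    buf = io.BytesIO()
    pickle.dump(model.state_dict(), buf)
    out = {"params": params,
           "serialized_size_mb": buf.getbuffer().nbytes / 2 ** 20}
    if macs is not None:
        out["flops_mac"] = float(macs)
        out["flops_2x"] = float(2 * macs)
    return out
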