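"""Image/annotation I/O, polygon-mask conversion, dataset splitting and the
augmentation policy used to expand the stick-image corpus.

Coordinate convention: 0-based, pixel-center, ``(x=column, y=row)``.
Polygons are filled with the even-odd rule; a pixel belongs to the mask iff
its center lies inside any polygon.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from skimage import measure
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import rotate as sk_rotate


class Stage(IntEnum):
    """Browning maturity stage of a cultivation stick."""
    PRE = 0
    MID = 1
    POST = 2
    UNKNOWN = -1


DEFAULT_LABEL_MAP = {"0": Stage.PRE, "1": Stage.MID, "2": Stage.POST,
                     "pre": Stage.PRE, "mid": Stage.MID, "post": Stage.POST}


@dataclass
class StickImage:
    """An RGB photograph of one cultivation stick."""
    id: str
    pixels: np.ndarray                       # H x W x 3 uint8
    stage: Stage = Stage.UNKNOWN
    background: str = "unknown"              # red | green | unknown
    exposure_tag: str = "unknown"            # low | normal | over | unknown

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1 x 1")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass
class PolygonAnnotation:
    """Closed contour polygons with a stage class, Labelme-style."""
    image_id: str
    polygons: list = field(default_factory=list)   # list of (N,2) arrays, (x, y)
    class_label: Stage = Stage.UNKNOWN
    polygon_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                raise ValueError("each polygon needs >= 3 (x, y) vertices")
        if not self.polygon_labels:
            self.polygon_labels = [self.class_label] * len(self.polygons)


@dataclass
class MaskRaster:
    """Single-channel raster aligned with an image."""
    image_id: str
    values: np.ndarray
    kind: str = "binary"                     # binary | probability

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.kind == "binary":
            uniq = np.unique(v)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("binary mask values must be 0/1")
            self.values = v.astype(np.uint8)
        elif self.kind == "probability":
            if v.min() < 0 or v.max() > 1:
                raise ValueError("probability mask values must lie in [0, 1]")
            self.values = v.astype(np.float32)
        else:
            raise ValueError(f"unknown mask kind {self.kind!r}")

    def binarize(self, threshold: float = 0.5) -> "MaskRaster":
        if self.kind == "binary":
            return self
        return MaskRaster(self.image_id,
                          (self.values >= threshold).astype(np.uint8))


@dataclass
class SplitAssignment:
    train_ids: list
    val_ids: list
    test_ids: list
    ratios: tuple
    seed: int


@dataclass
class AugmentationPolicy:
    """The corpus-expansion policy: rotations of +-10/+-15 degrees,
    brightness-contrast of +-3/5/7 %, 1 % additive noise, horizontal flip,
    +-8 % exposure gain and +-3 % saturation scaling, combined at random.

    Empty magnitude tuples (or ``horizontal_flip=False`` /
    ``noise_fraction=0``) disable the corresponding transform.
    """
    rotations: tuple = (-15.0, -10.0, 10.0, 15.0)
    brightness_contrast: tuple = (-7, -5, -3, 3, 5, 7)
    noise_fraction: float = 0.01
    horizontal_flip: bool = True
    exposure: tuple = (-8, 8)
    saturation: tuple = (-3, 3)
    variants_per_original: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.variants_per_original < 0:
            raise ValueError("variants_per_original must be >= 0")

    @classmethod
    def disabled(cls, **kw):
        """Policy with every transform switched off (identity)."""
        return cls(rotations=(), brightness_contrast=(), noise_fraction=0.0,
                   horizontal_flip=False, exposure=(), saturation=(), **kw)


# ---------------------------------------------------------------------------
# annotation parsing and rasterization
# ---------------------------------------------------------------------------

def parse_polygon_annotation(document: str,
                             label_map: dict | None = None) -> PolygonAnnotation:
    """Parse a Labelme-dialect JSON document into a :class:`PolygonAnnotation`.

    Every ``shape`` record of type polygon becomes one vertex sequence; the
    shape ``label`` string is mapped to a :class:`Stage` via ``label_map``.
    """
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed annotation JSON: {e}") from e
    if not isinstance(doc, dict) or "shapes" not in doc:
        raise ValueError("annotation document lacks a 'shapes' field")
    image_id = str(doc.get("imagePath", doc.get("image_id", "")))
    polygons, labels = [], []
    for i, shape in enumerate(doc["shapes"]):
        if "points" not in shape:
            raise ValueError(f"shape {i} lacks a 'points' field")
        if "label" not in shape:
            raise ValueError(f"shape {i} lacks a 'label' field")
        lbl = str(shape["label"])
        if lbl not in label_map:
            raise ValueError(
                f"unknown label {lbl!r}; permitted: {sorted(label_map)}")
        pts = np.asarray(shape["points"], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError(f"shape {i}: polygon needs >= 3 [x, y] points")
        polygons.append(pts)
        labels.append(label_map[lbl])
    cls = labels[0] if labels else Stage.UNKNOWN
    return PolygonAnnotation(image_id=image_id, polygons=polygons,
                             class_label=cls, polygon_labels=labels)


def annotation_to_json(ann: PolygonAnnotation) -> str:
    """Serialize back to the Labelme dialect read by
    :func:`parse_polygon_annotation`."""
    shapes = [{"label": str(int(lbl)), "points": p.tolist(),
               "shape_type": "polygon"}
              for p, lbl in zip(ann.polygons, ann.polygon_labels)]
    return json.dumps({"imagePath": ann.image_id, "shapes": shapes}, indent=1)


def _even_odd_inside(poly: np.ndarray, xs: np.ndarray,
                     ys: np.ndarray) -> np.ndarray:
    """Crossing-number (even-odd) point-in-polygon test, vectorized over
    test points.  Points are nudged by a sub-pixel epsilon so centers lying
    exactly on an edge resolve deterministically (half-open convention:
    top/left boundary in, bottom/right out, for axis-aligned polygons)."""
    eps = 1e-6
    px = xs + eps
    py = ys + eps
    inside = np.zeros(px.shape, dtype=bool)
    x0, y0 = poly[-1]
    for x1, y1 in poly:
        crosses = (y0 > py) != (y1 > py)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = (x1 - x0) * (py - y0) / (y1 - y0) + x0
            inside ^= crosses & (px < xint)
        x0, y0 = x1, y1
    return inside


def polygon_to_mask(annotation: PolygonAnnotation, height: int,
                    width: int) -> MaskRaster:
    """Rasterize polygons: pixel is 1 iff its center lies inside any polygon
    (even-odd rule); overlapping polygons union."""
    if height < 1 or width < 1:
        raise ValueError("canvas must be at least 1 x 1")
    mask = np.zeros((height, width), dtype=bool)
    if annotation.polygons:
        xs, ys = np.meshgrid(np.arange(width, dtype=float),
                             np.arange(height, dtype=float))
        for poly in annotation.polygons:
            mask |= _even_odd_inside(poly, xs, ys)
    return MaskRaster(annotation.image_id, mask.astype(np.uint8))


def mask_to_polygons(mask: MaskRaster) -> PolygonAnnotation:
    """Trace the 0.5-level contours of a binary mask back into polygons."""
    m = mask.binarize().values.astype(float)
    padded = np.pad(m, 1)
    polys = []
    for contour in measure.find_contours(padded, 0.5):
        # find_contours yields (row, col) on the padded grid
        xy = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])
        if len(xy) >= 3:
            polys.append(xy)
    return PolygonAnnotation(image_id=mask.image_id, polygons=polys)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(ids, ratios, seed: int) -> SplitAssignment:
    """Deterministic random partition; per-split size is round-half-up of
    ``n * ratio`` with the remainder assigned to the training split."""
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids")
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("need three non-negative ratios")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(ids)

    def round_half_up(x):
        return int(np.floor(x + 0.5))

    n_val = round_half_up(n * ratios[1])
    n_test = round_half_up(n * ratios[2])
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("rounding produced a negative training split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n))
    shuffled = [ids[i] for i in order]
    return SplitAssignment(train_ids=shuffled[:n_train],
                           val_ids=shuffled[n_train:n_train + n_val],
                           test_ids=shuffled[n_train + n_val:],
                           ratios=ratios, seed=seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _border_median(px: np.ndarray) -> np.ndarray:
    border = np.concatenate([px[0], px[-1], px[:, 0], px[:, -1]])
    return np.median(border, axis=0)


def _apply_contrast(px: np.ndarray, scale: float) -> np.ndarray:
    mean = px.mean(axis=(0, 1), keepdims=True)
    return mean + scale * (px - mean)


def augment_pair(image: StickImage, mask: MaskRaster,
                 policy: AugmentationPolicy, draw_seed: int):
    """Apply a random combination of policy transforms to an image/mask pair.

    Geometric transforms (rotation, flip) act on both rasters, the mask with
    nearest-neighbour resampling; photometric transforms act on the image
    only.  Deterministic under ``draw_seed``.
    """
    if image.pixels.shape[:2] != mask.values.shape:
        raise ValueError("image and mask dimensions differ")
    rng = np.random.default_rng(draw_seed)
    px = image.pixels.astype(np.float64)
    mk = mask.values.copy()

    # rotation keeps the original frame: fill with the median border colour
    if policy.rotations and rng.random() < 0.5:
        angle = float(rng.choice(policy.rotations))
        fill = _border_median(px)
        rot = np.stack([sk_rotate(px[..., c], angle, resize=False, order=1,
                                  mode="constant", cval=fill[c],
                                  preserve_range=True)
                        for c in range(3)], axis=-1)
        px = rot
        mk = sk_rotate(mk.astype(float), angle, resize=False, order=0,
                       mode="constant", cval=0,
                       preserve_range=True).astype(mask.values.dtype)
    if policy.horizontal_flip and rng.random() < 0.5:
        px = px[:, ::-1].copy()
        mk = mk[:, ::-1].copy()
    if policy.brightness_contrast and rng.random() < 0.5:
        k = float(rng.choice(policy.brightness_contrast))
        px = _apply_contrast(px, 1.0 + k / 100.0)
    if policy.exposure and rng.random() < 0.5:
        k = float(rng.choice(policy.exposure))
        px = px * (1.0 + k / 100.0)
    if policy.saturation and rng.random() < 0.5:
        k = float(rng.choice(policy.saturation))
        hsv = rgb2hsv(np.clip(px, 0, 255).astype(np.uint8))
        hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + k / 100.0), 0, 1)
        px = hsv2rgb(hsv) * 255.0
    if policy.noise_fraction and rng.random() < 0.5:
        px = px + rng.normal(0.0, policy.noise_fraction * 255.0, px.shape)

    out_img = StickImage(id=image.id, stage=image.stage,
                         background=image.background,
                         exposure_tag=image.exposure_tag,
                         pixels=np.clip(np.round(px), 0, 255).astype(np.uint8))
    return out_img, MaskRaster(mask.image_id, mk, kind=mask.kind)


def expand_dataset(originals, policy: AugmentationPolicy, masks=None):
    """Return the originals plus ``variants_per_original`` augmented copies
    of each; total count is ``n * (1 + variants_per_original)``.

    When ``masks`` is given (one per original) a parallel mask list is
    returned as well.
    """
    originals = list(originals)
    with_masks = masks is not None
    if with_masks:
        masks = list(masks)
        if len(masks) != len(originals):
            raise ValueError("need one mask per original")
    out_imgs, out_masks = [], []
    for i, img in enumerate(originals):
        mk = masks[i] if with_masks else MaskRaster(
            img.id, np.zeros(img.shape, dtype=np.uint8))
        out_imgs.append(img)
        out_masks.append(mk)
        for v in range(policy.variants_per_original):
            draw = int(np.random.default_rng(
                [policy.seed, i, v]).integers(0, 2 ** 31 - 1))
            aimg, amk = augment_pair(img, mk, policy, draw)
            aimg.id = f"{img.id}__aug{v}"
            amk.image_id = aimg.id
            out_imgs.append(aimg)
            out_masks.append(amk)
    return (out_imgs, out_masks) if with_masks else out_imgs


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def save_image(image: StickImage, path) -> None:
    Image.fromarray(image.pixels).save(str(path))


def load_image(path, **meta) -> StickImage:
    arr = np.asarray(Image.open(str(path)).convert("RGB"))
    return StickImage(id=meta.pop("id", Path(path).stem), pixels=arr, **meta)


def save_mask(mask: MaskRaster, path) -> None:
    m = mask.binarize().values * 255 if mask.kind == "binary" else \
        np.round(mask.values * 65535).astype(np.uint16)
    Image.fromarray(m.astype(np.uint8) if mask.kind == "binary" else m
                    ).save(str(path))


def load_mask(path, image_id: str | None = None) -> MaskRaster:
    arr = np.asarray(Image.open(str(path)))
    iid = image_id or Path(path).stem
    if arr.dtype == np.uint16:
        return MaskRaster(iid, arr.astype(np.float32) / 65535.0,
                          kind="probability")
    return MaskRaster(iid, (arr > 127).astype(np.uint8))


def save_split(split: SplitAssignment, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "split"])
        for name, lst in (("train", split.train_ids), ("val", split.val_ids),
                          ("test", split.test_ids)):
            for i in lst:
                w.writerow([i, name])


def load_split(path, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> SplitAssignment:
    groups = {"train": [], "val": [], "test": []}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            groups[row["split"]].append(row["id"])
    return SplitAssignment(groups["train"], groups["val"], groups["test"],
                           tuple(ratios), seed)


def save_policy(policy: AugmentationPolicy, path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in vars(policy).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def load_policy(path) -> AugmentationPolicy:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for k in ("rotations", "brightness_contrast", "exposure", "saturation"):
        if k in d:
            d[k] = tuple(d[k])
    return AugmentationPolicy(**d)
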