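"""Seeded synthetic stick scenes with exact ground truth.

No imagery is deposited with the study this package operationalises, so the
generator emulates the documented acquisition conditions: a stick-shaped
substrate block photographed on a uniformly red or green background at three
exposure levels, with mycelium texture, diffuse brown patches whose colour
fades over a soft gradient, and optional specular "plastic bag" streaks.
Scenes carry their contour polygon, stick mask, browning mask and the
achieved browning area ratio, all mutually consistent by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import metrics
from .dataset import (MaskRaster, PolygonAnnotation, Stage, StickImage,
                      annotation_to_json, mask_to_polygons, save_image,
                      save_mask)

EXPOSURE_GAIN = {"low": 0.8, "normal": 1.0, "over": 1.25}
BACKGROUND_RGB = {"red": (172, 46, 40), "green": (52, 138, 70)}
SUBSTRATE_RGB = (214, 196, 164)          # pale colonised substrate
BROWN_RGB = (116, 66, 30)                # fully pigmented mycelium

#: generator convention tying stage labels to browning-ratio bands
STAGE_BANDS = {Stage.PRE: (0.0, 0.10), Stage.MID: (0.30, 0.60),
               Stage.POST: (0.70, 1.0)}


@dataclass
class SceneSpec:
    seed: int
    canvas: tuple = (256, 256)
    background: str = "green"
    exposure: str = "normal"
    stage: Stage = Stage.MID
    nominal_browning_ratio: float = 0.45
    n_blobs: int = 5
    blob_softness: float = 4.0
    bag_glare: bool = False

    def __post_init__(self):
        h, w = self.canvas
        if h < 64 or w < 64:
            raise ValueError("canvas must be at least 64 x 64")
        if self.background not in BACKGROUND_RGB:
            raise ValueError("background must be red or green")
        if self.exposure not in EXPOSURE_GAIN:
            raise ValueError("exposure must be low, normal or over")
        lo, hi = STAGE_BANDS[Stage(self.stage)]
        r = self.nominal_browning_ratio
        if not (0.0 <= r <= 1.0):
            raise ValueError("nominal ratio must lie in [0, 1]")
        if r > 0 and not (lo <= r <= hi) and not (self.stage == Stage.PRE and r < hi):
            raise ValueError(
                f"ratio {r} outside the {Stage(self.stage).name} band {lo}-{hi}")


@dataclass
class SceneBundle:
    image: StickImage
    contour: PolygonAnnotation
    stick_mask: MaskRaster
    browning_mask: MaskRaster
    achieved_ratio: float
    spec: SceneSpec


def _stick_silhouette(h: int, w: int, rng) -> np.ndarray:
    """Rounded-rectangle (capsule) silhouette with mild jitter."""
    cy, cx = h / 2 + rng.uniform(-h * 0.02, h * 0.02), w / 2
    half_h = h * rng.uniform(0.33, 0.38)
    half_w = w * rng.uniform(0.20, 0.26)
    radius = min(half_h, half_w) * 0.8
    yy, xx = np.mgrid[0:h, 0:w]
    dy = np.maximum(np.abs(yy - cy) - (half_h - radius), 0.0)
    dx = np.maximum(np.abs(xx - cx) - (half_w - radius), 0.0)
    return (np.hypot(dy, dx) <= radius)


def _band_noise(shape, rng, sigma: float = 3.0) -> np.ndarray:
    """Band-limited texture noise in [-1, 1]."""
    n = gaussian_filter(rng.standard_normal(shape), sigma)
    return n / (np.abs(n).max() + 1e-9)


def generate_scene(spec: SceneSpec) -> SceneBundle:
    """Render one scene; deterministic under ``spec.seed``.

    Brown blobs are added until the achieved browning ratio lies within
    +-0.02 of the nominal ratio; an unreachable target raises with the best
    achieved value.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    stick = _stick_silhouette(h, w, rng)
    stick_area = int(stick.sum())

    # browning mask: disks are ground truth, colour extends one softness
    # width beyond with a linear alpha ramp crossing 0.5 on the disk edge
    brown = np.zeros((h, w), dtype=bool)
    alpha = np.zeros((h, w), dtype=np.float32)
    target = spec.nominal_browning_ratio
    if target > 0:
        ys, xs = np.nonzero(stick)
        yy, xx = np.mgrid[0:h, 0:w]
        achieved = 0.0
        planned = max(spec.n_blobs, 1)
        for attempt in range(500):
            remaining = target - achieved
            if abs(remaining) <= 0.02:
                break
            want_px = remaining * stick_area
            if attempt < planned:
                want_px = want_px / max(planned - attempt, 1)
            r = float(np.clip(np.sqrt(max(want_px, 4.0) / np.pi), 2.0,
                              min(h, w) / 3.5))
            k = rng.integers(0, len(ys))
            d = np.hypot(yy - ys[k], xx - xs[k])
            blob = (d <= r) & stick
            a = np.clip((r - d) / max(spec.blob_softness, 1e-6) + 0.5, 0, 1)
            a *= stick
            jitter = rng.uniform(0.85, 1.0)
            alpha = np.maximum(alpha, (a * jitter).astype(np.float32))
            brown |= blob
            achieved = brown.sum() / stick_area
        achieved = brown.sum() / stick_area
        if abs(achieved - target) > 0.02:
            raise RuntimeError(
                f"could not reach nominal ratio {target}: best {achieved:.3f}")

    # render
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB[spec.background]
    img += 4.0 * rng.standard_normal((h, w, 3))
    tex = _band_noise((h, w), rng)
    substrate = np.asarray(SUBSTRATE_RGB, dtype=np.float64)
    for c in range(3):
        layer = substrate[c] * (1.0 + 0.08 * tex)
        img[..., c] = np.where(stick, layer, img[..., c])
    brown_col = np.asarray(BROWN_RGB, dtype=np.float64)
    shade = 1.0 + 0.10 * _band_noise((h, w), rng, sigma=6.0)
    for c in range(3):
        img[..., c] = (1 - alpha) * img[..., c] + \
            alpha * brown_col[c] * shade
    if spec.bag_glare:
        for _ in range(2):
            y0 = rng.uniform(0.2 * h, 0.8 * h)
            x0 = rng.uniform(0.3 * w, 0.7 * w)
            slope = rng.uniform(-0.4, 0.4)
            yy2, xx2 = np.mgrid[0:h, 0:w]
            dist = np.abs((yy2 - y0) - slope * (xx2 - x0)) / np.hypot(1, slope)
            streak = np.exp(-(dist ** 2) / (2 * 2.5 ** 2)) * stick
            img += 90.0 * streak[..., None]
    img *= EXPOSURE_GAIN[spec.exposure]
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    sid = f"scene_{spec.seed:08d}"
    image = StickImage(id=sid, pixels=pixels, stage=Stage(spec.stage),
                       background=spec.background,
                       exposure_tag=spec.exposure)
    stick_mask = MaskRaster(sid, stick.astype(np.uint8))
    browning_mask = MaskRaster(sid, brown.astype(np.uint8))
    contour = mask_to_polygons(stick_mask)
    contour.image_id = sid
    contour.class_label = Stage(spec.stage)
    contour.polygon_labels = [Stage(spec.stage)] * len(contour.polygons)
    if brown.any():
        ratio, _, _ = metrics.browning_ratio(browning_mask, stick_mask)
        achieved = ratio / 100.0
    else:
        achieved = 0.0
    return SceneBundle(image=image, contour=contour, stick_mask=stick_mask,
                       browning_mask=browning_mask, achieved_ratio=achieved,
                       spec=spec)


def _ratio_for_stage(stage: Stage, rng) -> float:
    lo, hi = STAGE_BANDS[stage]
    if stage == Stage.PRE:
        return float(rng.uniform(0.03, hi - 0.025))
    if stage == Stage.POST:
        return float(rng.uniform(lo + 0.02, 0.88))
    return float(rng.uniform(lo + 0.02, hi - 0.02))


def generate_corpus(n: int, seed: int, stage_mix=(0.2, 0.55, 0.25),
                    canvas=(128, 128), out_dir=None) -> list[SceneBundle]:
    """Generate ``n`` scenes with stages drawn from ``stage_mix``; when
    ``out_dir`` is given, side-write the on-disk corpus layout
    (images/, labels_contour/, masks_browning/, manifest.csv)."""
    if n <= 0:
        raise ValueError("n must be positive")
    mix = np.asarray(stage_mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("stage_mix must sum to 1")
    rng = np.random.default_rng(seed)
    bundles = []
    for i in range(n):
        stage = Stage(int(rng.choice(3, p=mix)))
        sub = np.random.default_rng([seed, i])
        spec = SceneSpec(
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            canvas=canvas,
            background="red" if sub.random() < 0.5 else "green",
            exposure=["low", "normal", "over"][int(sub.integers(0, 3))],
            stage=stage,
            nominal_browning_ratio=_ratio_for_stage(stage, sub),
            n_blobs=int(sub.integers(3, 8)),
            bag_glare=bool(sub.random() < 0.3),
        )
        bundles.append(generate_scene(spec))
    if out_dir is not None:
        write_corpus(bundles, out_dir)
    return bundles


def write_corpus(bundles, out_dir) -> None:
    out = Path(out_dir)
    for sub in ("images", "labels_contour", "masks_browning", "masks_stick"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for b in bundles:
        sid = b.image.id
        save_image(b.image, out / "images" / f"{sid}.png")
        (out / "labels_contour" / f"{sid}.json").write_text(
            annotation_to_json(b.contour))
        save_mask(b.browning_mask, out / "masks_browning" / f"{sid}.png")
        save_mask(b.stick_mask, out / "masks_stick" / f"{sid}.png")
        rows.append({"id": sid, "stage": int(b.image.stage),
                     "background": b.image.background,
                     "exposure": b.image.exposure_tag,
                     "achieved_ratio": f"{b.achieved_ratio:.4f}"})
    with open(out / "manifest.csv", "w", newline="") as fh:
        wtr = csv.DictWriter(fh, fieldnames=list(rows[0]))
        wtr.writeheader()
        wtr.writerows(rows)
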