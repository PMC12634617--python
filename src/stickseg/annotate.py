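"""Semi-automatic browning-region labelling.

A practitioner scribbles a few browning and non-browning pixels inside the
stick ROI; a per-pixel feature stack (colour, difference-of-Gaussians edge
responses, local entropy, membrane projections, neighbourhood statistics)
feeds a random-forest pixel classifier, whose cleaned-up prediction becomes
the training label for the browning-segmentation network.

Feature layout under the default recipe (18 channels): R, G, B, H, S, V,
DoG at three sigma pairs on luminance, local entropy, six membrane
projections (sum/mean/max/min/median/std over rotated line kernels), and
neighbourhood mean/std of luminance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.transform import rotate as sk_rotate
from sklearn.ensemble import RandomForestClassifier

from .dataset import MaskRaster, StickImage

PROJECTION_FUNCS = {
    "sum": lambda s: s.sum(axis=0),
    "mean": lambda s: s.mean(axis=0),
    "max": lambda s: s.max(axis=0),
    "min": lambda s: s.min(axis=0),
    "median": lambda s: np.median(s, axis=0),
    "std": lambda s: s.std(axis=0),
}


@dataclass
class FeatureRecipe:
    """Parameters of the per-pixel feature stack."""
    dog_sigma_pairs: tuple = ((1.0, 2.0), (2.0, 4.0), (4.0, 8.0))
    entropy_radius: int = 4
    entropy_bins: int = 64
    membrane_kernel_size: int = 19
    membrane_rotations: int = 6
    membrane_projections: tuple = ("sum", "mean", "max", "min", "median", "std")
    neighborhood_radius: int = 2
    color_spaces: tuple = ("RGB", "HSV")

    def __post_init__(self):
        for s1, s2 in self.dog_sigma_pairs:
            if not (0 < s1 < s2):
                raise ValueError("sigma pairs must satisfy 0 < s1 < s2")
        if self.entropy_radius < 1 or self.entropy_bins < 2:
            raise ValueError("entropy radius >= 1 and bins >= 2 required")
        if self.membrane_kernel_size % 2 == 0:
            raise ValueError("membrane kernel size must be odd")
        unknown = set(self.membrane_projections) - set(PROJECTION_FUNCS)
        if unknown:
            raise ValueError(f"unknown projections: {sorted(unknown)}")
        if self.neighborhood_radius < 1:
            raise ValueError("neighborhood radius must be >= 1")
        bad = set(self.color_spaces) - {"RGB", "HSV"}
        if bad:
            raise ValueError(f"unsupported color spaces: {sorted(bad)}")

    def digest(self) -> str:
        blob = json.dumps(
            {k: v for k, v in sorted(vars(self).items())}, default=list,
            sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def channel_names(self) -> list[str]:
        names = []
        if "RGB" in self.color_spaces:
            names += ["R", "G", "B"]
        if "HSV" in self.color_spaces:
            names += ["H", "S", "V"]
        names += [f"dog_{s1:g}_{s2:g}" for s1, s2 in self.dog_sigma_pairs]
        names += [f"entropy_r{self.entropy_radius}"]
        names += [f"membrane_{p}" for p in self.membrane_projections]
        r = self.neighborhood_radius
        names += [f"nbr_mean_r{r}", f"nbr_std_r{r}"]
        return names


@dataclass
class ScribbleSet:
    """Manually selected training pixels for the two classes."""
    image_id: str
    positive_pixels: list                 # (row, col) browning
    negative_pixels: list                 # (row, col) non-browning
    provenance: str = ""

    def validate(self, shape) -> None:
        pos = {tuple(p) for p in self.positive_pixels}
        neg = {tuple(p) for p in self.negative_pixels}
        if pos & neg:
            raise ValueError("positive and negative scribbles overlap")
        if not pos or not neg:
            raise ValueError("each class needs at least one scribbled pixel")
        h, w = shape
        for r, c in pos | neg:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"scribble ({r}, {c}) outside image bounds")

    def to_json(self) -> str:
        return json.dumps({"image_id": self.image_id,
                           "positive": [list(map(int, p))
                                        for p in self.positive_pixels],
                           "negative": [list(map(int, p))
                                        for p in self.negative_pixels],
                           "provenance": self.provenance})

    @classmethod
    def from_json(cls, text: str) -> "ScribbleSet":
        d = json.loads(text)
        return cls(d["image_id"], [tuple(p) for p in d["positive"]],
                   [tuple(p) for p in d["negative"]],
                   d.get("provenance", ""))


@dataclass
class PixelFeatureStack:
    image_id: str
    features: np.ndarray                  # H x W x F
    channel_names: list
    recipe_hash: str
    roi_mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.features.shape[2] != len(self.channel_names):
            raise ValueError("channel_names length must equal feature depth")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature stack contains non-finite values")


@dataclass
class PixelClassifier:
    forest: RandomForestClassifier
    n_trees: int
    recipe_hash: str
    class_map: dict = field(default_factory=lambda: {0: "non-browning",
                                                     1: "browning"})
    train_accuracy: float = float("nan")


# ---------------------------------------------------------------------------
# individual operators
# ---------------------------------------------------------------------------

def dog_filter(channel: np.ndarray, sigma1: float, sigma2: float) -> np.ndarray:
    """Difference of Gaussians: blur at sigma1 minus blur at sigma2,
    reflective boundaries."""
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigmas must be positive")
    x = np.asarray(channel, dtype=np.float64)
    # truncate=6 keeps the discrete kernel within ~1e-9 of the continuous
    # Gaussian so impulse responses match the analytic difference closely
    return ndimage.gaussian_filter(x, sigma1, mode="reflect", truncate=6.0) - \
        ndimage.gaussian_filter(x, sigma2, mode="reflect", truncate=6.0)


def local_entropy(channel: np.ndarray, radius: int, n_bins: int) -> np.ndarray:
    """Shannon entropy (bits) of the quantized gray-value histogram in each
    (2r+1)^2 neighbourhood."""
    if radius < 1 or n_bins < 2:
        raise ValueError("radius >= 1 and n_bins >= 2 required")
    x = np.asarray(channel, dtype=np.float64)
    lo, hi = x.min(), x.max()
    q = np.zeros_like(x, dtype=np.int32) if hi - lo < 1e-12 else \
        np.minimum((n_bins * (x - lo) / (hi - lo)).astype(np.int32),
                   n_bins - 1)
    size = 2 * radius + 1
    ent = np.zeros_like(x, dtype=np.float64)
    for b in range(n_bins):
        p = ndimage.uniform_filter((q == b).astype(np.float64), size,
                                   mode="reflect")
        nz = p > 0
        ent[nz] -= p[nz] * np.log2(p[nz])
    return ent


def histogram_entropy(values, n_bins: int, value_range=None) -> float:
    """Shannon entropy (bits) of the quantized histogram of a value list —
    the per-neighbourhood formula that :func:`local_entropy` evaluates at
    every pixel."""
    v = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = (v.min(), v.max()) if value_range is None else value_range
    if hi - lo < 1e-12:
        return 0.0
    q = np.minimum((n_bins * (v - lo) / (hi - lo)).astype(np.int64),
                   n_bins - 1)
    p = np.bincount(q, minlength=n_bins) / len(v)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def membrane_kernels(kernel_size: int, rotations: int) -> np.ndarray:
    """Line kernels: a central column of ones rotated through evenly spaced
    angles over [0, 180)."""
    if kernel_size % 2 == 0:
        raise ValueError("membrane kernel size must be odd")
    base = np.zeros((kernel_size, kernel_size))
    base[:, kernel_size // 2] = 1.0
    kernels = []
    for r in range(rotations):
        k = sk_rotate(base, -(180.0 * r / rotations), order=1,
                      preserve_range=True)
        # unit-sum normalisation keeps responses comparable across angles
        # (and annihilates rotation-to-rotation variation on constants)
        kernels.append(k * (kernel_size / k.sum()))
    return np.stack(kernels)


def membrane_projections(channel: np.ndarray,
                         recipe: FeatureRecipe) -> np.ndarray:
    """Rotation-stack reductions of line-kernel convolutions; H x W x P."""
    x = np.asarray(channel, dtype=np.float64)
    kernels = membrane_kernels(recipe.membrane_kernel_size,
                               recipe.membrane_rotations)
    stack = np.stack([ndimage.convolve(x, k, mode="reflect")
                      for k in kernels])
    return np.stack([PROJECTION_FUNCS[p](stack)
                     for p in recipe.membrane_projections], axis=-1)


# ---------------------------------------------------------------------------
# the stack, the forest
# ---------------------------------------------------------------------------

def build_feature_stack(image: StickImage, roi_mask: MaskRaster | None,
                        recipe: FeatureRecipe) -> PixelFeatureStack:
    """Concatenate colour, edge, texture and neighbourhood features.

    Features are computed over the image as given (normally the ROI crop
    from stage 1); the ROI mask only flags which pixels may participate in
    training and inference.
    """
    px = image.pixels.astype(np.float64) / 255.0
    if roi_mask is not None and roi_mask.values.shape != px.shape[:2]:
        raise ValueError("ROI mask is not aligned with the image")
    lum = 0.2126 * px[..., 0] + 0.7152 * px[..., 1] + 0.0722 * px[..., 2]
    chans = []
    if "RGB" in recipe.color_spaces:
        chans += [px[..., c] for c in range(3)]
    if "HSV" in recipe.color_spaces:
        hsv = rgb2hsv(image.pixels)
        chans += [hsv[..., c] for c in range(3)]
    for s1, s2 in recipe.dog_sigma_pairs:
        chans.append(dog_filter(lum, s1, s2))
    chans.append(local_entropy(lum, recipe.entropy_radius,
                               recipe.entropy_bins))
    mp = membrane_projections(lum, recipe)
    chans += [mp[..., i] for i in range(mp.shape[-1])]
    size = 2 * recipe.neighborhood_radius + 1
    nmean = ndimage.uniform_filter(lum, size, mode="reflect")
    nsq = ndimage.uniform_filter(lum ** 2, size, mode="reflect")
    chans += [nmean, np.sqrt(np.maximum(nsq - nmean ** 2, 0.0))]
    feats = np.stack(chans, axis=-1).astype(np.float32)
    roi = None if roi_mask is None else roi_mask.binarize().values
    return PixelFeatureStack(image_id=image.id, features=feats,
                             channel_names=recipe.channel_names(),
                             recipe_hash=recipe.digest(), roi_mask=roi)


def fit_pixel_classifier(stack: PixelFeatureStack, scribbles: ScribbleSet,
                         n_trees: int = 100, seed: int = 0) -> PixelClassifier:
    """Train a random forest on the scribbled pixels only."""
    scribbles.validate(stack.features.shape[:2])
    if stack.roi_mask is not None:
        for r, c in list(scribbles.positive_pixels) + \
                list(scribbles.negative_pixels):
            if not stack.roi_mask[r, c]:
                raise ValueError(f"scribble ({r}, {c}) lies outside the ROI")
    pos = np.asarray(scribbles.positive_pixels, dtype=int)
    neg = np.asarray(scribbles.negative_pixels, dtype=int)
    X = np.vstack([stack.features[pos[:, 0], pos[:, 1]],
                   stack.features[neg[:, 0], neg[:, 1]]])
    y = np.concatenate([np.ones(len(pos), dtype=int),
                        np.zeros(len(neg), dtype=int)])
    forest = RandomForestClassifier(n_estimators=n_trees,
                                    max_features="sqrt", random_state=seed,
                                    n_jobs=1)
    forest.fit(X, y)
    acc = float(forest.score(X, y))
    return PixelClassifier(forest=forest, n_trees=n_trees,
                           recipe_hash=stack.recipe_hash,
                           train_accuracy=acc)


def predict_browning_labels(classifier: PixelClassifier,
                            stack: PixelFeatureStack,
                            roi_mask: MaskRaster | None = None,
                            min_component_px: int = 20) -> MaskRaster:
    """Classify every ROI pixel, then drop connected components smaller than
    ``min_component_px``.  Refuses stacks built under a different recipe."""
    if classifier.recipe_hash != stack.recipe_hash:
        raise ValueError(
            "feature recipe mismatch: classifier was trained under "
            f"{classifier.recipe_hash}, stack built under {stack.recipe_hash}")
    h, w, f = stack.features.shape
    roi = stack.roi_mask if roi_mask is None else roi_mask.binarize().values
    if roi is None:
        roi = np.ones((h, w), dtype=np.uint8)
    sel = roi.astype(bool)
    pred = np.zeros((h, w), dtype=bool)
    if sel.any():
        votes = classifier.forest.predict(
            stack.features[sel].reshape(-1, f))
        pred[sel] = votes.astype(bool)
    if min_component_px > 0 and pred.any():
        lbl, ncomp = ndimage.label(pred)
        sizes = ndimage.sum_labels(pred, lbl, index=np.arange(1, ncomp + 1))
        small = np.nonzero(sizes < min_component_px)[0] + 1
        if small.size:
            pred[np.isin(lbl, small)] = False
    return MaskRaster(stack.image_id, pred.astype(np.uint8))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_classifier(classifier: PixelClassifier, recipe: FeatureRecipe,
                    seed: int, path) -> None:
    joblib.dump({"version": 1, "forest": classifier.forest,
                 "n_trees": classifier.n_trees,
                 "recipe": vars(recipe), "recipe_hash": classifier.recipe_hash,
                 "seed": seed,
                 "train_accuracy": classifier.train_accuracy}, str(path))


def load_classifier(path) -> tuple[PixelClassifier, FeatureRecipe]:
    d = joblib.load(str(path))
    recipe_kwargs = {
        k: (tuple(tuple(x) if isinstance(x, list) else x for x in v)
            if isinstance(v, list) else v)
        for k, v in d["recipe"].items()}
    recipe = FeatureRecipe(**recipe_kwargs)
    clf = PixelClassifier(forest=d["forest"], n_trees=d["n_trees"],
                          recipe_hash=d["recipe_hash"],
                          train_accuracy=d.get("train_accuracy", float("nan")))
    return clf, recipe
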