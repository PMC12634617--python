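import json

import numpy as np
import pytest

from stickseg import metrics
from stickseg.dataset import (AugmentationPolicy, MaskRaster,
                              PolygonAnnotation, Stage, StickImage,
                              augment_pair, expand_dataset, mask_to_polygons,
                              parse_polygon_annotation, polygon_to_mask,
                              split_dataset)


def labelme(shapes):
    return json.dumps({"imagePath": "img", "shapes": shapes})


class TestParseAnnotation:
    def test_single_triangle(self):
        doc = labelme([{"label": "1", "points": [[0, 0], [4, 0], [2, 3]]}])
        ann = parse_polygon_annotation(doc)
        assert len(ann.polygons) == 1
        assert ann.polygons[0].shape == (3, 2)
        assert ann.class_label == Stage.MID

    def test_empty_document(self):
        ann = parse_polygon_annotation(labelme([]))
        assert ann.polygons == []
        assert ann.class_label == Stage.UNKNOWN

    def test_two_shapes_pre_and_post(self):
        doc = labelme([
            {"label": "0", "points": [[0, 0], [2, 0], [1, 2]]},
            {"label": "2", "points": [[3, 3], [6, 3], [5, 6]]}])
        ann = parse_polygon_annotation(doc)
        assert len(ann.polygons) == 2
        assert ann.polygon_labels == [Stage.PRE, Stage.POST]

    @pytest.mark.parametrize("doc,match", [
        ("{not json", "malformed"),
        (json.dumps({"nothing": 1}), "shapes"),
        (labelme([{"label": "7", "points": [[0, 0], [1, 0], [0, 1]]}]),
         "unknown label"),
        (labelme([{"points": [[0, 0], [1, 0], [0, 1]]}]), "label"),
    ])
    def test_errors(self, doc, match):
        with pytest.raises(ValueError, match=match):
            parse_polygon_annotation(doc)


def brute_force_inside(poly, x, y):
    """Independent crossing-number oracle at a nudged pixel center."""
    x, y = x + 1e-6, y + 1e-6
    cnt = 0
    for i in range(len(poly)):
        x0, y0 = poly[i - 1]
        x1, y1 = poly[i]
        if (y0 > y) != (y1 > y):
            if x < (x1 - x0) * (y - y0) / (y1 - y0) + x0:
                cnt += 1
    return cnt % 2 == 1


class TestPolygonToMask:
    def test_rectangle_pixel_centers(self):
        # corners (1,1)-(4,3): 6 centers inside under the half-open rule,
        # frozen from the brute-force oracle over all 36 centers
        ann = PolygonAnnotation("t", [[[1, 1], [4, 1], [4, 3], [1, 3]]])
        mask = polygon_to_mask(ann, 6, 6).values
        expected = np.array(
            [[brute_force_inside(ann.polygons[0], c, r) for c in range(6)]
             for r in range(6)], dtype=np.uint8)
        assert mask.sum() == 6
        np.testing.assert_array_equal(mask, expected)

    def test_whole_canvas(self):
        ann = PolygonAnnotation("t", [[[0, 0], [6, 0], [6, 6], [0, 6]]])
        assert polygon_to_mask(ann, 6, 6).values.all()

    def test_empty_polygon_list(self):
        assert polygon_to_mask(PolygonAnnotation("t", []), 5, 5).values.sum() == 0

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            PolygonAnnotation("t", [[[0, 0], [1, 1]]])

    def test_matches_oracle_on_random_polygons(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            poly = rng.uniform(0, 12, (rng.integers(3, 8), 2))
            mask = polygon_to_mask(PolygonAnnotation("t", [poly]), 12, 12).values
            oracle = np.array(
                [[brute_force_inside(poly, c, r) for c in range(12)]
                 for r in range(12)], dtype=np.uint8)
            np.testing.assert_array_equal(mask, oracle)

    def test_roundtrip_through_contour_tracing(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            r0, c0 = rng.integers(1, 5, 2)
            r1, c1 = r0 + rng.integers(2, 8), c0 + rng.integers(2, 8)
            m = np.zeros((16, 16), dtype=np.uint8)
            m[r0:r1, c0:c1] = 1
            mask = MaskRaster("t", m)
            back = polygon_to_mask(mask_to_polygons(mask), 16, 16)
            assert metrics.mask_scores(back, mask).iou == 1.0


class TestSplitDataset:
    def test_exact_division(self):
        s = split_dataset([f"i{k}" for k in range(10)], (0.8, 0.1, 0.1), 0)
        assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (8, 1, 1)

    def test_published_corpus_size(self):
        ids = [f"i{k}" for k in range(3762)]
        s = split_dataset(ids, (0.8, 0.1, 0.1), 1)
        assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == \
            (3010, 376, 376)

    def test_deterministic(self):
        ids = [f"i{k}" for k in range(37)]
        a = split_dataset(ids, (0.8, 0.1, 0.1), 5)
        b = split_dataset(ids, (0.8, 0.1, 0.1), 5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            split_dataset(["a", "a", "b"], (0.8, 0.1, 0.1), 0)

    def test_partitions_for_all_sizes(self):
        for n in range(1, 501):
            s = split_dataset(list(range(n)), (0.8, 0.1, 0.1), n)
            parts = s.train_ids + s.val_ids + s.test_ids
            assert len(parts) == n and len(set(parts)) == n


def checker_image(n=32):
    rng = np.random.default_rng(0)
    return StickImage("t", rng.integers(0, 256, (n, n, 3), dtype=np.uint8))


def disk_mask(n=256, r=80):
    yy, xx = np.mgrid[0:n, 0:n]
    return MaskRaster("t", (np.hypot(yy - n / 2, xx - n / 2) < r).astype(np.uint8))


class TestAugmentPair:
    def test_disabled_policy_is_identity(self):
        img, mask = checker_image(), disk_mask(32, 10)
        out_i, out_m = augment_pair(img, mask, AugmentationPolicy.disabled(), 3)
        np.testing.assert_array_equal(out_i.pixels, img.pixels)
        np.testing.assert_array_equal(out_m.values, mask.values)

    def test_flip_is_involution(self):
        pol = AugmentationPolicy.disabled()
        pol.horizontal_flip = True
        img, mask = checker_image(), disk_mask(32, 10)
        # find a seed where the flip fires
        for seed in range(20):
            o1, m1 = augment_pair(img, mask, pol, seed)
            if not np.array_equal(o1.pixels, img.pixels):
                o2, m2 = augment_pair(o1, m1, pol, seed)
                np.testing.assert_array_equal(o2.pixels, img.pixels)
                np.testing.assert_array_equal(m1.values[:, ::-1], mask.values)
                return
        pytest.fail("flip never sampled in 20 seeds")

    def test_small_rotation_mask_iou(self):
        mask = disk_mask()
        img = StickImage("t", np.zeros((256, 256, 3), dtype=np.uint8))
        pol = AugmentationPolicy.disabled()
        pol.rotations = (10.0,)
        for seed in range(20):
            _, m1 = augment_pair(img, mask, pol, seed)
            if not np.array_equal(m1.values, mask.values):
                pol.rotations = (-10.0,)
                for seed2 in range(20):
                    _, m2 = augment_pair(img, m1, pol, seed2)
                    if not np.array_equal(m2.values, m1.values):
                        iou = metrics.mask_scores(m2, mask).iou
                        assert iou >= 0.98
                        return
        pytest.fail("rotation never sampled")

    def test_photometric_leaves_mask_untouched(self):
        img, mask = checker_image(), disk_mask(32, 10)
        pol = AugmentationPolicy(rotations=(), horizontal_flip=False)
        for seed in range(10):
            _, m = augment_pair(img, mask, pol, seed)
            np.testing.assert_array_equal(m.values, mask.values)

    def test_deterministic_under_seed(self):
        img, mask = checker_image(), disk_mask(32, 10)
        pol = AugmentationPolicy()
        a = augment_pair(img, mask, pol, 11)
        b = augment_pair(img, mask, pol, 11)
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimensions"):
            augment_pair(checker_image(8), disk_mask(9, 3),
                         AugmentationPolicy(), 0)


class TestExpandDataset:
    def test_counts(self):
        img = checker_image(8)
        assert len(expand_dataset([img], AugmentationPolicy())) == 3
        assert expand_dataset([], AugmentationPolicy()) == []

    def test_published_expansion(self):
        originals = [StickImage(f"i{k}", np.full((4, 4, 3), k % 255,
                                                 dtype=np.uint8))
                     for k in range(1254)]
        pol = AugmentationPolicy(rotations=(), noise_fraction=0.01,
                                 variants_per_original=2)
        out = expand_dataset(originals, pol)
        assert len(out) == 3762
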