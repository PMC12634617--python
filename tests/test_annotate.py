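import numpy as np
import pytest

from stickseg import fixtures, metrics
from stickseg.annotate import (FeatureRecipe, ScribbleSet,
                               histogram_entropy,
                               build_feature_stack, dog_filter,
                               fit_pixel_classifier, load_classifier,
                               local_entropy, membrane_projections,
                               predict_browning_labels, save_classifier)
from stickseg.dataset import MaskRaster, StickImage


class TestDoG:
    def test_annihilates_constants(self):
        c = np.full((32, 32), 7.3)
        assert np.allclose(dog_filter(c, 1, 2), 0.0, atol=1e-10)

    def test_impulse_response_matches_analytic(self):
        # center value of G(1) - G(2): 1/(2*pi) - 1/(8*pi)
        x = np.zeros((129, 129))
        x[64, 64] = 1.0
        expected = 1 / (2 * np.pi * 1.0 ** 2) - 1 / (2 * np.pi * 2.0 ** 2)
        assert dog_filter(x, 1, 2)[64, 64] == pytest.approx(expected,
                                                            abs=1e-6)

    def test_antisymmetry_and_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.random((24, 24))
        np.testing.assert_allclose(dog_filter(x, 1, 3),
                                   -dog_filter(x, 3, 1), atol=1e-12)
        np.testing.assert_allclose(dog_filter(2.5 * x + 4.0, 1, 2),
                                   2.5 * dog_filter(x, 1, 2), atol=1e-9)

    def test_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            dog_filter(np.ones((4, 4)), 0, 1)


class TestLocalEntropy:
    def test_homogeneous_is_zero(self):
        assert np.allclose(local_entropy(np.full((16, 16), 5.0), 2, 16), 0.0)

    def test_balanced_neighbourhoods_hit_exact_bits(self):
        # two gray values in equal counts -> 1 bit; four equally frequent
        # values -> 2 bits (the per-neighbourhood histogram formula)
        assert histogram_entropy([0, 0, 1, 1], 2) == pytest.approx(1.0)
        assert histogram_entropy([0, 1, 2, 3], 4) == pytest.approx(2.0)

    def test_matches_neighbourhood_formula_at_interior_pixels(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 8, (16, 16)).astype(float)
        e = local_entropy(x, 1, 8)
        vrange = (x.min(), x.max())
        for r, c in [(5, 5), (8, 3), (12, 12)]:
            window = x[r - 1:r + 2, c - 1:c + 2]
            assert e[r, c] == pytest.approx(
                histogram_entropy(window, 8, vrange), abs=1e-9)

    def test_bounds_on_random_input(self):
        rng = np.random.default_rng(1)
        e = local_entropy(rng.random((32, 32)), 2, 8)
        assert e.min() >= 0.0 and e.max() <= np.log2(8) + 1e-12


class TestMembraneProjections:
    def test_constant_input(self):
        recipe = FeatureRecipe()
        out = membrane_projections(np.full((32, 32), 2.0), recipe)
        assert out.shape[-1] == len(recipe.membrane_projections)
        std_idx = recipe.membrane_projections.index("std")
        assert np.allclose(out[..., std_idx], 0.0, atol=1e-9)
        for i, name in enumerate(recipe.membrane_projections):
            if name != "std":
                assert np.ptp(out[..., i]) < 1e-9

    def test_vertical_line_preferred_by_vertical_kernel(self):
        from stickseg.annotate import membrane_kernels
        img = np.zeros((64, 64))
        img[:, 32] = 1.0
        kernels = membrane_kernels(19, 6)
        from scipy import ndimage
        r0 = ndimage.convolve(img, kernels[0], mode="reflect")   # vertical
        r90 = ndimage.convolve(img, kernels[3], mode="reflect")  # horizontal
        on_line = slice(12, 52)
        assert np.all(r0[on_line, 32] >= r90[on_line, 32] - 1e-9)
        recipe = FeatureRecipe()
        out = membrane_projections(img, recipe)
        mx = out[..., recipe.membrane_projections.index("max")]
        assert mx[32, 32] == pytest.approx(mx.max())

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            FeatureRecipe(membrane_kernel_size=18)


class TestFeatureStack:
    def test_default_recipe_channel_count(self):
        img = StickImage("t", np.random.default_rng(0).integers(
            0, 256, (32, 32, 3), dtype=np.uint8))
        stack = build_feature_stack(img, None, FeatureRecipe())
        assert stack.features.shape == (32, 32, 18)
        assert len(stack.channel_names) == 18

    def test_finite_at_dynamic_range_extremes(self):
        px = np.zeros((24, 24, 3), dtype=np.uint8)
        px[:12] = 255
        stack = build_feature_stack(StickImage("t", px), None, FeatureRecipe())
        assert np.all(np.isfinite(stack.features))


def separable_fixture():
    """White background with a brown rectangle: linearly separable."""
    px = np.full((40, 40, 3), 245, dtype=np.uint8)
    px[10:30, 10:30] = (120, 70, 30)
    gt = np.zeros((40, 40), dtype=np.uint8)
    gt[10:30, 10:30] = 1
    img = StickImage("t", px)
    roi = MaskRaster("t", np.ones((40, 40), dtype=np.uint8))
    rng = np.random.default_rng(0)
    pos = [tuple(p) for p in np.argwhere(gt)[rng.choice(400, 50, replace=False)]]
    neg_all = np.argwhere(gt == 0)
    neg = [tuple(p) for p in neg_all[rng.choice(len(neg_all), 50,
                                                replace=False)]]
    return img, roi, gt, ScribbleSet("t", pos, neg)


class TestPixelClassifier:
    def test_separable_fixture_perfect_training_accuracy(self):
        img, roi, gt, scr = separable_fixture()
        stack = build_feature_stack(img, roi, FeatureRecipe())
        clf = fit_pixel_classifier(stack, scr, n_trees=25, seed=0)
        assert clf.train_accuracy == 1.0
        pred = predict_browning_labels(clf, stack, min_component_px=0)
        assert metrics.mask_scores(pred, gt).iou > 0.95

    def test_deterministic_under_seed(self):
        img, roi, _, scr = separable_fixture()
        stack = build_feature_stack(img, roi, FeatureRecipe())
        a = predict_browning_labels(
            fit_pixel_classifier(stack, scr, 25, seed=3), stack)
        b = predict_browning_labels(
            fit_pixel_classifier(stack, scr, 25, seed=3), stack)
        np.testing.assert_array_equal(a.values, b.values)

    def test_single_class_scribbles_rejected(self):
        img, roi, _, scr = separable_fixture()
        stack = build_feature_stack(img, roi, FeatureRecipe())
        with pytest.raises(ValueError):
            fit_pixel_classifier(stack, ScribbleSet("t", scr.positive_pixels,
                                                    []), 10, 0)

    def test_recipe_hash_mismatch_refused(self):
        img, roi, _, scr = separable_fixture()
        stack = build_feature_stack(img, roi, FeatureRecipe())
        clf = fit_pixel_classifier(stack, scr, 10, 0)
        other = build_feature_stack(img, roi,
                                    FeatureRecipe(entropy_radius=3))
        with pytest.raises(ValueError, match="recipe"):
            predict_browning_labels(clf, other)

    def test_negative_only_image_yields_empty_mask(self):
        img, roi, _, scr = separable_fixture()
        stack = build_feature_stack(img, roi, FeatureRecipe())
        clf = fit_pixel_classifier(stack, scr, 25, 0)
        white = StickImage("w", np.full((40, 40, 3), 245, dtype=np.uint8))
        wstack = build_feature_stack(white, roi, FeatureRecipe())
        pred = predict_browning_labels(clf, wstack, min_component_px=0)
        assert pred.values.sum() == 0

    def test_component_cleanup_drops_small_blobs(self):
        px = np.full((64, 64, 3), 245, dtype=np.uint8)
        gt = np.zeros((64, 64), dtype=np.uint8)
        for (r, c, h, w) in [(5, 5, 12, 12), (40, 40, 12, 12), (30, 8, 1, 5)]:
            px[r:r + h, c:c + w] = (120, 70, 30)
            gt[r:r + h, c:c + w] = 1
        img = StickImage("t", px)
        roi = MaskRaster("t", np.ones((64, 64), dtype=np.uint8))
        rng = np.random.default_rng(1)
        pos = [tuple(p) for p in np.argwhere(gt[:20, :20])[::6]]
        neg = [tuple(p) for p in np.argwhere(gt == 0)[::40]]
        stack = build_feature_stack(img, roi, FeatureRecipe())
        clf = fit_pixel_classifier(stack, ScribbleSet("t", pos, neg), 25, 0)
        raw = predict_browning_labels(clf, stack, min_component_px=0)
        cleaned = predict_browning_labels(clf, stack, min_component_px=20)
        from scipy import ndimage
        _, n_raw = ndimage.label(raw.values)
        _, n_clean = ndimage.label(cleaned.values)
        assert n_raw >= 3
        assert n_clean == 2

    def test_output_contained_in_roi(self):
        img, _, _, scr = separable_fixture()
        rng = np.random.default_rng(2)
        roi = MaskRaster("t", (rng.random((40, 40)) > 0.3).astype(np.uint8))
        scr = ScribbleSet(
            "t",
            [p for p in scr.positive_pixels if roi.values[p]][:5] or
            [tuple(np.argwhere(roi.values)[0])],
            [p for p in scr.negative_pixels if roi.values[p]][:5] or
            [tuple(np.argwhere(roi.values)[1])])
        stack = build_feature_stack(img, roi, FeatureRecipe())
        clf = fit_pixel_classifier(stack, scr, 10, 0)
        pred = predict_browning_labels(clf, stack, min_component_px=0)
        assert not np.any(pred.values & ~roi.values)

    def test_persistence_roundtrip(self, tmp_path):
        img, roi, _, scr = separable_fixture()
        recipe = FeatureRecipe()
        stack = build_feature_stack(img, roi, recipe)
        clf = fit_pixel_classifier(stack, scr, 10, 7)
        path = tmp_path / "clf.joblib"
        save_classifier(clf, recipe, 7, path)
        loaded, loaded_recipe = load_classifier(path)
        assert loaded.recipe_hash == clf.recipe_hash
        assert loaded_recipe.digest() == recipe.digest()
        a = predict_browning_labels(clf, stack)
        b = predict_browning_labels(loaded, stack)
        np.testing.assert_array_equal(a.values, b.values)


class TestLabelRecovery:
    def test_recovers_generator_ground_truth(self):
        """Scribble-trained forests recover fixture browning masks."""
        ious = []
        recipe = FeatureRecipe()
        for s in range(10):
            b = fixtures.generate_scene(fixtures.SceneSpec(
                seed=100 + s, canvas=(128, 128),
                nominal_browning_ratio=0.45, n_blobs=4))
            stack = build_feature_stack(b.image, b.stick_mask, recipe)
            rng = np.random.default_rng(s)
            gt = b.browning_mask.values.astype(bool)
            stick = b.stick_mask.values.astype(bool)
            pos = np.argwhere(gt)
            neg = np.argwhere(stick & ~gt)
            scr = ScribbleSet(
                b.image.id,
                [tuple(p) for p in pos[rng.choice(len(pos), 50, replace=False)]],
                [tuple(p) for p in neg[rng.choice(len(neg), 50, replace=False)]])
            clf = fit_pixel_classifier(stack, scr, n_trees=100, seed=s)
            pred = predict_browning_labels(clf, stack, min_component_px=20)
            ious.append(metrics.mask_scores(pred, b.browning_mask).iou)
        assert float(np.mean(ious)) >= 0.9
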