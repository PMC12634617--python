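import numpy as np
import pytest

from stickseg import metrics
from stickseg.contour import (ContourModelConfig, GhostConvSpec,
                              VanillaBlockSpec, assemble_contour_model,
                              build_ghost_conv, build_vanilla_block,
                              extract_roi, predict_instances,
                              standard_conv_params, test_scale_config as small_config,
                              vanilla_config, vg_config)
from stickseg.dataset import MaskRaster, Stage, StickImage
from stickseg.nn import Tensor


class TestGhostConv:
    def test_worked_parameter_count(self):
        # primary 16->16 1x1 with bias (272) + cheap depthwise 3x3 (160)
        layer = build_ghost_conv(GhostConvSpec(16, 32, primary_kernel=1,
                                               ratio=2, cheap_kernel=3))
        assert layer.primary.num_parameters() == 272
        assert layer.cheap.num_parameters() == 160
        assert layer.num_parameters() == 432

    def test_ratio_one_degenerates_to_standard_conv(self):
        rng = np.random.default_rng(0)
        layer = build_ghost_conv(GhostConvSpec(4, 8, primary_kernel=3,
                                               ratio=1))
        x = Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))
        from stickseg.nn import conv2d
        ref = conv2d(x, layer.primary.weight, layer.primary.bias, 1, 1)
        np.testing.assert_allclose(layer(x).data, ref.data, atol=1e-6)

    def test_cheaper_than_standard_over_spec_grid(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            cin = int(rng.integers(4, 64))
            cout = 2 * int(rng.integers(4, 64))
            k = int(rng.choice([1, 3, 5]))
            ghost = build_ghost_conv(GhostConvSpec(cin, cout,
                                                   primary_kernel=k,
                                                   ratio=2, cheap_kernel=3))
            assert ghost.num_parameters() < standard_conv_params(cin, cout, k)

    def test_invalid_ratio_divisibility(self):
        with pytest.raises(ValueError):
            GhostConvSpec(8, 9, ratio=2)


class TestVanillaBlock:
    def test_shape_contract_with_downsample(self):
        blk = build_vanilla_block(VanillaBlockSpec(64, 128, groups=2,
                                                   downsample=True))
        x = Tensor(np.random.default_rng(0).normal(
            size=(1, 64, 32, 32)).astype(np.float32))
        assert blk(x).shape == (1, 128, 16, 16)

    def test_dynamic_relu_identity_configuration(self):
        blk_dyn = build_vanilla_block(VanillaBlockSpec(
            8, 8, activation="dynamic_relu"))
        blk_rel = build_vanilla_block(VanillaBlockSpec(8, 8, activation="relu"))
        blk_rel.load_state_dict(
            {k: v for k, v in blk_dyn.state_dict().items()
             if not k.startswith("act.")})
        x = Tensor(np.random.default_rng(1).normal(
            size=(2, 8, 6, 6)).astype(np.float32))
        blk_dyn.eval()
        blk_rel.eval()
        np.testing.assert_allclose(blk_dyn(x).data, blk_rel(x).data,
                                   atol=1e-6)

    def test_grouped_halves_convolution_parameters(self):
        g2 = build_vanilla_block(VanillaBlockSpec(16, 32, groups=2))
        assert g2.conv.num_parameters() == \
            standard_conv_params(16, 32, 3, bias=False) // 2

    def test_group_mismatch(self):
        with pytest.raises(ValueError):
            VanillaBlockSpec(15, 32, groups=2)


class TestAssembly:
    def test_full_scale_footprints(self):
        vg = assemble_contour_model(vg_config())
        vn = assemble_contour_model(vanilla_config())
        assert round(vg.num_parameters() / 1e6, 1) == 1.5
        assert round(vn.num_parameters() / 1e6, 1) == 1.7

    def test_parameter_monotonicity_in_width(self):
        params = [assemble_contour_model(
            ContourModelConfig(width_multiplier=w, activation="relu")
        ).num_parameters() for w in (0.25, 0.5, 1.0)]
        assert params[0] < params[1] < params[2]

    def test_sppf_removal_and_ghost_head_reduce_parameters(self):
        base = assemble_contour_model(ContourModelConfig(
            ghost_head=False, use_sppf=True))
        no_sppf = assemble_contour_model(ContourModelConfig(
            ghost_head=False, use_sppf=False))
        vg = assemble_contour_model(ContourModelConfig(
            ghost_head=True, use_sppf=False))
        assert base.num_parameters() > no_sppf.num_parameters() \
            > vg.num_parameters()

    @pytest.mark.parametrize("size,batch", [(320, 1), (640, 1)])
    def test_forward_shape_contract(self, size, batch):
        model = assemble_contour_model(small_config(seed=1))
        x = Tensor(np.zeros((batch, 3, size, size), dtype=np.float32))
        out = model.eval()(x)
        for o, stride in zip(out["scales"], model.STRIDES):
            assert o["cls"].shape == (batch, 3, size // stride, size // stride)
        assert out["protos"].shape[2:] == (size // 4, size // 4)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ContourModelConfig(num_classes=2)


class TestPrediction:
    def test_untrained_model_blank_image_high_threshold(self):
        """Random-init nets stay silent at a 0.99 confidence threshold."""
        blank = StickImage("b", np.full((64, 64, 3), 128, dtype=np.uint8))
        hits = 0
        for seed in range(5):
            model = assemble_contour_model(small_config(seed=seed))
            hits += len(predict_instances(model, blank, 0.99, 0.7))
        assert hits == 0

    def test_output_contract(self, trained_contour, scene_bundles):
        model, _ = trained_contour
        insts = predict_instances(model, scene_bundles[0].image, 0.1, 0.7)
        assert insts, "trained model finds the stick"
        h, w = scene_bundles[0].image.shape
        confs = [p.confidence for p in insts]
        assert confs == sorted(confs, reverse=True)
        for p in insts:
            x1, y1, x2, y2 = p.box
            assert 0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h
            assert p.mask.values.shape == (h, w)

    def test_overfit_recovers_stick_masks(self, trained_contour,
                                          scene_bundles):
        """Seeded optimisation on the fixture scenes reaches mask IoU >= 0.8."""
        model, losses = trained_contour
        assert losses[49] < losses[0]
        ious = []
        for b in scene_bundles[:4]:
            insts = predict_instances(model, b.image, 0.5, 0.7)
            assert len(insts) >= 1
            ious.append(metrics.mask_scores(
                insts[0].mask.binarize(), b.stick_mask).iou)
        assert float(np.mean(ious)) >= 0.8


class TestExtractROI:
    def full_mask_instance(self, img):
        m = MaskRaster(img.id, np.ones(img.shape, dtype=np.uint8))
        from stickseg.contour import InstancePrediction
        return InstancePrediction(box=(0, 0, img.shape[1], img.shape[0]),
                                  class_id=Stage.MID, confidence=1.0,
                                  mask=m)

    def test_full_mask_is_identity(self):
        img = StickImage("t", np.random.default_rng(0).integers(
            0, 255, (8, 8, 3), dtype=np.uint8))
        crop, roi, offset = extract_roi(img, self.full_mask_instance(img))
        assert offset == (0, 0)
        np.testing.assert_array_equal(crop.pixels, img.pixels)
        assert roi.values.all()

    def test_square_mask_crops_with_offset(self):
        img = StickImage("t", np.random.default_rng(1).integers(
            1, 255, (10, 10, 3), dtype=np.uint8))
        m = np.zeros((10, 10), dtype=np.uint8)
        m[2:6, 3:7] = 1
        from stickseg.contour import InstancePrediction
        inst = InstancePrediction(box=(3, 2, 7, 6), class_id=Stage.PRE,
                                  confidence=0.9,
                                  mask=MaskRaster("t", m))
        crop, roi, offset = extract_roi(img, inst)
        assert offset == (2, 3)
        assert crop.pixels.shape == (4, 4, 3)
        np.testing.assert_array_equal(crop.pixels, img.pixels[2:6, 3:7])
        assert roi.values.all()

    def test_empty_mask_errors(self):
        img = StickImage("t", np.zeros((8, 8, 3), dtype=np.uint8))
        from stickseg.contour import InstancePrediction
        inst = InstancePrediction(box=(0, 0, 1, 1), class_id=Stage.PRE,
                                  confidence=0.5,
                                  mask=MaskRaster("t", np.zeros((8, 8),
                                                                dtype=np.uint8)))
        with pytest.raises(ValueError, match="no ROI"):
            extract_roi(img, inst)
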