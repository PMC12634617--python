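"""Shared fixtures: a small synthetic scene corpus and the two networks
trained on it (session-scoped, so the expensive optimisation runs once)."""

from __future__ import annotations

import pytest

from stickseg import fixtures, pipeline
from stickseg.contour import assemble_contour_model
from stickseg.contour import test_scale_config as contour_test_config
from stickseg.rsunet import assemble_rsunet
from stickseg.rsunet import test_scale_config as rsunet_test_config

SCENE_SPECS = [
    dict(seed=40, nominal_browning_ratio=0.45, stage=1),
    dict(seed=41, nominal_browning_ratio=0.35, stage=1),
    dict(seed=42, nominal_browning_ratio=0.55, stage=1),
    dict(seed=43, nominal_browning_ratio=0.75, stage=2),
    dict(seed=44, nominal_browning_ratio=0.80, stage=2),
    dict(seed=45, nominal_browning_ratio=0.05, stage=0),
]


@pytest.fixture(scope="session")
def scene_bundles():
    """Six 64x64 scenes spanning the three maturity stages."""
    return [fixtures.generate_scene(fixtures.SceneSpec(
        canvas=(64, 64), n_blobs=3, **kw)) for kw in SCENE_SPECS]


@pytest.fixture(scope="session")
def trained_contour(scene_bundles):
    """Contour net overfitted on the scene corpus; returns (model, losses)."""
    model = assemble_contour_model(contour_test_config(seed=0))
    losses = pipeline.train_contour(model, scene_bundles, steps=400,
                                    lr=2e-3, seed=0)
    return model, losses


roi_training_arrays = pipeline.roi_training_arrays


@pytest.fixture(scope="session")
def trained_rsunet(scene_bundles):
    """RS-UNet overfitted on the scene ROIs; returns (model, losses, data)."""
    imgs, masks = roi_training_arrays(scene_bundles)
    model = assemble_rsunet(rsunet_test_config(seed=0))
    losses = pipeline.train_rsunet(model, imgs, masks, steps=150, lr=3e-3,
                                   seed=0)
    return model, losses, (imgs, masks)
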