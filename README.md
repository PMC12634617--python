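# stickseg

Machine-vision quantification of browning maturity for shiitake
cultivation sticks.

In factory-scale shiitake production, bagged substrate cylinders
("cultivation sticks") mature as their surface mycelium browns; the
fraction of the stick surface that has pigmented is the practical maturity
indicator. Measuring it from photographs is awkward: the substrate is
textured, the plastic bag glares, and light browning resembles both the
background and the film. `stickseg` implements a two-stage pipeline for
growers and phenotyping researchers that turns an RGB photograph into a
browning report:

1. **Contour extraction** — a lightweight anchor-free instance segmenter
   (VanillaNet-style grouped-convolution backbone, GhostConv segmentation
   head, prototype mask bank) finds the stick silhouette and classifies
   the browning stage (pre / mid / post).
2. **Semi-automatic labelling** — a random-forest pixel classifier trained
   from a few user scribbles inside the extracted ROI builds browning
   label masks from an 18-channel feature stack (RGB/HSV,
   difference-of-Gaussians, local entropy, membrane projections,
   neighbourhood statistics).
3. **Browning segmentation** — RS-UNet, a ResNet50 encoder–decoder with a
   dual-branch input adapter, a triple-3×3 stem, a hybrid grouped /
   depthwise-separable decoder with 30 % spatial dropout, and a 7×7
   mean/max spatial-attention gate on every skip connection. Its output
   yields the browning area ratio

   ratio = 100 · |browning ∩ ROI| / |ROI| (percent),

   the stage label, and a pigment-intensity heatmap.

The optimised RS-UNet assembles to **38.92 M** trainable parameters versus
**61.12 M** for the plain ResNet50-U-Net baseline (a 36.31 % reduction);
the contour net assembles to **1.5 M** with the Ghost head and **1.7 M**
with the standard head. The networks run on a small numpy autodiff engine
(`stickseg.nn`) — no GPU frameworks required.

No image corpus is distributed; `stickseg.fixtures` renders seeded
synthetic stick scenes (red/green backgrounds, three exposure levels,
soft-edged browning blobs, bag glare) with exact ground truth, and the
whole test suite runs on them.

## Worked example

Train both stages at test scale on three synthetic scenes and report
ratios:

```python
from stickseg import fixtures, pipeline
from stickseg.contour import assemble_contour_model, test_scale_config as ctest
from stickseg.rsunet import assemble_rsunet, test_scale_config as rtest

specs = [dict(seed=40, nominal_browning_ratio=0.45, stage=1),
         dict(seed=41, nominal_browning_ratio=0.35, stage=1),
         dict(seed=42, nominal_browning_ratio=0.55, stage=1)]
bundles = [fixtures.generate_scene(
    fixtures.SceneSpec(canvas=(64, 64), n_blobs=3, **kw)) for kw in specs]

stage1 = assemble_contour_model(ctest(seed=0))
pipeline.train_contour(stage1, bundles, steps=400, lr=2e-3, seed=0)

# stage 2 trains on stick-masked ROI crops with the generator's labels
imgs, masks = pipeline.roi_training_arrays(bundles)
stage2 = assemble_rsunet(rtest(seed=0))
pipeline.train_rsunet(stage2, imgs, masks, steps=150, lr=3e-3, seed=0)

reports = pipeline.run_two_stage_models(stage1, stage2,
                                        [b.image for b in bundles],
                                        confidence=0.5)
for b, r in zip(bundles, reports):
    print(f"{r.image_id}: stage={r.stage.name}  ratio={r.ratio_percent:.2f}%"
          f"  (generator truth {100*b.achieved_ratio:.2f}%)")
```

Output:

```
scene_00000040: stage=MID  ratio=42.30%  (generator truth 45.30%)
scene_00000041: stage=MID  ratio=30.60%  (generator truth 33.85%)
scene_00000042: stage=MID  ratio=52.32%  (generator truth 53.90%)
```

Each line is one image: the stage classified by stage 1 and the percentage
of the detected stick surface that stage 2 segments as browned, against
the synthetic ground truth. The same flow is available from the shell:

```bash
stickseg generate-fixtures --n 6 --seed 1 --out corpus/
stickseg train-contour  --corpus corpus/ --out run/ --steps 400
stickseg train-browning --corpus corpus/ --out run/ --steps 300
stickseg infer --corpus corpus/ --stage1-weights run/contour.ckpt \
               --stage2-weights run/browning.ckpt --out reports.json
stickseg audit --model rsunet        # parameter/FLOP audit of a profile
```

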