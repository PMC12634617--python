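# Methods

`stickseg` quantifies the browning maturity of shiitake cultivation sticks
from RGB photographs. Browning — the progressive pigmentation of the
surface mycelium as the substrate matures — is summarised per image as the
**browning area ratio**: 100 × (browning pixels inside the stick region) /
(stick-region pixels). The pipeline has two learned stages plus a
semi-automatic labelling tool:

1. a lightweight anchor-free instance segmenter extracts the stick
   silhouette and classifies the maturity stage (pre / mid / post);
2. a random-forest pixel classifier, trained from a handful of user
   scribbles inside that ROI, produces browning label masks;
3. an attention-augmented ResNet50 encoder–decoder (RS-UNet) segments the
   browning region and the ratio, stage and a pigment-intensity heatmap are
   reported.

## Numerical core

No GPU tensor library is used: `stickseg.nn` is a compact reverse-mode
autodiff engine on numpy arrays (im2col convolutions with channel groups,
batch normalisation, pooling, bilinear resampling, spatial dropout, AdamW).
It is small enough to audit and fast enough to train the test-scale model
profiles on one CPU; full-scale profiles are assembled for parameter and
FLOP audits.

## Stage 1 — contour network

A single-stage, anchor-free detector in the YOLO mould. The backbone
stacks VanillaNet-style blocks: one grouped 3×3 convolution (groups = 2),
batch norm, and a dynamic rectifier `y = relu(x)·(a_c + b_c·σ(GAP_c(x)))`
whose per-channel gates initialise to plain ReLU. Blocks carry no residual
additions or internal attention; there is no spatial-pyramid-pooling block
in the lightweight profile (its receptive-field role is absorbed by the
grouped blocks and the top-down neck). Decoupled heads at strides 8/16/32
emit 3-way class logits, ltrb box offsets (log-scale, decoded about the
cell center) and 32 prototype coefficients; a prototype bank at stride 4
composes instance masks. In the VG profile every 3×3 head/prototype
convolution is a **GhostConv**: a primary convolution producing half the
output channels and a cheap depthwise convolution generating the rest.

Channel plan (stem/stages 24/48/96/192/320, head width 48, prototype width
64, stage depths 2/2/3/1) was fixed so the two full-scale profiles land on
their published footprints: 1,695,805 parameters with the standard head
(1.7 M) and 1,489,165 with the Ghost head (1.5 M). Test profiles use a
0.25 width multiplier, depth 1 per stage, and plain ReLU.

Training uses a center-cell assignment: the cell containing the ground-
truth box center at each scale is the positive sample for classification
(BCE), box regression (squared error on log-ltrb) and mask-coefficient
supervision (BCE of the composed prototype mask against the downsampled
instance mask); all other cells train toward zero class scores. This is
deliberately simpler than dynamic label assignment — one stick per frame
is the imaging protocol — and suffices for the desk-scale fitting the
suite exercises. Inference applies class-agnostic NMS (IoU 0.7 default,
confidence 0.25) and returns instances sorted by confidence.

## Semi-automatic annotation

Per-pixel features (18 channels under the default recipe): RGB and HSV;
difference-of-Gaussians on luminance at σ pairs (1,2), (2,4), (4,8)
(reflective boundaries; kernels truncated at 6σ so impulse responses match
the analytic Gaussian difference to ~1e-9); local Shannon entropy (bits)
of a 64-bin histogram over a 9×9 window; six membrane projections
(sum/mean/max/min/median/std over a 19×19 line kernel rotated through 6
angles, each rotation unit-sum normalised); and neighbourhood mean/std of
luminance at radius 2. Features are computed on the ROI crop — background
suppression is the point of stage 1 — and pixels outside the ROI never
train or predict.

The classifier is a 100-tree random forest (scikit-learn, √F features per
split, unlimited depth, seeded). Predictions are restricted to the ROI and
connected components smaller than 20 px are removed. A digest of the
feature recipe is embedded in the classifier; predicting on a stack built
under a different recipe raises rather than silently proceeding.

## Stage 2 — RS-UNet

Encoder: ResNet50 bottleneck stages (widths 256/512/1024/2048, depths
3/4/6/3, batch norm, no conv biases). The optimised profile prepends an
**input adapter** — a colour branch `ReLU(W_rgb∗X+b)` (16 ch) and an edge
branch on `X − avgpool_3×3(X)` (16 ch), concatenated and fused by a 3×3
convolution to 64 channels (19,392 parameters; spatial dims preserved) —
and replaces the classic 7×7 stem with three stacked 3×3 convolutions
(64→64→64, first at stride 2).

Decoder: four levels of bilinear 2× upsampling, skip concatenation and a
fusion block. The deepest level fuses the 2048+1024 = 3072-channel
concatenation with a grouped 3×3 convolution (groups = 2); the middle two
levels use depthwise-separable convolutions (depthwise 3×3 + BN +
pointwise 1×1 + BN); the finest level is a plain 3×3. Spatial dropout
(p = 0.3, whole channels, training only) follows the final two levels. A
1×1 head after a last 2× upsample produces the browning-probability
raster; inputs must be multiples of 32.

**Spatial attention** gates every skip: channel-wise mean and max maps,
concatenated (2×H×W), a 7×7 convolution and a sigmoid, multiplied onto the
skip features — 99 parameters per module, exactly.

Decoder output widths (734, 719, 644, 564) are the remaining free choice;
they were fixed by an integer search against the published footprints of
the baseline (61.12 M) and optimised (38.92 M) models. The assembled
counts are 61,115,325 and 38,923,976 — within 4 parameters of the
published exact integers, which do not decompose exactly under the layer
conventions documented here. The published ablation attributes ~54 k
parameters to the attention module; the mean/max–7×7–sigmoid construction
implemented here costs 4×99, so the intermediate ablation rows are not
reproduced — the full-model and baseline footprints are.

Loss: binary cross-entropy plus Dice (equal weights), AdamW. Full-scale
reference hyperparameters: lr 1e-4, batch 4, 1024×448 inputs; the test
profile uses width 0.25, depth 1 per stage and 64 px inputs.

## Synthetic scenes

No imagery is deposited with the source study, so the generator renders
the documented acquisition conditions: a rounded-rectangle stick on a
uniform red or green background, band-limited substrate texture, soft-
edged brown blobs added until the achieved browning ratio is within ±0.02
of the nominal target, optional specular bag-glare streaks, and exposure
gains 0.8/1.0/1.25 (low/normal/over). Blob disks are the ground-truth
mask; the colour ramp crosses 50 % opacity exactly on the disk edge, so a
pixel classifier thresholding colour recovers the mask. Stage labels
follow generator-convention ratio bands (pre < 0.10, mid 0.30–0.60,
post > 0.70). The scenes exercise the stated difficulty factors — fuzzy
boundaries, background/browning colour similarity, glare — but make no
claim of statistical realism: passing tests demonstrate that the
implementation learns and measures correctly, not field accuracy.

## Evaluation conventions

Detection: greedy confidence-ordered one-to-one matching at IoU ≥ 0.5
(Hungarian matching behind a flag); empty-set conventions are explicit
(no predictions + no truths → precision 1). Segmentation: pixel-set
precision, recall, F1, IoU, with micro (pixel-pooled) and macro
(per-image averaged) modes both available since published F1 values are
consistent with per-image averaging. mIoU is the arithmetic class mean.
Complexity audits report parameters, serialized size, and traced FLOPs
under both the MAC and 2-op conventions at 640×640.

Pigment heatmaps are a reconstruction: inverse normalized luminance,
min–max rescaled inside the browning mask (uniform regions map to 0.5),
zero outside. This is a visual read-out, not colorimetry.

## Problem sizes and determinism

The test suite trains both networks once per session on six 64×64 scenes
(contour: 400 steps, lr 2e-3; RS-UNet: 150 steps, lr 3e-3) and reuses them
across overfit, contract and end-to-end tests; the forest recovery check
uses ten 128×128 scenes. Every stochastic component — scene rendering,
augmentation draws, weight init, dropout, forest fitting — takes an
explicit seed, and identical (config, seed, corpus) triples reproduce
byte-identical reports.

## Known limitations

- The published per-dataset accuracy/recall/IoU table values require the
  authors' 3,762-image corpus, which is not deposited; they are out of
  scope here and nothing in this package claims them.
- The center-cell assignment and single-instance policy assume one stick
  per frame; crowded frames are flagged, not split.
- The exact published parameter integers are matched to within single
  digits, not exactly (see the decoder-width discussion above).
- Synthetic scenes are deliberately stylised; real sticks add wrinkled
  film, yellow-water staining and 3-D curvature the generator does not
  model.
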