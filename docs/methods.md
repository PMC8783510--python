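# Methods

## Problem setting and model

Each grain image gets a single label, chalky or non-chalky; the pixel-level
location of the chalk is never shown to the model. A CNN is trained on the
binary task, and class activation maps of the *chalky* logit are used at
inference to localize and quantify the chalk. Heatmaps are always computed
for the chalky class (index 1), regardless of the predicted label; whether
a grain's record is gated on its prediction is a downstream choice
(`quantify_batch(gate_on_prediction=...)`, default on, so grains predicted
non-chalky report score 0 and an empty mask).

The built-in backbone (`tiny`) is three blocks of 3×3 convolution (same
padding) → ReLU → 2×2 max pooling with 8/16/32 channels, global average
pooling and a 2-logit linear head; input 64×64 RGB, scaled to [−1, 1] by a
direct bilinear resize without aspect preservation. It is implemented on
numpy with hand-written exact backpropagation, which keeps the package free
of a deep-learning runtime and makes the quantity Grad-CAM needs — the
gradient of the class logit with respect to intermediate feature maps —
available exactly, testable against finite differences, and bit-reproducible
under a fixed seed. Larger ImageNet-family backbones are deliberately not
bundled: requesting one raises a configuration error. On scans of real
polished/unpolished rice a pretrained deep backbone would be the appropriate
instrument; the tiny backbone is the CPU-trainable reference configuration
this package ships and tests.

Training: SGD with momentum 0.9 on cross-entropy, batch size 32, learning
rate 0.01, 30 epochs by default (all overridable; the conventional tuning
grids — batch 16/32/64, learning rate 0.1…1e-5, up to 200 epochs — are
available through the CLI). After every epoch the model is scored on the
development split and the checkpoint with the best chalky F1 is retained.
Class convention: non-chalky = 0, chalky = 1; argmax ties break toward
index 0.

## CAM engine

* **Grad-CAM**: `w_k = (1/N) Σ_ij ∂y^c/∂f^k_ij`, computed by exact
  backpropagation of the raw logit (not the softmax probability — the
  softmax would mix in the other class's evidence);
  `H = ReLU(Σ_k w_k f^k)`, then corner-aligned bilinear resize to the input
  size. Corner alignment is chosen so that a heatmap's extreme values are
  preserved exactly at the corners and results are reproducible to the bit;
  the same resize is used for every raster in the package.
* **Grad-CAM++**: pixel-wise coefficients
  `α_ij = g_ij² / (2 g_ij² + (Σ_ab f_ab) g_ij³)` with `g = ∂y^c/∂f^k`
  (elementwise powers of the first gradient, the standard closed form),
  `w_k = Σ_ij α_ij ReLU(g_ij)`; cells with a zero denominator get α = 0.
* **Score-CAM** (gradient-free): each map is upsampled, min–max normalized
  to [0, 1] and multiplied into the input; the map's weight is the softmax
  across maps of the chalky logit of the masked input. A constant map has no
  min–max normalization, so it is excluded and assigned weight exactly 0;
  constancy is tested on the feature map itself, since bilinear resampling
  of a constant is only constant up to float round-off.

## Quantification

The binarization threshold `T` is a percentage of the per-image maximum
heatmap value (mask = `H_final ≥ (T/100)·max`), inclusive at the cutoff; an
all-zero heatmap gives an empty mask. ChalkyScore divides the heatmap by its
per-image maximum before summing over grain-foreground pixels and dividing
by the grain pixel count `Z`. The max-normalization is an interpretive
choice: raw ReLU heatmap magnitudes scale with the logits and could not
guarantee the score's intended [0, 1] range ("1 = severe chalk over the
whole surface"); normalizing by the per-image maximum enforces it and makes
both the score and the mask invariant under positive rescaling of the
heatmap. The consequence worth knowing: the score is *relative* to the
image's own strongest response, and raising the maximum (e.g. a stronger
response elsewhere in the image) lowers the normalized contribution of
other pixels — so monotonicity of the score holds for changes that do not
move the per-image maximum. The grain foreground (denominator `Z`) is
Otsu-thresholded grayscale, largest connected component, holes filled,
computed in the model's input frame so heatmap, mask and grain mask share
one raster geometry. Defaults `T = 60`, layer `block2` mirror the
best-validated configuration of the grid-search protocol; both are
CLI-overridable, and a run's own grid search takes precedence.

## Cropper

Plate scans are converted to grayscale with BT.601 weights
(0.299/0.587/0.114), Canny edge detection (σ = 1.4; thresholds auto-set to
0.67/1.33 of the median gray value unless overridden), 3×3 morphological
closing (2 iterations) to bridge broken contours, hole filling, and
connected-component bounding boxes with a minimum area filter (200 px at
the default rendering scale). Two border subtleties are handled explicitly:
detection runs in an edge-replicated padded frame, because Canny suppresses
a border band and morphological erosion treats outside-image as background —
either would break the contour of a grain lying near the border; and bright
pixels in a 2-px band along the borders are added as edges after closing, so
a grain actually cut by the scan border still fills to a solid component
whose box touches the border. "Truncated" is defined as: box touches any
image border; truncated grains are dropped and counted by default.
Coordinates are 0-based with half-open boxes, rasters row-major; boxes are
sorted top-to-bottom, then left-to-right.

## Evaluation

IoU between binary chalk masks; average IoU in percent; GT-known
localization accuracy = fraction of truly chalky grains with IoU ≥ 0.5;
localization accuracy additionally requires the predicted label to be
correct, so it never exceeds the GT-known figure. The 0.5 cutoff is
inclusive (this only matters for exact-0.5 ties). All reported percentages
round half-up to 2 decimals; 0/0 ratios in precision/recall/F1 report as
0.00. The layer × threshold grid search computes one heatmap per (grain,
layer) and reuses it across thresholds; the default threshold grid is
10–80% in steps of 10 (the benchmark uses 20–80), and ties break toward the
lower layer, then the lower threshold. Group aggregation (e.g. genotype ×
panicle × treatment) reports mean ± SEM (sd/√n, ddof = 1) of chalk area and
ChalkyScore; single-record groups report SEM as NaN.

Ground-truth chalk polygons are exchanged as VGG Image Annotator v2 JSON
(v1-style region lists tolerated; non-polygon shapes skipped with a logged
warning). Rasterization sets a pixel iff its center lies inside the polygon
under the even-odd rule, so rasterized area tracks geometric area to about
half the perimeter in pixels.

## Synthetic study conditions

The generator renders what the pipeline assumes about real scans: bright
elliptical grains (default 44×26 px axes, intensity ≈ 130–160) on a
near-black background (gray 10 ± 5), ~25–30 per plate with a minimum 6-px
gap, and, on chalky grains, one bright blob (peak ≈ 70–90 added gray)
blurred with σ = 2 to give the soft boundary real chalk has. The blob is a
`sqrt(chalk_fraction)`-scaled copy of the grain ellipse, randomly offset
inside it, so its target area is met by construction at any fraction; its
binary ground truth is the support at half the peak added brightness — the
natural binary outline of a blurred object — with a 1-gray-level guard band
at that contour so the truth stays strictly separated after 8-bit
quantization. Ground-truth polygons are marching-squares outlines of the
chalk mask decimated to ≤ 100 vertices, mimicking manual click polygons.
The benchmark dataset is 16 plates × 25 grains = 400 grains, exactly half
chalky with chalk fractions uniform on [0.2, 0.5], split 2:1:1 into
train/dev/test with no grain in two splits.

What the generator does *not* emulate — translucency gradients, husk
texture on unpolished grains, abrasion stains, scratches, touching grains,
multiple chalk blobs, distinct chalk types (white-belly/core/base) — bounds
what the passing tests show: they demonstrate that the machinery (training,
gradients, heatmaps, thresholding, metrics) recovers planted signal
end-to-end, not that the tiny backbone would match a pretrained deep model's
accuracy on real rice scans.

## Numerical conventions and degenerate inputs

Float32 forward/backward with He initialization; all randomness flows from
`numpy.random.default_rng` seeds, so fixed seed + fixed data reproduces
training bit-for-bit on one BLAS. Max-pool gradient ties route to the first
maximum. A uniformly bright crop counts as all foreground; a (near-)uniform
dark crop raises an error rather than returning an empty grain mask. Empty
ground-truth masks are rejected by IoU (a chalky grain's truth is never
empty). The finite-difference check of the Grad-CAM gradients perturbs
every feature-map position by ±1e-3 and reruns the network from that layer
onward in small batches (the batch size is chosen to keep the working set
cache-resident).

## Problem sizes

Desk-scale defaults throughout: 64×64 model inputs, 400-grain benchmark,
30 epochs, grid search over 3 layers × 7 thresholds on ~50 development
chalky grains. These sizes make the whole pipeline run in minutes on one
CPU core while leaving every code path — including grid search and
polygon-based scoring — identical to what larger runs would use.
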