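# Methods

## Problem and overall design

During the post-embryonic growth period of larval zebrafish (roughly
7–12 days post-fertilization), the superficial epithelial cells (SECs)
of the skin divide by asynthetic fission — division without DNA
replication — producing connected patches ("clones") of cells that
share a heritable brainbow-style color. Both the number of SECs and the
extent of clonal division increase with the animal's overall size. The
package asks the operational question: can a local, cell-resolution
skin image predict the animal's whole-body size class?

The analysis is a pipeline of seven stages, each usable on its own:

1. **`synthetic`** — seeded generator of multicolor cell mosaics with
   full ground truth (cell and clone maps), plus whole-body silhouettes.
2. **`sizing`** — trunk-surface-area measurement, k=3 K-means staging
   into S/M/L, and fish-level train/val/test allocation (8:2, then 9:1).
3. **`features`** — clone merging at a color distance of 10 and the five
   scalar features (coverage, cell count, cell average size, color patch
   count, color patch average size); PCA scores as an alternative
   representation; feature-subtracted ablation image sets.
4. **`baselines`** — Random Forest on features or PCA scores, and the
   random-guessing floor.
5. **`cropping`** — random-crop training augmentation, isometric
   evaluation tiling, dark-ratio filtering, majority voting.
6. **`classifier`** — a 3-class CNN trainer with the dual-background
   invariance objective; bright-field branch included.
7. **`cam`** — Grad-CAM hotspot quantification of what the classifier
   attends to.

## The synthetic mosaic generator

The generator is first-class, tested code: it defines the study
conditions under which every downstream claim is verified.

**Geometry.** Founder cells are placed by dart-throwing Poisson-disc
sampling and rasterized as a Euclidean Voronoi tessellation, giving
convex, epithelium-like cells. Each founder undergoes a geometric
number of divisions (mean = `clone_division_rate`); each division
splits the clone's largest cell along a random chord, with an explicit
connectivity check so a clone always remains one connected color patch.
A fraction `1 − coverage_fraction` of cells (default coverage 0.95) is
then shed — reverted to background. When shedding disconnects a clone's
survivors, the ground-truth clone map splits them into separate
patches, because the observable quantity is the connected color patch.

**Color.** A 12-color palette with pairwise RGB distance > 30
guarantees that the merge threshold of 10 can never bridge two
founders; founders are greedily graph-colored so adjacent founders
never share a palette color, making the planted clone count
unambiguous. Per-pixel Gaussian jitter (sd 6 by default) adds texture.
Background pixels are drawn uniformly in [0, 20] and clamped to
brightness ≤ 30 after jitter; foreground pixels are kept strictly above
30. The brightness-30 rule therefore separates background exactly, by
construction.

**Class presets.** Images default to 192×192 px covering a 465 µm
field (2.42 µm/px). Presets per size class:

| class | founders | divisions/founder (mean) | ≈ cells/field |
|-------|----------|--------------------------|---------------|
| S     | 40       | 0.10                     | ~45           |
| M     | 85       | 0.50                     | ~130          |
| L     | 170      | 1.20                     | ~370          |

Both founder count and division rate increase strictly with class, so
cell count and mean clone size are strictly ordered S < M < L — the
planted signal. Per-animal lognormal variation (sd 0.05 on founders,
0.10 on the division rate) makes the classes overlap mildly at their
boundaries. Each animal gets two mosaics (anterior/posterior) drawn
from the same per-animal parameters, and one elliptical silhouette
whose area is drawn from class-conditional normals (means 6/10/14 mm²,
sd 0.7–0.9), well separated so K-means staging is essentially exact.

**What the generator does not emulate:** confocal optics (point-spread,
depth attenuation), irregular cell shapes, intensity gradients,
segmentation errors in the label map, and imaging artifacts. Passing
tests therefore demonstrate that the pipeline's logic recovers planted
structure under idealized imaging, not that any specific F-score will
transfer to real micrographs.

## Size staging and allocation

Trunk area is foreground-pixel count × (µm/px / 1000)². K-means (k=3,
fixed seed 2022, 10 restarts) runs on the 1-D areas; clusters are
relabeled S/M/L by ascending centroid, and cut-offs are midpoints
between the largest member of one cluster and the smallest of the next,
making `classify` monotone in area. Splits are assigned per fish (never
per image): test = round(0.2·N), validation = round(0.1·(N − test)),
round-half-up — the only convention that maps 361 animals to 260/29/72.
Within each total, per-class counts are apportioned by largest
remainder, i.e. stratified as closely as integers allow.

## Features and ablations

Cells are merged into clones when they share a 4-connected boundary
and their mean-RGB Euclidean distance is ≤ 10, with transitive
(union-find) closure. Color space and connectivity are deliberate
choices: Euclidean RGB is the simplest reading of "color distance", and
4-connectivity is the conservative adjacency (8-connectivity would also
merge diagonal touches). The five features follow the defining
identities exactly: average sizes are coverage divided by the
respective count, and an empty label map yields a zero vector with a
warning rather than an error.

Ablation images preserve the label-map footprint exactly and remove one
attribute at a time: `random_color_1` paints each clone one flat color
from a random six-hex-digit identifier (texture removed, clone
structure kept); `random_color_2` paints each cell flat, the
representative cell of each former clone keeping the clone's identifier
and all others drawing fresh identifiers (clone structure removed too);
`cell_less` keeps only coverage (background 0, cells gray 127). On a
mosaic without any merges, `random_color_2` equals `random_color_1`
identically — a useful consistency check.

PCA resizes each image to 224×224×3 (150,528 features), mean-centers,
and projects onto the top five axes (full SVD, float32). A Gram-matrix
eigendecomposition serves as the independent oracle in tests.

## Crop-and-vote classification

Crop sizes are physical areas (0.1 / 0.05 / 0.02 / 0.01 / 0.006 mm²)
converted through each image's µm/px: side = round(√area·1000/µm_per_px).
The axis-trimmed variants halve one side and double the other at equal
area. Training takes one uniformly placed crop per image per epoch
(520 training images over 167 epochs is exactly the ~80,000-crop
augmentation regime: 86,840), with flips, one of gamma/sigmoid contrast
(p = 0.3), one of blur/sharpen (p = 0.3), and ±30° rotation in the
voting configuration. Evaluation tiles each image with a non-overlapping
grid anchored top-left (partial edge tiles discarded), drops crops
whose dark ratio — the fraction of pixels with HSB brightness ≤ 30 —
is ≥ 0.65, and takes a plurality vote over the survivors. Ties break
by the larger summed class score, then by fixed class order S < M < L;
an all-dark image falls back to a whole-image prediction. Validation
crops pass the same dark-ratio filter as test crops.

## The classifier and its objective

Because no GPU deep-learning stack is assumed, the trainer is a small,
fully deterministic numpy engine (`cellscale.nn`): 3×3 same-padding
convolutions via im2col, ReLU, 2×2 max pooling, global average pooling,
a linear head, softmax cross-entropy, and AdamW with decoupled weight
decay. Backpropagation is verified against central finite differences
in the test suite. The default backbone `tiny_cnn` is three conv blocks
+ GAP + linear (~25k parameters at width 16).

Every training input is duplicated with its background (brightness
≤ 30) forced to 255 and to 0, and the loss is

    CE(softmax(logits_bg255), y) + w · MSE(logits_bg255, logits_bg0),

with the MSE averaged over the three logit entries. The relative
weight w defaults to 1.0 and is exposed in the config; at w = 0 the
loss reduces exactly to cross-entropy. Which branch feeds the CE term
is also configurable (bright-background by default); inference uses the
same branch. Model selection maximizes the validation score
(weighted F1 + macro F1)/2 per epoch, keeps the best checkpoint, and
stops after a patience window without improvement.

**Desk-scale training sizes.** The config defaults (lr 1e-5, weight
decay 1e-2, batch 64, ≤500 epochs, patience 50) are the fine-tuning
settings appropriate to large pretrained backbones. Training the tiny
CNN from scratch uses lr 1e-3, input side 32 px, width 12, ≤100 epochs
with patience 35. The parameter-recovery experiment runs on a 300-fish
cohort (600 images; 432/48/120 train/val/test images after fish-level
allocation) at crop area 0.01 mm² — the smallest area reported to
support reliable prediction — and verifies voted weighted F1 ≥ 0.85 on
held-out fish, with voting at least matching whole-image prediction in
seeded subsample replicates. The whole-image (no-voting) path evaluates
the same trained model on the full field resized to the input side;
because that view is far off the crop-scale training distribution, its
F1 is much lower, which is the directional effect voting is meant to
demonstrate.

The bright-field branch rescales every whole-body image to exactly
1,288×214 px before the input resize, removing absolute-size cues, and
trains without cropping or voting. Binary silhouettes are rendered as
gray body (160) on dark background (12) so the background rule and the
dual-background construction behave as for fluorescence images. Two
controls bracket it: identical silhouettes across classes stay at
chance, and class-dependent body aspect ratio (shape, not size) is
learnable above chance.

## Grad-CAM hotspots

Activation maps are taken at the ReLU output of the last conv block
(the layer preceding the classifier head); channel weights are the
spatial means of the class-logit gradients, and the rectified weighted
sum is normalized to 0–255 and resized to the source crop. Hotspots are
connected components (8-connectivity) of (CAM ≥ 120) AND a cleaned
foreground mask (brightness > 30, 2×2 erosion, 2×2 dilation); the
area in pixels of the largest hotspot is the per-crop statistic, with
peak activation reported alongside. "Largest hotspot value" is read as
area, consistent with comparing the spatial extent of attention between
classes; the mean largest-hotspot area for class L versus class S is
reported (L is expected to exceed S as attention spreads over clones),
not asserted at a fixed percentage.

## Numerical and degenerate-input conventions

- F1 zero divisions (0/0) resolve to 0 everywhere.
- Dark-ratio exclusion is a closed boundary: exactly 0.65 is excluded.
- CAM thresholding is inclusive: activation ≥ 120 survives.
- K-means requires ≥ 3 distinct areas; classes with < 3 fish are
  allocated without stratification, with a warning.
- A mosaic founder that loses every pixel during tessellation is simply
  absent; empty cells are never emitted.
- Max-pooling gradients are split evenly over tied maxima, keeping the
  backward pass deterministic.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; pipeline stages derive their seeds from the
  global seed and the stage name (CRC-mixed `SeedSequence`), so stages
  are independent but reruns are byte-identical.

## Known limitations

- The tiny CNN is a demonstration backbone; headline F-scores of
  full-scale pretrained models on real data are out of scope, and the
  synthetic cohort's effect sizes are larger than biology would give.
- The generator's clones are geometric chord-splits of convex cells;
  real clones show oriented division and curved boundaries.
- Grad-CAM at 8×8 feature resolution (32-px inputs) is coarse; hotspot
  areas are comparable within a run, not across input resolutions.
- The x/y-trimmed crop geometry is one reading of a pictorial
  definition (halve one axis, double the other at equal area).
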