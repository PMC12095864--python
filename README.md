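# cellscale

Predicting a growing animal's whole-body size class from a local,
cell-resolution skin image.

During larval zebrafish growth (~7–12 dpf), the outermost skin cells
(superficial epithelial cells, SECs) divide without DNA replication,
leaving connected same-color patches — clones — when the cells carry
heritable brainbow-style color barcodes. Cell number and clonal extent
both scale with the animal's size, so a 465 µm field of skin carries a
readable signature of a millimeter-scale quantity. `cellscale`
implements the full analysis pipeline around that idea, for
computational biologists who want to test, extend or stress the
approach without any imaging data: a ground-truth-complete synthetic
mosaic generator stands in for the microscope.

The pipeline:

- **Synthetic mosaics** — seeded Voronoi cell fields with planted
  clone structure whose cell count and clone size increase with a
  latent S/M/L class; paired whole-body silhouettes carry the class in
  their area.
- **Growth staging** — trunk surface area (mm²) from silhouettes,
  k = 3 K-means into small/medium/large, and fish-level 8:2 / 9:1
  train–validation–test allocation (both images of a fish always share
  its split).
- **Clone-resolved features** — adjacent cells within mean-RGB
  distance 10 merge transitively into clones; five scalar features per
  image (cell coverage, cell count, cell average size = coverage/count,
  color patch count, color patch average size = coverage/patch count),
  plus 224×224 PCA scores and three feature-subtracted ablation image
  sets.
- **Classifiers** — a Random Forest baseline (100 trees, seeded) and a
  CNN trained with the dual-background invariance objective
  `CE(softmax(z⁺), y) + w·MSE(z⁺, z⁻)`, where `z⁺`/`z⁻` are logits of
  the same image with its background (brightness ≤ 30) forced to 255
  and 0. Model selection uses (weighted F1 + macro F1)/2.
- **Crop-and-vote** — one random crop per image per epoch for
  training; deterministic isometric tiling at evaluation, crops with
  dark ratio ≥ 0.65 excluded, plurality vote per image.
- **Grad-CAM hotspots** — activation maps thresholded at 120, ANDed
  with a morphologically cleaned foreground mask, summarized by the
  largest connected hotspot area per crop.
- A **random-guessing floor**: uniform 3-class predictions against
  class-ratio truth, with the closed-form expectation
  `Σ_c q_c · 2q_c(1/3)/(q_c + 1/3)` as its oracle.

See `docs/methods.md` for models, parameters and conventions.

## Worked example

```python
import cellscale as cs

# one synthetic medium-size animal field, fully ground-truthed
mosaic = cs.generate_mosaic(cs.MosaicParams.for_class("M", rng_seed=7))
graph = cs.merge_clones(mosaic.image, mosaic.label_map)   # threshold 10
vec = cs.extract_features(mosaic.image, mosaic.label_map, graph)
print(vec.cell_count, mosaic.true_cell_count)    # 132 132
print(vec.color_patch_count, mosaic.true_clone_count)  # 82 82
print(round(vec.cell_average_size, 1))           # 263.6  (px/cell)
```

The extracted cell count (132) and color patch count (82) match the
planted ground truth exactly; 132 cells in 82 patches means the
average clone has ~1.6 cells — a mid-size animal, consistent with its
"M" preset. End-to-end on a cohort:

```bash
cellscale all --out runs/demo --seed 2022 --n-fish 60
```

which generates 120 images for 60 fish, stages them by K-means, trains
the Random Forest and the crop-and-vote CNN, and writes per-stage
reports (confusion matrices, macro/weighted F1) plus CAM hotspot
statistics into `runs/demo/manifest.json`. At the test scale used in
the suite (300 fish), the crop-and-vote classifier reaches a voted
weighted F1 of 0.948 on held-out fish, versus 0.355 for random
guessing.

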