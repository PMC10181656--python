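# Methods

## Pipeline

Five stages, each idempotent given config + seed, each reading only its
predecessor's outputs inside `output_dir`:

1. **simulate** — generate the synthetic labelled dataset (PNG images, PNG
   masks, CSV manifest);
2. **train** — train `n_models` tiny CNNs with distinct seeds, save
   checkpoints (`.npz`) and per-epoch accuracy histories (CSV);
3. **saliency** — for every test image × model, compute CAM and Grad-CAM at
   the last convolutional layer, upsample to input resolution, save one
   `.npy` per (image, model, method);
4. **compare** — Otsu-binarize, compute per-image IoU and CaD for every
   model pair and method, aggregate to CSV tables and heatmap figures;
5. **report** — assemble config, seeds and tables into a markdown report.

## Synthetic data generator

Each image is a dark background (intensity 0.08) with a brighter filled
ellipse (0.45) — the "skull/brain" — centred near the image centre with
semi-axes drawn uniformly from `skull_axes_range` (default 0.30–0.42 of the
side). Tumour images add a circular blob with radius from
`tumour_radius_range` (default 0.06–0.12 of the side) at a uniform random
position fully inside the ellipse, with intensity multiplied by
`tumour_intensity_gain` (default 1.8, clipped to 1); the blob's pixel set is
the ground-truth mask. Additive Gaussian noise (sd 0.03) and clipping to
[0, 1] come last. Defaults mirror the study conditions the pipeline
emulates: 55% tumour prevalence enforced as an exact rounded count, images
at a fixed square size (default 64, desk scale for the study's 150),
3 channels (grayscale replicated), stratified 80/20 train/test split, and
augmentation by rotation (±15°), zoom (0.9–1.1) and sharpness change
(0.8–1.2, an unsharp mask; exact identity at factor 1). The noise level and
geometry were chosen once so that the task is clearly learnable but not
trivial for a linear pixel model; they are not tuned per experiment.

What the generator does *not* emulate: anatomical texture, acquisition
physics, label noise, and tumours that modulate texture rather than
brightness. Passing tests therefore show that the *pipeline* measures
agreement and localisation correctly on images with known structure — not
that any particular architecture localises real tumours.

## Classifier

`TinyCNN` is the canonical CAM-compatible shape: four convolutional layers
with 16/32/64/128 filters (first kernel 2×2, the rest 3×3, ReLU), a 2×2
max-pool after each of the first three, global average pooling, and a
single dense softmax layer over two classes. Implemented directly on numpy
(im2col convolutions), so training is exactly deterministic given the seed.
GAP is the spatial mean; the sum variant differs by the constant number of
spatial positions Z, which cannot affect Otsu masks or mass-normalised
centres of mass and is absorbed by the min–max normalisation.

Two numerical choices matter for training at desk scale:

* **Frozen GAP standardisation.** Before optimisation, the per-channel mean
  and standard deviation of the GAP features over the training set are
  frozen into a fixed diagonal affine ahead of the dense layer. Without it,
  the features' large constant offsets dominate Adam's second moment and
  the head stalls at the prevalence baseline. Being a *fixed* affine, it
  folds into the dense layer — `classifier_weights` returns the folded
  `wd / sd`, so CAM and the Grad-CAM gradient identity remain exact.
* **Frozen trunk by default.** Random convolutional projections of these
  images are already linearly separable, and joint full-network updates at
  this scale destabilise the features faster than they improve them (Adam's
  per-parameter normalisation amplifies small noisy conv gradients). The
  default training regime therefore freezes the trunk and trains the
  GAP+softmax head (Adam, lr 1e-2, batch 32, cross-entropy) — the same
  frozen-base / retrained-head scheme used for transfer-learning backbones.
  `freeze_trunk=False` enables joint training (trunk lr 1e-3), and the full
  backward pass is finite-difference checked either way.

The headline run uses 400 images at 64×64, four models (seeds derived from
the master seed), 10 epochs; every model exceeds 0.85 synthetic test
accuracy with large margin, and the whole five-stage pipeline completes in
well under a minute on one CPU.

## Saliency

* CAM is computed raw and **signed** — ReLU enters only Grad-CAM's
  definition; normalisation to [0, 1] happens once, immediately before
  Otsu. The Grad-CAM ≡ ReLU(CAM)/Z identity on GAP architectures is
  verified numerically and as a bit-exact equality of Otsu masks.
* Saliency is computed for the **predicted** class by default (configurable
  to a fixed class).
* Upsampling is align-corners **bilinear** (no overshoot; identity at equal
  size); nearest-neighbour is available for ablation.
* A constant map (this genuinely occurs: the weighted sum under ReLU can be
  non-positive everywhere, a known Grad-CAM failure mode) normalises to
  all-zeros and is flagged *degenerate*.

## Metrics

* **Otsu** operates on a fixed 256-bin histogram of the [0, 1]-normalised
  map and returns the bin edge maximising the between-class variance, ties
  broken toward the lowest edge; constant maps raise an explicit error. The
  implementation is checked against an exhaustive per-edge sweep and
  against `skimage.filters.threshold_otsu` on bimodal data.
* **Binarize** keeps pixels strictly above the threshold.
* **IoU** of two empty masks is defined as 1.0 (identical maps) and logged.
* **Centre of mass** defaults to the standard mass normalisation
  (divide by Σp, coordinates always inside the grid). The printed formula
  divides by W·H instead, which makes coordinates scale with total mass;
  that variant is retained as `normalisation="as_printed"` so both
  behaviours are reproducible. CoM is computed on the normalised saliency
  values, not the binary mask.
* **CaD** divides the Euclidean CoM distance by √(W²+H²); both centres must
  have been computed on the same grid (IoU and CoM are always taken at
  input resolution, after upsampling, so differently sized feature grids
  are comparable).
* In the aggregation, a degenerate map contributes an empty mask and a
  centre of mass at the grid centre — the continuous limit of a uniform
  map — with a logged warning.

## Aggregation and rounding

Model pairs are enumerated in lexicographic canonical order so CSV outputs
are byte-stable. The summary table rounds metric columns to 4 decimals and
percentage columns to 2, **half away from zero** (the printed-table
convention; verified against the published worked-example cells). The
"Avr" row averages the unrounded per-pair values.

Derived-cell caveat: four printed E_CaD cells of the published table are
not recoverable from their rounded per-pair means — CNN+EfficientNet
prints −17.72 (recomputes to −17.68), CNN+ResNet −17.78 (−17.81),
ResNet+EfficientNet −31.92 (−31.88), VGG+EfficientNet 50.50 (50.51) — so
they were evidently computed before rounding. Only exactly recoverable
cells are used as worked-example targets; the run report notes the
discrepancy class.

## Localisation check

Because synthetic tumour masks exist, localisation is tested absolutely:
for each of 20 seeded repetitions, a fresh dataset (400 images, 64×64) and
a fresh model (10 epochs) are drawn, and the mean IoU between the Otsu-
binarized Grad-CAM mask and the ground-truth tumour mask over tumour test
images is compared with a uniformly random mask of equal area. Absolute
IoU values are modest (the frozen-trunk features spread attention), but
they exceed the random baseline consistently.

## Known limitations

* Backbone adapters (pre-trained VGG16/ResNet50/EfficientNetB7 with frozen
  bases) satisfy the same `ModelAdapter` contract but require external
  weights and are not part of the test surface; the four seeded tiny CNNs
  preserve the 6-pair comparison geometry.
* The tiny CNN's absolute localisation quality is weak by design scale;
  the pipeline measures agreement, not clinical localisation.
* Whether saliency maps should be normalised before Otsu is not fixed by
  the method definitions; normalisation-first is chosen and isolated in
  `normalize01` so the raw-threshold variant can be swapped in.
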