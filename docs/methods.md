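# Methods

## Task and data model

A registration instance is a spot array: a regular lattice (Cartesian or
hexagonal) of centroids over a whole-slide histology image, a square RGB
patch sampled at each centroid, and a per-spot label in {0, 1, ..., Nclass}
with 0 reserved for slide background. Patches are stacked into a 5-D array
`(H_ST, W_ST, Hp, Wp, 3)`; background positions are all-zero sub-arrays.

Coordinate conventions (the formats in the wild do not fix these, so they
are fixed here):

- array indices are 0-based `(row, col)`; pixel coordinates are 0-based
  with x right and y down;
- a Cartesian spot `(i, j)` sits at `origin + (j*spacing, i*spacing)`; on a
  hexagonal grid, rows of the configured parity (default: odd) are shifted
  `+spacing/2` in x and the row pitch is `spacing * sqrt(3)/2`, which makes
  all six neighbors of an interior spot exactly `spacing` away;
- an even patch side `P` crops the half-open window `[c - P/2, c + P/2)`
  around the (nearest-pixel-rounded) centroid in each axis, so crops are
  exactly `P` pixels wide; crops that overhang the image are zero-padded,
  because tissue-edge spots are legitimate foreground;
- background status is computed from raw pixels (`max = 0`) and cached at
  extraction, since channel normalization makes zero non-special. Channel
  normalization is `(x_c - mu_c) / sigma_c` with the conventional RGB
  constants mu = (0.485, 0.456, 0.406), sigma = (0.229, 0.224, 0.225),
  both configurable.

Spot annotations travel as tab-separated text with columns `array_row`,
`array_col`, `pixel_x`, `pixel_y`, `label`, a `# classes:` directive naming
the ordered class vocabulary, and `#` comments ignored; write-then-read is
the identity on records.

## Networks

**Patch classifier f.** Maps one normalized patch to a probability vector
over the Nclass *foreground* classes (softmax head; background is never a
class the networks predict — see masking below). Backbones:

- `reduced_resnet18_nobn` — an 18-layer residual network with batch
  normalization removed (deleted, not replaced) and every convolution's
  filter count divided by 4 (configurable). Removing batch norm avoids the
  train-time batch-statistics mismatch between patch-level and array-level
  batches when f is trained inside the composed model.
- `densenet121` — a densely connected network (growth 32, blocks
  6/12/24/16, batch norm), the higher-capacity option.
- `tiny_test_cnn` — two convolutions, a pooling stage, global average
  pooling and a linear head. This is the desk-scale backbone used by the
  package's own experiments and tests; it is deliberately small enough to
  train on a CPU in seconds while still separating the synthetic textures.

**Global corrector g.** Operates on the `(H_ST, W_ST, Nclass)` probability
grid with stride 1 and same padding throughout, so spatial dimensions are
preserved for any grid from 1x1 up, and ends in a per-position softmax.
The layer stack is configuration-driven; defaults keep g shallow:

- Cartesian: 3x3 conv (64 filters) -> ReLU -> 3x3 conv (64) -> ReLU ->
  1x1 conv (Nclass);
- hexagonal: two hexagonal layers (one ring, 64 filters) with ReLUs, then a
  1x1 conv (Nclass).

g consumes probabilities rather than logits: f's contract already
constrains its output to (0,1)^Nclass, and feeding bounded inputs keeps the
corrector's scale well-conditioned across backbones.

**Hexagonal convolution.** On an offset-coordinate raster, the raster
offset of each kernel position depends on the parity of the center row. A
kernel of size k covers the center plus k concentric hexagonal rings
(ring r has 6r positions), each position carrying its own weight per
channel pair. Offsets are derived from axial-coordinate ring enumeration
and converted per row parity; out-of-grid neighbors contribute zero. The
implementation is validated against brute-force neighbor enumeration (a
spot's neighbors are the spots at unit center distance) on all grids up to
6x6 for both parities, including all boundary cases.

**Background masking.** At decision time, positions whose raw patch maximum
is zero are assigned class 0 and everything else gets the argmax over
classes 1..Nclass, so the composed model cannot confuse tissue with slide
background in either direction. Background positions feed zero vectors into
g and their patch activations are never computed, which is also what makes
the checkpointed training pass memory-bounded.

**Segmentation baseline.** A 34-layer residual network over the stitched
`(H_ST*Hp, W_ST*Hp, 3)` patch mosaic, with the classification head replaced
by adaptive average pooling to `(H_ST, W_ST)` followed by a 1x1 convolution
with Nclass filters, and all filter counts divided by 4 (the reduction that
makes whole-mosaic training feasible at all; the parameter audit in the
tests checks the intended ~16x shrink of convolutional weights). Stitched
background tiles are zeroed for consistency with the patch representation.

## Losses and memory-bounded training

Patch-stage loss: mean cross-entropy `-(1/B) sum_b log f(X_b)[y_b]` over a
patch batch. Grid-stage loss: the foreground-restricted cross-entropy of
the corrected map, averaged over arrays; background positions contribute
exactly nothing, and an array with empty foreground contributes zero with a
warning. Probabilities are floored at 1e-12 inside logarithms — numerical
safety only, invisible at any reported precision.

**Gradient checkpointing.** When an array's patch activations do not fit in
memory, gradients of the grid loss are computed as: (1) run f forward over
the foreground patch list in D-sized mini-batches, keeping only the
outputs; (2) assemble the probability grid, run g forward/backward once,
obtaining g's parameter gradients and the loss gradient at every f output;
(3) re-run each mini-batch of f forward with activations cached and
back-propagate its slice of that gradient. Per-mini-batch contributions are
summed, so the final f gradient equals the monolithic gradient of the same
loss exactly — the procedure is a memory strategy, not a different
objective — and the equivalence is asserted at 1e-5 relative tolerance
(measured agreement is ~1e-15 in float64). D defaults to 32; a D larger
than the patch count degrades gracefully to a single mini-batch.

**Gradient accumulation** sums back-propagated gradients over a number of
batches (default 5) before each optimizer update, emulating larger batches;
a trailing partial group still triggers an update.

**Regimens.** All use Adam (conventional beta/eps defaults; only learning
rates are tuned):

- *two-stage*: train f on all foreground training patches for E1 epochs
  with patch batches of B*H_ST*W_ST patches (so patch- and grid-stage
  batches carry the same number of patches), fix f at its end-of-E1
  parameters, then train g for E2 epochs on the grid loss with batches of B
  arrays. Because f is frozen, its probability grids are computed once per
  array and cached for the whole of stage 2.
- *at-once*: joint training from random initialization for E epochs, g at
  learning rate `lr` and f at `alpha*lr` with `alpha` in (0, 0.1] — f's
  parameters are shared across every patch of every array, so equal step
  sizes destabilize it.
- *fine-tuning*: initialize from the two-stage result, restore g's Adam
  state (the snapshot taken at the selected stage-2 epoch, so parameters
  and moments are a consistent pair), give f a fresh optimizer at
  `alpha*lr`, and train jointly for E3 epochs.

Model selection maximizes foreground validation accuracy, ties broken by
the earliest epoch. The fine-tuning regimen includes its initialization as
an epoch-0 candidate, so zero epochs returns the pretrained model unchanged
and fine-tuning can never select a model worse on validation than its
starting point. Hyperparameter search samples `log10(lr) ~ U(-4, -3)` and
`alpha ~ U(0, 0.1)`; ensembles vote without weights among the selected
models, ties broken by the mean predicted probability of the tied classes
(or the lowest class index when probabilities are unavailable).

Every source of randomness (initialization, shuffling, sampling) flows from
the run's single seed, so a repeated run reproduces its accuracy traces and
bundle predictions bit-for-bit. No data augmentation is applied.

## Evaluation

All metrics are restricted to foreground spots: background is decided
deterministically by masking and would inflate every score. Accuracy is the
fraction of foreground spots correctly labeled. One-vs-rest AUROC uses
trapezoidal integration and AUPRC step-wise (non-interpolated) integration
(via scikit-learn; both are cross-checked against exhaustive
threshold-sweep oracles in the tests); classes absent from the truth have
undefined curves and are excluded from the unweighted macro averages with a
warning. Confusion matrices are row-normalized (rows with support sum to
1). Class adjacency counts neighboring foreground pairs — 4-neighborhood on
Cartesian grids, true 6-neighborhood on hexagonal grids, a choice the grid
geometries make natural — incrementing both symmetric entries per unordered
pair, so the total equals twice the edge count. Misclassification-density
maps show `1 - P(true class)` per spot with NaN as the background sentinel.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes, with
every artifact a pure function of (spec, seed):

- an elliptic tissue mask (default covering ~65% of the grid) surrounded by
  zero background;
- spatially contiguous class regions from one of three layouts — Voronoi
  cells around random seed spots (default), horizontal layered bands, or
  nested elliptic rings. Constructions are retried deterministically, with
  a connectivity-repair pass that merges minor components into an adjacent
  class, until every class forms one connected region under the grid's own
  neighborhood;
- per-class dot-density textures: Poisson-placed dots of class-specific
  density (default: expected counts laddered from ~3 to ~25 per 32-px
  patch) and radius over a class-specific base color, plus Gaussian pixel
  jitter, clipped to [0.01, 1] so foreground patches are never accidentally
  all-zero. Dot-density fields were chosen over natural-image crops so
  class separability and difficulty are controllable and license-free;
- noise: a label-flip rate (training labels reassigned uniformly among the
  other classes; the truth is kept separately so correction can be scored)
  and a damaged-patch rate ("blank": pixels replaced by constant mid-gray
  0.5, which removes all class information while keeping the patch
  foreground; or "blur": heavy Gaussian smoothing). Both default to 0 and
  are switched on per experiment;
- a 70/10/20 train/validation/test split by array (validation gets at
  least one array).

The desk-scale default — 24 arrays, 9x9 grid, 32-px patches, 4 classes —
was sized so the full experiment suite runs on one CPU in well under a
minute per training run. What passing these experiments shows is that the
architecture and training machinery behave as specified (the corrector
demonstrably recovers context-resolvable errors that defeat the patch
classifier); what they cannot show is performance on real histology, whose
stain variation, orientation variability, continuous class boundaries and
annotation noise the dot-texture generator deliberately does not model.

## Numerical and design notes

- All computation is float64; convolution uses im2col with explicit
  scatter-add backward passes, and every layer's backward is verified by
  finite differences in the test suite's development history and by the
  checkpointing equivalence test at run time.
- The patch classifier emits probabilities; the composed gradient therefore
  passes through two softmaxes (f's and g's). The `-1/p` loss gradient is
  floored as above.
- Bundles serialize as a directory: a JSON sidecar (configurations,
  normalization constants, class vocabulary, provenance) plus an `.npz` of
  parameters and batch-norm running statistics; save -> load -> predict is
  bit-identical.
- Hexagonal annotation rasters written to disk overlap (row pitch is
  sqrt(3)/2 of the spacing), so the written-image round trip reproduces
  patches exactly only for Cartesian layouts; hexagonal datasets remain
  exact in memory.
- Known limitations: no learning-rate schedules or early stopping beyond
  best-checkpoint selection; no class-frequency loss weighting or
  label-noise-robust objectives; no stain normalization; single-process CPU
  execution (the NumPy substrate favors verifiability over throughput, and
  the filter-reduced segmentation baseline in particular is slow at
  realistic mosaic sizes); per-class balancing in patch-stage training is
  not attempted (sampling is unweighted).
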