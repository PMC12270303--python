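# Methods

`colonytda` classifies cultured stem-cell colonies by the spatial
organization of their cells alone. The input per colony per frame is a 2-D
point cloud of cell centroids; the representation is Vietoris–Rips
persistent homology vectorized as persistence landscapes; the classifier is
a small dense feedforward network. This note records the models, the
conventions, and the design choices at every point where more than one
reasonable definition exists.

## Synthetic colonies

Real colony time series (hundreds of frames of 500–2000 segmented cells)
are replaced by a generative model with one spatial motif per treatment
class, all on a disk footprint of radius `footprint_radius` (default 175
coordinate units, 1000 cells, giving a mean nearest-neighbour spacing of
about 5 units):

* **WT** — homogeneous uniform scatter on the disk.
* **BMP4** — *fringe*: a boundary annulus (width 0.2 of the radius) whose
  point density is `fringe_density_ratio` (default 0.25) times the interior
  density. Expected counts in the two regions follow from equating total
  count with the two densities; positions are uniform within each region
  via inverse-CDF radial sampling.
* **CHIR** — *enlarged footprint*: radius scaled by `enlargement` (default
  1.35) at constant cell count, i.e. globally lower density.
* **DS** — *rosettes*: `rosette_count` (default 4) circular voids of radius
  `rosette_radius` (default 0.09, as a fraction of the footprint radius)
  enforced by hard-core rejection sampling. Rosette centres are fixed per
  colony (they persist across frames, as real rosettes do), drawn so each
  disk lies fully inside the footprint and retried up to 200 times for a
  centre separation of 2.4 hole radii.
* **DS+CHIR** — rosettes and enlargement combined.

Time is a frame index (5-minute spacing in the emulated imaging protocol).
At frame 0 every class samples the same uniform disk; motif strength
(density ratio, radius scale factor, hole radius) interpolates linearly up
to `differentiation_time` and is constant afterwards. Linear interpolation
is the simplest ramp producing the two-plateau accuracy curve the
evaluation exercises; nothing biological is claimed for it. Each frame is
an independent draw (cells are resampled, not moved), seeded by
(colony seed, frame), so datasets are reproducible point-for-point.

What the generator does *not* emulate: cell division and migration,
frame-to-frame positional correlation, segmentation noise, irregular colony
outlines, within-class morphological heterogeneity beyond Poisson
fluctuation. Passing tests on these data show the pipeline detects the
stated motifs; they are not evidence about real microscopy data.

## Rips persistence

* Filtration convention: an edge enters at Euclidean **distance** ≤ r (the
  convention of standard Rips software), not at circle-intersection radius;
  births and deaths are in distance units, matching the landscape grid.
* Dimension 0 is computed by a union-find sweep over edges sorted by
  (weight, i, j). All points are born at 0; at each merge the elder rule
  applies with ties broken by smaller point index. The finite death values
  are exactly the Euclidean MST edge weights (tested against an independent
  MST). One essential bar [0, ∞) remains. Dimension 0 uses the full
  filtration (no threshold), so it is well defined even for clouds whose
  MST has edges above the dim-1 threshold.
* Dimension 1 comes from GF(2) column reduction of the triangle boundary
  matrix, restricted to simplices with filtration value ≤ `threshold`;
  a simplex's value is its largest pairwise distance. Simplices are ordered
  by (value, dimension, lexicographic vertex tuple), which fixes every tie
  deterministically. Columns are bitsets; a numba-compiled kernel is used
  when numba is importable, with a pure-Python fallback (both are tested
  against each other and against a naive full-boundary-matrix oracle).
* Zero-persistence bars (birth = death) are dropped; duplicate points are
  legal and handled by that rule. A loop still open at the threshold is
  reported with death = ∞.
* Default threshold: 2 × (landscape grid maximum) = 80. For bars that die
  by the threshold the landscape on the grid is exact; a bar alive at the
  threshold is excluded from landscapes (below). In the colony data regime
  — all feature scales well below the grid maximum — diagrams at threshold
  2G give landscape matrices identical to much larger thresholds (tested).
  This is a property of the data, not a theorem: a point set with a loop
  born at fine spacing that encloses a very large hole could outlive any
  fixed threshold.

## Persistence landscapes

Each finite bar (b, d) contributes the tent function rising from b, peaking
at (d−b)/2, and returning to 0 at d; λ_k(t) is the k-th largest tent value
at t, and 0 when fewer than k bars overlap t (the standard convention).
The classifier input samples λ_1..λ_K on the grid t = 1, 2, …, 40 — forty
functions for a single homology dimension, twenty per dimension when dims 0
and 1 are combined, with the dim-0 block stacked above the dim-1 block
(an arbitrary but fixed order). Infinite-death bars are excluded: their
tent is undefined and any finite cap would inject an arbitrary constant, so
the essential connected component is never featurized.

A note on input width: a 40 × 40 landscape matrix flattens to 1600 values,
but the canonical three-hidden-layer architecture's stated total of 16,965
parameters corresponds to an 800-dimensional input (e.g. 20 functions × 40
samples, or 2 × 20 × 20). Both layouts are supported through the grid
configuration; the parameter-count check uses the 800-wide input.

## Classifier

Dense feedforward network: input → 20 → 20 → 20 → n_classes, ReLU hidden
activations, softmax output, categorical cross-entropy loss. Implemented in
numpy with full-batch gradients (datasets are tens of colonies). Defaults:

* optimizer Adam, learning rate 1e−3 (unstated upstream; the conventional
  default), β = (0.9, 0.999);
* He-normal weight initialization, zero biases, seeded;
* at most 200 epochs; early stopping after 5 consecutive strict decreases
  in validation accuracy ("several" fixed at 5, configurable); the returned
  model is the checkpoint with the highest validation accuracy (earliest
  epoch on ties);
* train/validation split: randomized, non-stratified, train size
  = ceiling(0.70 × n); stratification available by flag; the cross-time
  experiments use an 80/20 preset;
* no feature scaling — raw landscape values are already on a common scale.

The randomized-label control reassigns each colony an i.i.d. uniform label
(not a permutation), fixed across that colony's frames.

Parameter arithmetic is exposed for three architectures: the landscape
network (16,965 parameters at input 800), a single 5-way dense head on a
frozen 512-feature backbone (2,565), and the standard 18-layer residual
image classifier with that head (11,179,077, counted layer by layer —
convolutions, batch-norm scale/shift pairs, dense head). No image model is
trained.

## Evaluation

* Accuracy = fraction of exact matches; confusion matrices are (true,
  predicted) counts, averageable over repeat models.
* Per-class precision = TP/(TP+FP), recall = TP/(TP+FN),
  F1 = 2pr/(p+r). A class never predicted (or absent) yields 0 with a
  `degenerate` flag rather than NaN, so per-timepoint curves stay defined.
* Cross-time grid Acc_T(S): models trained at T, averaged over repeats,
  evaluated on timepoint-S features. On the diagonal (T = S) only each
  model's held-out validation colonies are scored; off the diagonal the
  model never saw timepoint-S data and all colonies are scored.
* Time differential ⟨T,S⟩ = Acc_T(S) − Acc_{S\*}(S), S\* = S − offset
  (default 10 frames = 50 minutes). It is defined only for T ≠ S: the
  diagonal mixes a validation-only accuracy with a full-dataset accuracy
  and is reported as NaN. Cells with T = S\* are identically 0. Columns
  whose S\* is outside the grid are NaN, never extrapolated.

## Scaled-down experiment conditions

Full-scale persistence (1000+ cells per frame) is too slow for routine
testing, so the packaged experiments run smaller colonies whose
*dimensionless* geometry matches the full-scale defaults: density fixed at
a mean nearest-neighbour spacing ≈ 5.6 units, and rosette holes kept at
≈ 2–3 nearest-neighbour spacings (the ratio the full-scale defaults give),
which is what dimension-1 persistence actually responds to. Two presets:
250 cells on radius 100 (hole fraction 0.18, 3 rosettes) and 180 cells on
radius 85 (hole fraction 0.21, 3 rosettes). These sizes were chosen from
the geometry, once, and the experiments report whatever they produce.

The learning experiment measures accuracy on a held-out **test** subset
disjoint from both the training split and the validation split used for
early stopping and checkpoint selection. Selecting the best-validation
checkpoint inflates the validation accuracy itself (a maximum over ~200
correlated evaluations on a small set); on a 12-colony validation set the
inflation is roughly +0.1–0.15 at chance level, which would swamp the
randomized-label control. Test-subset accuracy is unbiased; the same
estimator is used for the true-label arm for comparability. The
per-timepoint accuracy curves (two-plateau experiment) keep the plain
best-validation-accuracy protocol, since there the comparison is between
timepoints that share the bias.

The time-invariant control (classes fully expressed at every frame) pools
the non-trivial ⟨T,S⟩ cells (T ≠ S and T ≠ S\*) over three independent
datasets; single cells carry training-set sampling noise of order ±0.1 at
25 colonies, so the centering-on-zero check is made on the pooled mean
against its standard error.

## Known limitations

* Homology stops at dimension 1; no cohomology or apparent-pair shortcuts,
  so very dense clouds (≫ 500 points at threshold 80) are slow.
* The dim-0 diagram ignores the threshold; for clouds with disconnected
  clusters farther apart than the threshold, dim-0 deaths can exceed it.
* The synthetic generator's class motifs are stylized; accuracy numbers on
  it are not comparable to accuracies on real imaging data.
* Landscape exactness under the 2G threshold is validated for colony-like
  data, not guaranteed for arbitrary point sets (see above).
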