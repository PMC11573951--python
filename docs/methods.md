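# Methods

This note records the models, parameter choices and numerical decisions
behind `gliotme`, and what its synthetic-data experiments do and do not
establish about real tissue.

## Synthetic TMA cores

Each core is a circular tissue disc (radius 0.47 × image side) on a white
background. Rendering follows Beer–Lambert absorption: per-pixel optical
densities (OD) for a brown DAB-like chromogen and a blue
hematoxylin-like counterstain are accumulated and converted to RGB as
`I = exp(−OD_brown·A_DAB − OD_blue·A_HEM)` with the fixed unit absorbance
vectors A_DAB ∝ (0.27, 0.57, 0.78) and A_HEM ∝ (0.65, 0.70, 0.29)
commonly used for stain separation. This reproduces the two-colour
statistics of single-stain immunohistochemistry without modelling optics,
scanner noise, or focus variation.

**Phenotypes.** A phenotype specifies a cell radius range, a shape
(round, ameboid with a harmonic-wobble boundary, or ramified with thin
processes), the mean ± s.d. of its brown OD and a nuclear counterstain
OD. Cells have near-uniform chromogen density with a soft rim, and are
placed with soft pairwise exclusion (bounded rejection sampling at 0.8 ×
summed radii) so cells approximate a monolayer rather than stacking OD.
The default panel of eight spans weakly stained small round cells through
intensely stained ameboid cells, loosely following how resting versus
activated myeloid cells appear under HLA class II staining.

**Neighborhoods and grades.** Region seeds are drawn from a Poisson
process over the disc (expected count = disc area / cluster_scale², so
cluster_scale sets the spatial correlation length, default 40 px at the
256-px scale), labelled by a multinomial draw from a per-image mixture
sampled from the grade's Dirichlet concentration vector, and grown into
contiguous regions by nearest-seed (Voronoi) partition. Cells are then
scattered per region at the neighborhood's density with phenotypes from
its mixture. The default grade profiles follow the study cohort's
composition (21/24/84/26/51 images for grades 0–4, 206 total) and shift
concentration mass from weak-stain neighborhoods in normal tissue toward
dense, intensely stained neighborhoods (N2, N4, N8) in grade 4, with
deliberately overlapping profiles for grades 2 and 3 — the pair that is
hardest to separate in practice. A `separation` dial interpolates every
grade's concentration vector between the cohort mean (0, grades
indistinguishable — used for null calibration) and the configured
profile (1, default).

Two derived configurations serve testing: `easy_phenotype_config` (three
visually disjoint phenotypes in pure neighborhoods, high density) for
phenotype-recovery checks, and `strong_coupling_config` (default
profiles with concentrations ×3, shrinking within-grade variance) for
pipeline-recovery checks. `sample_abundance_cohort` draws per-image
compositions from the same Dirichlet model without rendering pixels,
making 500-cohort calibration runs cheap.

All randomness flows through one `numpy.random.Generator`; identical
(config, seed) gives bit-identical images and truth maps.

## Supervised grading track

Preprocessing is exactly the deterministic pipeline the benchmark
defines: center-crop of the 19,200 × 1200 acquisition strip to
1200 × 1200 (pure slicing, no resampling), optional RGB→HSV conversion on
[0, 1]-scaled pixels (applied last, at load time), and augmentation of
the minority grades {0, 1, 3, 4} with lossless 90°/180° rotations —
applied only to the training split so validation and test never contain
rotated copies. Fold splitting is stratified 10-fold with nested roles
(1 fold test, 1 fold validation, 8 folds train), so each image is tested
exactly once and per-grade proportions stay within one sample of ideal.

**Parameter accounting.** Trainable-parameter counts for the six
benchmark architectures are computed by explicit layer-by-layer
enumeration of the standard model-zoo definitions (convolutions without
bias followed by batch norm, squeeze-excitation widths per family
convention, classifier heads as in the reference implementations). The
accounting reproduces the reference 1000-class totals exactly
(e.g. ResNet18 11,689,512; EfficientNet-B0 5,288,548) and therefore the
5-class totals and last-layer transfer counts. In the transfer regime
only the final linear layer trains, so its count is (features + 1) × 5.

**Trainable model.** The classifier trained per fold is a compact NumPy
network: a fixed 8 × 8 × 3 pooled-intensity feature grid plus channel
statistics, a 64-unit ReLU hidden layer, and a zero-initialised softmax
head optimised by Adam (lr 10⁻³, batch 16, 10 epochs by default) under
cross-entropy. "Pretrained" freezes the hidden layer at its seeded
initialisation and trains only the head, mirroring last-layer-only
transfer; "scratch" trains everything. Zero-initialising the head makes
the untrained model emit a uniform softmax, so its loss on balanced data
is exactly ln 5. This model is deliberately small — the benchmark's
*contract* (fold-wise metrics, confusion matrices, statistical
comparison) is the deliverable, not ImageNet-scale capacity.

**Statistics.** Model comparison uses the two-sided Mann–Whitney U with
the exact enumerative null when both samples have ≤ 10 values and no
ties (the fold-count regime), otherwise the normal approximation with
tie correction; Shapiro–Wilk p-values are reported per sample, and the
median difference is median(a) − median(b).

## TME discovery track

**Patches.** Cores are tiled on a grid (default 16 px, non-overlapping)
keeping patches whose center lies in the tissue mask; at this scale one
patch approximates one cell footprint.

**Encoder.** The patch encoder is a stain-aware featuriser — optical
densities projected onto the DAB and hematoxylin absorbance directions,
summarised by coverage-robust statistics (stained fraction, median and
75th-percentile OD of stained pixels, dark-pixel ratio, counterstain
stats, gradient texture) — followed by a trainable two-layer projection
(64 hidden units) onto the 256-d unit sphere. Training minimises NT-Xent
(τ = 0.5) with hand-derived gradients through the L2 normalisation:
positives are augmented views (flips, 90° rotations, ±10% brightness) of
the anchor or of patches within 1.5 × patch size; negatives are sampled
beyond 8 × patch size or from other images (16 per anchor). Adam,
lr 10⁻², per-anchor updates; an optional anchor subsample per epoch caps
cost on large cohorts.

**Graph.** Per image, a k-nearest-neighbour graph on patch centers
(k = 8, union-symmetrised) — robust to density variation across the
disc; a fixed-radius rule is available. Edges never cross images.

**Three-level assignment.** Each level learns k prototypes by seeded
k-means and assigns softly by a softmax over negative squared distances
(temperature = median squared distance, making the soft assignment
scale-free); hard labels are the argmax. Phenotypes (P = 8) cluster the
embeddings directly; neighborhoods (N = 8) cluster each patch's mean
phenotype composition over its 1-hop graph neighborhood (isolated
patches fall back to their own composition); areas (A = 7) cluster the
3-hop distribution of neighborhood labels, which separates interleaved
(interacting) from segregated neighborhood layouts. Degenerate inputs
with fewer distinct compositions than k occupy only the leading
prototypes. A deterministic k-means path is used throughout; the
prototype layers could be refined end-to-end, but at desk scale the
deterministic path is reproducible and sufficient for every contract.

**Patient classification.** Per-image abundance is the hard-label
fraction per level block (each block sums to 1; P + N + A = 23
features). A multinomial logistic model (scikit-learn, lbfgs, C = 100)
trained with cross-entropy on image-level grades provides both the
classifier and its interpretation surface (per-element weights). Binary
grade evaluation fits a per-pair logistic model under stratified
cross-validation and reports accuracy, sensitivity and specificity at
the 0.5 threshold (higher grade = positive class) and AUC-ROC with
midrank tie handling.

## Differential analysis

Per element and grade pair, a two-sided Mann–Whitney rank-sum test on
per-image relative abundance (consistent with the model-comparison
track); elements constant across both groups are skipped with a warning.
Star levels use strict thresholds (\* p<0.05, \*\* p<0.01, \*\*\*
p<0.001). P-values are reported raw — star levels are nominal and not
adjusted for multiple comparisons — and the choice is recorded here and
in output metadata. The shared-cluster graph weighs each significant
element by its star multiplier (×1/×2/×3) and sums per grade pair.
Predictive influence replaces one element by its cohort mean,
renormalises the element's block, and reports the ratio of the
predicted-class probability before versus after; a block whose sum
degenerates to zero yields NaN. Heatmap ordering is average-linkage
hierarchical clustering on Euclidean distances, deterministic given the
input order (leaf order within subtrees is linkage-tie dependent, so
permutation invariance holds at the level of the dendrogram, not the
leaf sequence).

## What the synthetic experiments show — and what they do not

Passing tests establish that the implementation recovers planted
structure under its own generative assumptions: distinct phenotypes are
recovered from pixels (ARI ≥ 0.8 on the benign three-phenotype cohort),
differential analysis is calibrated (planted effect detected at \*\*\*,
null false-positive rate ≈ 5% over 500 simulated cohorts), and
grade-coupled composition yields the expected binary-AUC ordering
(extreme pairs ≈ 1.0, grades 2 vs 3 near chance). They do not establish
performance on real tissue: the generator omits nuclear texture,
staining batch effects, tissue folds, scanner noise and the continuum of
real cell morphologies, and the study's image data are not publicly
available, so its absolute accuracies and AUCs are not reproduction
targets.

## Problem sizes and numerical notes

Test and acceptance runs use desk-scale conditions chosen once: 128–256
px cores (the 1200-px study scale is available via config and covered by
a geometry test), 15–80 image cohorts, 1–4 encoder epochs with at most
1500 anchors per epoch on the larger cohorts. Tolerances: unit-norm and
sum-to-1 invariants at 1e-9 (1e-6 for float32-sensitive embedding
paths); oracle comparisons (NT-Xent, exact Mann–Whitney) at 1e-9.
Ties in AUC use midranks; k-means uses 10 restarts with a fixed seed;
the soft-assignment temperature falls back to 1 when all distances are
zero. The fold-splitting fallback for classes with fewer than k samples
is scikit-learn's stratified behaviour (it raises; configs keep class
counts ≥ k). Known limitations: the patch featuriser is tuned to
two-stain brightfield appearance and would need replacement for
multiplexed imaging; neighborhood naming is positional (N1…N8), so
labels are only meaningful relative to a fixed seed.
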