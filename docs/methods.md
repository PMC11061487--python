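# Methods

## Setting

The pipeline targets small case-control neuroimaging cohorts (tens of
subjects) in which each subject contributes two kinds of regional
measurements over the 78 cortical regions of the AAL atlas: vertex-wise
cortical thickness from T1-weighted MRI and voxel-wise cerebral blood flow
(CBF, mL/100 g/min) from arterial spin labeling. Image preprocessing
(registration, segmentation, surface reconstruction, CBF quantification) is
out of scope: the pipeline starts from per-region sample tables, with an
optional ROI extractor (`extract_roi_samples`) that pulls voxel values out of
already-registered NIfTI volumes.

## Per-subject networks

**Gray-matter similarity.** Each region is reduced to its mean thickness
u (mm) and across-vertex SD ∂ (n−1 denominator). The edge weight between
regions a and b is the Gaussian kernel
exp(−(u_a − u_b)²/(2(∂_a² + ∂_b²))) ∈ (0, 1]. Properties relied on by the
tests: symmetry, unit diagonal, invariance to a common thickness offset.
Degenerate edges (both SDs zero) take the limit value — 1 for equal means,
0 otherwise — with a warning rather than an error.

**CBF correlation.** A single scalar per region cannot support a per-subject
correlation network, so each region is represented by a Q-vector of empirical
quantiles of its voxel CBF distribution (default Q = 50, levels (i + 0.5)/Q,
linear interpolation between order statistics — mid-levels avoid min/max
outlier sensitivity). The edge weight is the Pearson correlation of two
regions' descriptors; constant descriptors get zeroed edges with a warning.

A consequence worth stating plainly: Pearson correlation is exactly invariant
to positive affine transforms of either vector, and a quantile descriptor
responds to location/scale changes of the underlying distribution only
affinely. The ASL network therefore compares distribution *shapes*; a pure
mean (or SD) shift of a region's CBF leaves every ASL edge unchanged. Under
the simulator below — whose group effects are mean shifts — the ASL modality
carries no group signal, and group separability is driven by the T1 kernel.
This is an honest property of the construction, verified by a dedicated test,
and it bounds what the synthetic experiments can show about real ASL data
(where group differences may well be distributional, not just mean shifts).

**Vectorisation and fusion.** Strict upper triangles in row-major (a < b)
order give 3003 edges per modality. Columns are z-scored with statistics
fitted on training folds only (leakage avoidance; a canary test plants an
outlier in a held-out subject and asserts training-fold statistics are
unchanged), then weighted w·T1 and (1−w)·ASL and concatenated. The default
w = 0.5 reflects the equal-weight optimum of the fusion-weight sweep in the
motivating study; the sweep itself (`weight_sweep`, w = 0.1…0.9) is part of
the API.

## Feature selection

Per training fold: pooled two-sample t-test per edge, keep p < 0.05
(uncorrected — the protocol is a screening filter, not inference); survivors
ranked by greedy mRMR with the MID (difference) criterion on equal-frequency
tertiles, mutual information in nats, ties to the lower column index;
top k = 20 retained by default. Tertiles are a robust discretisation for the
~40-subject training folds this pipeline sees; k, bins and α are
configurable. If nothing survives the filter, the 10 smallest-p edges are
kept and the result is flagged.

## Classifier

RVFL: random hidden weights/biases i.i.d. Uniform(−1, 1) from a per-fold seed,
sigmoid activation, design [X | H | 1], ridge solution
β = (DᵀD + λI)⁻¹Dᵀy with λ = 0.1 and ±1 label coding, so the continuous
score Dβ doubles as the ROC input, with sign(score) as the label (0 → +1).
λ = 0 falls back to the minimum-norm least-squares solution. The bias column
is penalised along with everything else (λ is small; simplicity wins).
Defaults (100 hidden nodes, sigmoid, unit init scale) are conventional RVFL
settings — the motivating study reports none. ELM is the same machine without
the direct-link block; the SVM baseline delegates to scikit-learn's SVC
(C = 1, RBF, γ = 1/d) as a fixed, untuned reference point.

## Evaluation

Stratified k-fold (per-class shuffled round-robin; per-fold class counts
differ by ≤ 1), k = 5, repeated 20 times; repeat r uses base_seed + r, and
each fold's model seed derives from (base_seed, repeat, fold) via a seed
sequence. Metrics (ACC, SEN, SPC, precision, F1 with ASD positive; AUC as the
Mann-Whitney probability with ties counting ½) are computed per repeat from
that repeat's pooled out-of-fold predictions and reported as mean ± SD over
repeats — the aggregation convention is this package's own, since single
numbers without an aggregation rule are not reproducible. Zero-denominator
metrics report 0 with a warning. DeLong's paired AUC test uses midrank
placement values; by default it is applied to one repeat's pooled
out-of-fold scores (repeat 0), since averaging scores over repeats before a
variance-based test has no clean sampling theory.

## Discriminative edges

Within each of one repeat's k training folds, the 20 smallest-p edges are
tallied; edges are ordered by cross-fold count (desc), then by their minimum
p across the folds where they appeared (asc; a mean-p variant would also be
defensible but minimum-p matches "smallest p for the same count"), then by
edge identity, and the top 9 are reported with AAL-78 names and lobes. The
p-values are the training-fold filter p-values computed on the z-scored,
pre-weighting features (selection statistics should not depend on the fusion
scalar). The sex-stratified analysis re-runs the group t-test per reported
edge on all/male/female subjects, flags p < 0.01, and marks strata with
fewer than two subjects per group as missing.

## Synthetic cohorts

The simulator emulates the study conditions: 30 ASD vs 22 TD subjects,
78 regions, 200 vertices and 150 voxels per region. Region-level population
parameters are drawn once per cohort (thickness mean Uniform(2.0, 3.5) mm and
SD Uniform(0.2, 0.5) mm — the plausible cortical range; CBF mean
Normal(50, 8), SD Uniform(5, 10) mL/100 g/min — typical pediatric gray-matter
perfusion); each subject adds a global offset (Normal(0, 0.1) mm thickness,
Normal(0, 3) CBF) and i.i.d. within-region sampling noise. Group effects are
mean shifts added in designated regions for ASD subjects only. Sex follows
the study marginals (24/30 vs 14/22 male) and age the study summaries
(4.71 ± 1.41 vs 5.49 ± 1.68 years), truncated to (2, 9) by resampling.
Subjects own RNG substreams keyed by (group, within-group index), so cohorts
are byte-reproducible and enlarging one group never perturbs the other.

What the simulator does *not* model: registration error, motion, scanner
effects, spatial correlation between neighbouring regions, non-Gaussian CBF
distributions, and any dependence of features on age or sex. Passing recovery
tests therefore demonstrate that the pipeline's statistics behave as designed
under their own assumptions — not that comparable accuracy is attainable on
real cohorts.

## Numerical choices and problem sizes

- Symmetry tolerance for vectorisation: 1e−10; correlation matrices are
  symmetrised against floating-point noise and clipped to [−1, 1].
- The Gaussian kernel can underflow to exactly 0 for pathological inputs
  (exponent > ~700); the (0, 1] bound holds wherever double precision can
  represent it.
- mRMR near-ties: distinct columns can share a contingency table, making the
  argmax order-dependent at the 1e−16 level; results are deterministic for a
  given platform, and the oracle tests check greedy-optimality of each pick
  rather than a unique order.
- Null edge-wise calibration is assessed on the rate averaged over five
  cohorts: edges sharing a region are correlated, so a single cohort's rate
  fluctuates beyond the binomial band for 6006 independent tests.
- The weight-sweep trend is demonstrated at a small effect (0.05 mm in two
  regions) chosen to keep the AUC off its ceiling — at saturation every
  weight wins and the trend is undefined. Selection statistics are
  scale-invariant, so the fusion weight influences the result only through
  the classifier's scale sensitivity; the trend is real but modest.
- Desk-scale sizes used by the test suite and acceptance script: 5 cohorts ×
  20 CV repeats for separability, 10 cohorts for selection recovery, 5
  cohorts × 3 repeats × 9 weights for the sweep, 2000 simulations for the
  DeLong null, 200 × 5 features for the filter null.

## Known limitations

- The ASL construction is one of several defensible readings of building a
  per-subject correlation network from scalar regional CBF; alternatives
  (e.g. across-subject group networks, eigen-features) would change the
  feature semantics entirely.
- No multiple-testing correction in the filter (by protocol design).
- The demographic chi-square reports the standard Pearson statistic; for the
  study's printed sex table (24/6 vs 14/8) this gives p ≈ 0.19, and no
  standard 2×2 test reproduces the much smaller value printed there.
- RVFL hyperparameters are conventions, not tuned values; on real data a
  nested search would be warranted (and is deliberately out of scope).
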