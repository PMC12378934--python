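# Methods

## The model

Two single-cell omics modalities — for instance gene expression (scRNA-seq)
and chromatin accessibility (scATAC-seq), or RNA and surface-protein ADT
counts — measure different feature spaces on the same biology.  The package
learns one shared d-dimensional latent space for both.  Each modality gets
its own encoder `f`/`g`: a multilayer perceptron
`Linear(p -> 256) -> BatchNorm -> ReLU -> Linear(256 -> 128)` followed by
row-wise L2 normalization, so every cell lands on the unit sphere and inner
products are cosine similarities.  The nonlinearity sits between the two
linear maps: a ReLU after the final layer would confine embeddings to the
nonnegative orthant and destroy most of the cosine range.

Training is contrastive.  A mini-batch holds exactly one cell per cell type
in each modality (M cells for M types), and the M×M matrix of cross-modal
inner products S has positives on its diagonal and different-type negatives
off it.  For anchor i the loss is the symmetric softmax cross-entropy

    L(i) = -1/2 ln[ exp(s_ii) / Σ_j exp(s_ij) ]
           -1/2 ln[ exp(s_ii) / Σ_j exp(s_ji) ]

summed over the M anchors of the batch.  There is no temperature in this
formulation (an optional one is exposed, default 1, i.e. off).  In the paired
regime the same cells index both sides of the batch, so the diagonal pairs
the two measurements of one physical cell; in the unpaired regime one cell
per type is drawn independently from each modality, so the diagonal pairs
same-type cells.  Same-type different-cell pairs are never used as
negatives — the one-cell-per-type batch construction guarantees every
off-diagonal entry crosses types.

Key consequences, each verified by tests: the loss is nonnegative, zero at
M = 1, invariant under modality swap (transpose of S) and simultaneous
row/column permutation, strictly decreasing in diagonal similarities and
increasing in off-diagonal ones.

## Batch construction and the epoch

Per epoch, each type's training cells are shuffled and consumed without
replacement; the number of batches equals the largest type count, and
smaller types are topped up by sampling with replacement so every batch keeps
the one-cell-per-type structure and every training cell appears at least
once per epoch.  Types present in only one modality of an unpaired dataset
are excluded with a logged warning.  If the number of types exceeds
`max_batch_types` (default 512) types are subsampled per batch.

## Optimization and early stopping

Both encoders are trained jointly by Adam (learning rate 1e-3 by default; the
original training schedule does not pin an optimizer, and adaptive moments
are the standard choice for contrastive objectives).  The schedule is up to
150 epochs with early stopping on the epoch-mean training loss: stop when the
best loss fails to improve by more than `min_delta` = 1e-4 for `patience` =
10 consecutive epochs.  No validation split is used for stopping — the
monitored quantity is the training loss itself.  The forward, backward and
optimizer steps are explicit NumPy; the backward pass is checked against
finite differences in the test suite, and batch-norm uses batch statistics
during training but running averages (momentum 0.1) at evaluation, so
held-out cells are embedded deterministically and independently of one
another.

## Preprocessing and the leakage-free protocol

The chain per modality is: total-count normalization to `target_sum` (1e4) →
log1p → per-feature standardization (population variance; zero-variance
features are centered with a unit divisor) → PCA (default 100 components,
clipped to the rank bound; signs fixed so each axis's largest-magnitude
loading is positive).  Inputs that arrive already normalized can skip the
count steps via `PreprocessConfig`.  Every statistic is fitted on training
cells only; each fitted transform records `fitted_on`, and the protocol
asserts it equals the training size.  The evaluation protocol is 10
train/test splits (hold-out fraction 0.3 — the replicate count is the fixed
part of the protocol, the fraction a configurable convention), with replicate
r seeded as `base_seed + r` so splits are reproducible and independent.

## Unpaired simulation

From a paired dataset, a uniformly random subset of `round(proportion · N)`
cells keeps only the second modality and the complement keeps only the
first, giving disjoint cell sets that share a type vocabulary.  The sweep
proportions follow the published grid (1–50%).  Sampling is uniform over
cells by default; a stratified flag guarantees every type survives at very
small proportions.  The simulation applies to the training portion only —
the hold-out stays paired so Recall@k and median rank remain computable.
The random baseline permutes cell-type labels uniformly, preserving marginal
type counts.

## Metrics

All metrics use Euclidean distance.  KNN ties break by reference index
order; in median rank the matched pair wins ties (optimistic rule).  The
median-rank normalization is raw/N, so perfect alignment scores 1/N ≈ 0.
ASW uses cell-type labels as clusters on the joint embedding — column-wise
concatenation (N × 2d) for matched cells, row-wise stacking for unmatched —
and is mapped to [0, 1] via (ASW + 1)/2; singleton clusters contribute
silhouette 0.  Both query directions (modality 1 → 2 and 2 → 1) are computed
and reported.  The silhouette itself is delegated to scikit-learn; the test
suite checks it against an independent from-scratch implementation, and
every retrieval metric against exhaustive full-distance-matrix oracles.

## The synthetic generator

The generator emulates exactly the structure the method assumes: a shared
per-cell latent state drives both modalities.  Each cell draws a type
(default 5 types, uniform proportions) and a latent vector from that type's
unit-variance Gaussian; type centroids sit at pairwise distance `separation`
(default 6, i.e. six within-type standard deviations — cleanly separable).
Two fixed random linear maps project the latent state into p and q features
(default 200 each) with independent Gaussian noise (sd 1), emulating distinct
feature spaces and modality-specific distortion.  A negative-binomial option
(softplus mean, dispersion 2) emits integer counts so the full count chain is
exercised; the Gaussian option produces continuous values used with the
scale+PCA chain only.  What the generator does *not* emulate: scATAC peak
sparsity patterns, batch effects, doublets, or continuous differentiation
trajectories — passing tests demonstrate correctness of the machinery and
recoverability of discrete type structure, not performance on real tissue.

## Problem sizes used in the shipped checks

End-to-end parameter recovery runs at 2000 cells (5 types, 200 features per
modality, separation 6, 30% hold-out) — large enough that hold-out metrics
are stable, small enough for a single CPU.  The unpaired-proportion sweep
uses 1000 cells with 3 seeds per proportion in the test suite and 1 seed in
the acceptance script.  Chance levels use 500-cell embedding sets.

## Known limitations

Two modalities only; discrete cell types only (the type-structured batches
have no notion of a continuum); cell-type labels are required inputs — a
missing label column is a hard error, not imputed.  Training is CPU-bound
NumPy: fine at desk scale (thousands of cells), not tuned for atlas-scale
data.  Early stopping on training loss can overtrain slightly relative to a
validation-based rule; the contract favors faithfulness to the published
schedule over generalization tweaks.
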