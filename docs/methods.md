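# Methods

## Model and assumptions

The pipeline treats a cytometry cohort as S samples of exchangeable cells,
each cell a point in the m-dimensional space of transformed marker
expression (phenotypic lineage markers plus functional/signaling readouts).
Cell populations are regions of that space shared across samples; a clinical
contrast manifests as between-class differences in the *proportion* of each
sample's cells falling in a population. Because populations are defined on
functional as well as phenotypic channels, a signaling shift inside a
lineage also appears as a frequency shift of a functionally defined
subpopulation, so frequency features alone carry both kinds of information.

Population discovery is deliberately redundant. Each sample is over-
clustered (k-means, k-means++ init, 10 restarts, tolerance 1e-4) into up to
k_i clusters; cluster centers are empirical member means, recomputed after
fitting so the center-equals-mean invariant holds exactly. Empty clusters
are dropped — k_i is an upper bound, and k_i is capped at a sample's cell
count. The pooled K = Σ k_i centers are metaclustered into K′ groups, and
this stochastic stage is repeated I times with independent derived seeds.
The per-sample stage is computed once and shared across the I repetitions:
stochastic diversity enters at the metaclustering stage, where it is cheap,
while a flag (`recluster_samples`) re-randomizes both stages for users who
want full re-runs. Metaclustering treats pooled centers as unweighted
points; member counts are kept as provenance but do not weight the fit.

Any clusterer with the `(matrix, k, seed) -> labels` signature can replace
k-means in either stage; the pipeline's invariants (assignment totality,
per-block frequency normalization, determinism given seeds) do not depend
on the clusterer.

## Feature engineering

F is S × P with P = Σ_m K′_m; entry F_ij is the fraction of sample i's
cells mapped (via its within-sample cluster) to metacluster j. Within each
solution's block the row entries sum to 1 by construction. Functional
features X* = [X¹|…|X^f] hold per-(metacluster, marker) mean expression;
a (sample, metacluster) pair receiving no cells is recorded as missing and
imputed with the metacluster's cross-sample mean only when exported to a
classifier, to avoid inventing a zero signaling level. F is the default
classification input; X* is opt-in.

## Feature selection

Each solution's block is scored independently with the Laplacian score:
build a k-nearest-neighbor graph over samples (union of directed
neighborhoods), heat-kernel weights exp(−d²/bandwidth) with bandwidth
defaulting to the squared median pairwise distance of the block
(scale-free; a binary 0/1 kernel is available), then score each feature f
as (f̃ᵀLf̃)/(f̃ᵀDf̃) with D the degree matrix, L = D − W, and f̃ the
degree-weighted centering of f. Features constant across samples score +∞.
The top_m lowest-scoring features per block are retained, ties broken by
ascending column index. Defaults k_nn = 5, top_m = 40 with K′ = 50. Labels
are not an input, so selection cannot bias downstream cross-validation.

## Cross-validation

The resampling unit is the patient: each of B iterations sends
floor(train_fraction · n_patients) random patients (and all their samples)
to training, fits the classifier (Random Forest, 100 trees, √d features per
split, seeded), and stores held-out class-1 probabilities. Iterations whose
training half lacks a class are skipped and counted, not resampled. A
sample's y* is the median over its test appearances; samples never tested
are excluded from the AUROC with a warning. AUROC is computed from midranks
(exact tie handling) and equals the pairwise concordance
P(score⁺ > score⁻) + ½P(tie).

Class-stratified patient sampling is off by default, matching the simple
random halves of the original procedure. The desk-scale experiment designs
in `cytopool.experiments` *do* stratify: with only 20–40 samples, the
training half's class composition anti-correlates with the test half's, so
under the null the held-out class-1 probabilities are depressed exactly
when the test half is class-1-heavy, biasing null AUROC well below 0.5
(≈0.42 on average, excursions to ≈0.21 across seeds, measured on the null
fixture). Stratification removes this artifact; at hundreds of samples it
is negligible and the default applies.

## Differentiation scores

Metacluster significance w_j is the two-sided Wilcoxon rank-sum p-value of
the frequency feature between the two groups, computed on a user-specified
comparison subset of samples when the visualized contrast differs from the
classification task (e.g. a single timepoint). The exact null distribution
is used when both groups have ≤ 25 observations and the data are tie-free;
otherwise the tie-corrected normal approximation. These p-values order
populations for visualization only: no multiple-testing correction is
applied and no inferential claim is attached — the direction of change is
reported as the sign of the median frequency difference.

For display, up to 30,000 cells are uniformly subsampled across samples
(an optional per-cell exclusion predicate removes dominant populations such
as granulocytes from the *visualization only*; modeling always uses every
cell) and embedded in 2-D (t-SNE default; PCA and UMAP built in, any
`(matrix, seed) -> n×2` callable accepted). Each cell's score per solution
is the similarity-weighted average of that solution's w_j with
s_ji = exp(−α‖c_j − x_i‖₂); the final score averages over solutions and is
therefore bounded by the w range of each solution. Cells and centers are
z-scored per channel (statistics of the subsample) before distances, so
α = 1 has a scale-free meaning; if all similarities underflow for a cell,
the nearest center's w is used. Maps are rendered colored by −log₁₀(score).

## Synthetic cohorts

The generator emulates the statistical skeleton of a case-control CyTOF
study, in transformed (post-arcsinh) space: populations are diagonal
Gaussians; per-sample population proportions are Dirichlet with
concentration κ around the class target vector; cell counts are multinomial;
a class effect multiplies one population's base frequency in class 1 with
renormalization. The default fixture has 10 channels (6 lineage, 4
signaling), five leukocyte-like populations at base frequencies
0.30/0.25/0.20/0.15/0.10 with sd 0.4 per channel, the 0.20 population
(monocyte-like) expanded 1.5-fold in class 1, 10 patients per class with one
sample each, and 2,000 cells per sample.

κ = 500 (between-sample frequency CV ≈ 9% for a 0.20 population) models a
tightly batch-controlled, barcoded acquisition. At this noise level a
1.5-fold expansion is a strong effect at ten patients per class, which is
what a recovery fixture must provide; with substantially noisier cohorts
(κ ≈ 100, CV ≈ 20%) the same fold-change is statistically marginal at this
sample size, a regime better probed by the null fixture and by scaling
patient counts, not by weakening the planted truth. The null fixture (20
patients/class, 1,000 cells/sample, no effects, labels assigned
independently) checks calibration rather than power.

What the generator does **not** model: batch effects, acquisition drift,
doublets, spillover, non-Gaussian population shapes, patient-level random
effects beyond the Dirichlet, or correlated multi-sample patients. Passing
tests therefore demonstrate the pipeline's statistical machinery — not
robustness to instrument artifacts, which the upstream normalization and
gating steps are assumed to have handled.

## Numerical and design choices

- **Expression transform:** arcsinh(x/5) per channel by default (the mass
  cytometry community standard), overridable per channel, applied
  identically to phenotypic and functional markers; synthetic data is
  generated on the transformed scale and marked `transform: none`.
- **Seeds:** one master seed; every stochastic stage derives a child seed
  from the master plus an integer stream path (SeedSequence-hashed), so
  results are independent of execution order and safely parallelizable.
- **Desk-scale experiment sizes:** K′ = 10, I = 10, 50 within-sample
  clusters, B = 30–50 CV iterations, 20 paired trials — chosen so each
  experiment design completes in seconds-to-minutes on one core while
  exercising every stage; the library defaults (K′ = 50, I = 50, B = 500)
  reflect full-scale studies.
- **Degenerate inputs:** constant features score +∞ in selection (never
  retained ahead of informative ones); an all-identical feature block falls
  back to bandwidth 1; equal scores break ties by column index; k above a
  sample's cell count is capped; constant differentiation scores still
  render with a valid colorbar.
- **Half splits with odd patient counts** floor to training (7 → 3 train /
  4 test).

## Known limitations

- k-means is a local optimizer; the exhaustive-partition oracle is matched
  on small instances only when restarts are allowed to find the optimum.
- The rank-sum exact path requires tie-free data; heavily tied frequency
  features (many exact zeros) silently use the asymptotic approximation.
- Feature selection filters within solutions; it does not deduplicate
  *across* solutions, where redundancy is by design.
- t-SNE coordinates are seed-reproducible but not stable under subsample
  changes; treat map geometry qualitatively.
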