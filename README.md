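# cytopool

Repeated-metaclustering analysis of multi-sample mass cytometry (CyTOF)
cohorts: robust cluster-frequency features, unsupervised feature selection,
patient-level ensemble cross-validation, and per-cell visualization of the
cellular correlates of a clinical outcome.

## Who this is for

Translational immunology groups with a cohort of per-sample single-cell
protein-expression matrices (pre-gated live cells, FCS or CSV) and a binary
clinical contrast — treatment vs placebo, timepoint A vs B, case vs control —
who want (a) a sample-level classifier built from interpretable
cell-population abundance features and (b) a single-cell map showing *which*
populations drive the separation.

## The method

Stochastic clustering algorithms return a different cell-to-population
partition on every run. Instead of committing to one partition, the pipeline
embraces the variability and pools many:

1. **Per-sample clustering.** Cells of each of the *S* samples are coarsely
   over-clustered (k-means, default k_i = 1000) on all phenotypic +
   functional channels — no downsampling, every cell contributes. This
   yields K = Σᵢ kᵢ cluster centers.
2. **Repeated metaclustering.** The K pooled centers are re-clustered into
   K′ metaclusters (default 50). Because this stage is stochastic, it is
   repeated I times (default 50) with independent seeds, giving
   P = I · K′ overlapping candidate populations.
3. **Frequency features.** F ∈ ℝ^(S×P) with F_ij the proportion of sample
   i's cells assigned to metacluster j. Since clustering used functional
   channels too, frequencies carry signaling information; per-metacluster
   functional means (X\* = [X¹|…|X^f]) are available but opt-in.
4. **Unsupervised feature selection.** Within each solution's K′-column
   block, features are ranked by the Laplacian score on a k-nearest-neighbor
   sample-similarity graph (lower = better locality preservation) and the
   top m (default 40) are retained. Labels are never consulted, so no
   selection bias enters cross-validation.
5. **Classification.** B (default 500) bootstrapped leave-group-out
   iterations: a random half of *patients* (all their samples together — no
   leakage) trains a Random Forest; held-out samples receive class-1
   probabilities. A sample's final score y\*ᵢ is the median over its test
   appearances; AUROC(y, y\*) is the figure of merit.
6. **Differentiation map.** Each metacluster j gets a two-sided Wilcoxon
   rank-sum p-value w_j comparing its frequency between the two groups
   (optionally on a comparison subset of samples). Each cell i gets, per
   solution, p_i^m = Σ_j s_ji w_j / Σ_j s_ji with
   s_ji = exp(−α‖c_j − x_i‖₂), averaged over the I solutions, and is drawn
   on a 2-D embedding (t-SNE by default; pluggable) colored by −log₁₀ of
   its score. Low scores flag outcome-associated populations.

Pooling solutions raises classification accuracy and shrinks its variance
relative to any single metaclustering solution; the package ships desk-scale
experiments demonstrating both properties on synthetic cohorts with planted
effects.

## Worked example

```python
import cytopool as cp

# synthetic cohort: 10 patients/class, 2000 cells/sample, 5 immune-like
# populations, monocytes expanded 1.5-fold in class 1
cohort, truth = cp.signal_cohort(seed=7)
print(f"cohort: {cohort.n_samples} samples, {cohort.total_cells} cells")

meta = cp.repeated_metacluster(
    cohort.cells, k_per_sample=50, k_prime=10, n_solutions=10, master_seed=7
)
F = cp.frequency_features(meta, sample_ids=cohort.manifest.sample_ids)
print(f"F: {F.n_samples} x {F.n_features} (P = {meta.total_metaclusters})")

sel = cp.select_features(F, top_m=8)
print(f"retained {sel.retained_columns.size} features")

cv = cp.run_cv(
    F.values[:, sel.retained_columns],
    cohort.manifest.labels,
    cohort.manifest.patient_ids,
    cp.CVConfig(n_iterations=100, seed=7),
)
print(f"AUROC = {cv.auroc:.3f}")

sig = cp.cluster_significance(F, cohort.manifest.labels)
best = min(sig.p_values, key=sig.p_values.get)
print(f"most significant metacluster: iteration {best[0]}, "
      f"metacluster {best[1]}, p = {sig.p_values[best]:.2e}")
```

prints

```
cohort: 20 samples, 40000 cells
F: 20 x 100 (P = 100)
retained 80 features
AUROC = 0.975
most significant metacluster: iteration 6, metacluster 8, p = 2.06e-04
```

The 20 samples yield 100 overlapping metacluster-frequency features
(10 solutions × K′ = 10); cross-validated AUROC 0.975 reflects the planted
abundance shift, and the minimum rank-sum p-value points at the metacluster
containing the expanded population. Continuing with
`cp.build_differentiation_map(...)` and `cp.render_map(...)` writes the
score-colored embedding and its per-cell CSV.

## Command line

```bash
cytopool simulate --out-dir demo/cohort --seed 1          # synthetic cohort
cytopool run --config config.yaml                         # everything
cytopool cluster|featurize|select|classify|viz --config config.yaml   # staged
```

A YAML config names the manifest (CSV: sample_id, patient_id, class, path),
the marker panel (YAML: channel name / role / transform / cofactor), and the
pipeline parameters; every stage writes plain CSV/JSON artifacts plus a
provenance record (config hash, master seed, version), and a re-run with the
same config reproduces them byte for byte.

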