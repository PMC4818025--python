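# Methods

## Model

The pipeline assumes that clinically meaningful patient subgroups are
driven by a subset of molecular features, and that this subset is
enriched for *important regulators* — miRNAs and TFs that sit upstream
of many targets in the miRNA–TF–mRNA regulatory network — and for
features with high expression variation across the cohort. Both
signals are converted into a single per-feature weight and injected
into the patient-distance computation of similarity network fusion.

### Regulatory rank

The rank recursion R(fᵢ) = (1 − d)/N + d·Σ_{fⱼ∈T(fᵢ)} R(fⱼ)/L(fⱼ) is a
PageRank run along *outgoing* edges: a feature inherits importance
from its targets, each target's contribution diluted by its number of
regulators L(fⱼ). The recursion is implemented literally:

- **No dangling-mass redistribution.** Mass flowing into features with
  L = 0 (never targeted) is lost, so Σ R ≤ 1, with equality exactly
  when every node has at least one regulator. Canonical PageRank
  redistributes this mass; we keep the printed recursion and document
  the consequence. Relative orderings — all the method uses — are
  unaffected on the graphs we generate.
- **Self-loops are dropped** during network construction (and
  counted): a node appearing in both its own T and L makes the
  recursion's bookkeeping ambiguous, and autoregulation at this
  granularity does not change relative ranks materially.
- **Isolated features** keep the teleport floor (1 − d)/N, so every
  expression feature receives a weight even when absent from all edge
  lists.
- Synchronous (Jacobi) iteration from the uniform vector, L1 tolerance
  1e-9, max 1000 iterations. Since the update operator has spectral
  radius ≤ d < 1 the iteration is a contraction and the converged
  flag is essentially always set; a direct sparse linear solve is
  shipped as an independent oracle (guarded to N ≤ 5000).
- The damping factor default is d = 0.85, the classic choice; it is a
  free parameter of the method and exposed everywhere.

### Weights

MAD uses no consistency constant (no 1.4826 factor) and even-length
medians are midpoints of the central order statistics. RN and MADN are
normalized **jointly over all N features** by default — the literal
reading of the normalization sums — even though gene and miRNA
expression live on different scales; `WeightingParams(per_view=True)`
normalizes within each view instead, for users worried about scale
mixing. With joint normalization the per-view weight sub-vectors are
used as-is in the distances (not renormalized within view).

β defaults to 0.8, weighting the network signal 4:1 over expression
variation. The GeneRank/NCIS alternative — replacing the teleport term
with MAD inside the recursion — is shipped as `generank_weights`
purely as a diagnostic: on networks where MAD is independent of
degree, its output correlates with the rank-only weights far more
strongly than the convex combination does, which is the motivation for
the linear model.

### Fusion and clustering

Weighted distances are computed after z-scoring each feature across
samples (population SD; zero-variance features are left centered).
The affinity kernel is exp(−d²/(μ·ε)) with ε the mean of the two
samples' K-nearest-neighbor mean distances and their distance
(ε floored at 1e-20 to guard duplicate points). Defaults K = 20,
μ = 0.5, T = 20 diffusion iterations — the customary ranges for the
fused-network method, which does not pin them; all are configurable.
The diffusion updates every view synchronously
(P⁽ᵛ⁾ ← S⁽ᵛ⁾·mean_{k≠v}P⁽ᵏ⁾·S⁽ᵛ⁾ᵀ, then re-normalized to diagonal 1/2 /
off-diagonal row sums 1/2), and the fused matrix is the symmetrized
mean of the final P's. A single view bypasses diffusion.

Cluster number defaults to the largest eigengap of the normalized
graph Laplacian over k ∈ [2, 8] (ties broken toward smaller k;
connected-component count reported alongside for degenerate graphs);
explicit k overrides it. Spectral clustering row-normalizes the bottom-k
Laplacian eigenvectors and runs k-means with 50 seeded restarts, so
labels are deterministic given the seed. On a perfectly uniform
similarity the eigengap ranking is arbitrary but still returned.

### Evaluation

Silhouette dissimilarity is 1 − min-max-scaled similarity (scaled over
off-diagonal entries); the transform is a convention, not pinned by
the method, and silhouette values are invariant to positive affine
rescalings of the similarity. Singleton clusters get width 0. Core
samples are those with width ≥ 0 ("negative" read strictly). The
log-rank test uses the standard k-group O/E/V chi-square with the
aggregated hypergeometric treatment of tied event times; records
censored at an event time count as at risk at that time.

## Preprocessing

Two paths mirror common practice for the two data technologies:
RNA-seq counts are log2(x + 1)-transformed (pseudocount 1, count data
being otherwise zero-inflated at log scale), then the lowest-mean
quantile of features is dropped (25% for genes, 60% for miRNAs in the
reference configuration), then features with SD < 0.5 are dropped;
microarray data are KNN-imputed (k = 10 nearest *features* by
Euclidean distance on co-observed samples, the classic microarray
imputer's semantics) and SD-filtered (0.6 genes / 0.2 miRNAs). The
quantile is computed after the log transform, following the stated
processing order. SD uses the n − 1 denominator and features exactly
at the threshold are kept. Each matrix records the steps applied, in
order, since the filters do not commute.

## Synthetic test bed

The generators produce what the method assumes rather than what TCGA
marginals look like:

- **Network**: class-consistent edges only (miRNA→{mRNA,TF},
  TF→{miRNA,mRNA,TF}, mRNA→mRNA), with regulators drawn
  Zipf-like (propensity rank^(−hub_exponent), default exponent 1) so a
  minority of features become hubs.
- **Expression**: Gaussian log-scale values, N(0, noise_sd), with a
  +effect_size·noise_sd mean shift on each subtype's disjoint signal
  set. Default study conditions: 150 samples, 3 balanced subtypes,
  300 mRNA + 60 TF + 40 miRNA, effect size 2, signal placed on the
  top-out-degree regulators and their targets ("network-central").
  The signal-set size, 40 features per subtype (10% of the feature
  space), is the one free choice; it is the scale of a realistic
  marker panel and is fixed once for all experiments. A Poisson
  count mode (rates exp(x + 3)) exercises the log2 path.
- **Survival**: exponential times with per-subtype hazards (default
  0.001·2ˢ per day, i.e. hazard ratio 2 between adjacent subtypes and
  median survival ≈ 700 days for the best group) and independent
  exponential censoring whose rate is solved to hit the requested
  censoring fraction (default 20%).

What passing tests on this bed shows: the pipeline recovers planted
structure when discriminative features are network-central, and the
weighting mechanism moves mass toward (away from) the signal when it
is central (isolated). What it does not show: robustness to heavy-tailed
count noise, batch effects, unbalanced or overlapping subtypes, or
identifier-mapping noise in real interaction databases — real-data
performance is not established by these tests.

## Problem sizes

Test and acceptance experiments run at 150 samples × 400 features with
20 replicate seeds, and 200 replicates for survival-test calibration
and power — sizes at which every experiment is exactly reproducible on
a laptop in seconds while leaving the planted-recovery task
non-trivial (recovery is imperfect on some seeds).

## Known limitations

- Exact, case-sensitive identifier matching; alias resolution is an
  upstream concern.
- Exactly two views are wired into `run_wsnf` (genes + miRNA), though
  `snf_fuse` accepts any m ≥ 2.
- The eigengap selector is a heuristic; for uniform similarity its
  ranking is arbitrary (documented behavior, not an error).
- Conflicting TF/mRNA class assignments raise an error rather than
  being resolved by precedence.
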