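# wsnf — weighted similarity network fusion for cancer-subtype discovery

Cancer subtypes identified from molecular data guide prognosis and
treatment, but clustering patients on expression alone treats every
gene, transcription factor (TF) and microRNA as equally informative.
`wsnf` implements *weighted* similarity network fusion: prior knowledge
from a miRNA–TF–mRNA regulatory network is turned into per-feature
weights, so that master regulators and high-variation features dominate
the patient-similarity structure that gets clustered. It is aimed at
computational biologists integrating matched gene (mRNA + TF) and
miRNA expression with curated interaction databases.

## Method

1. **Feature ranking.** On the directed regulatory graph (nodes =
   features, edges regulator → target), each feature's regulatory
   importance is the fixed point of a PageRank-style recursion run
   along outgoing edges:

   R(fᵢ) = (1 − d)/N + d · Σ_{fⱼ ∈ T(fᵢ)} R(fⱼ)/L(fⱼ)

   where T(fᵢ) is fᵢ's target set, L(fⱼ) the number of regulators of
   fⱼ, and d the damping factor (default 0.85). A regulator of many
   well-regulated targets ranks high.

2. **Feature weighting.** Expression variation is measured by the
   median absolute deviation MAD(fᵢ) = median(|X(fᵢ) − median(X(fᵢ))|).
   Rank and MAD are each normalized to sum to one (RN, MADN) and
   combined as

   W(fᵢ) = β·RN(fᵢ) + (1 − β)·MADN(fᵢ),  β ∈ [0, 1], default 0.8.

3. **Weighted fusion and clustering.** Per view (genes; miRNAs),
   patient distances are weighted Euclidean,
   Distance(Sᵢ,Sⱼ) = √(Σₘ W(fₘ)(fₘ^{Sᵢ} − fₘ^{Sⱼ})²), converted to
   scaled-exponential affinity kernels and fused by SNF's
   cross-network diffusion; the fused similarity matrix is clustered
   by normalized spectral clustering, with the cluster number chosen
   by the Laplacian eigengap or supplied explicitly.

4. **Validation.** Silhouette widths on the fused similarity,
   core-sample extraction (dropping negative-width samples), the
   k-group log-rank test on overall survival, and adjusted Rand index
   against known labels for synthetic data.

A seeded synthetic test bed (`wsnf.simulate`) generates regulatory
networks with hub structure, two-view expression with planted
subtypes, and exponential survival with subtype-specific hazards, so
the whole pipeline is verifiable without any data downloads.

## Worked example

Generate a synthetic cohort (90 patients, 3 planted subtypes, 200
features), run the pipeline with automatic cluster-number selection,
and evaluate:

```sh
wsnf simulate --config sim.yaml --seed 7 --out fix
wsnf rank --network fix/edges.tsv --classes fix/classes.tsv --out ranks.tsv
wsnf run --gene-expr fix/genes.tsv --mirna-expr fix/mirna.tsv \
         --network fix/edges.tsv --classes fix/classes.tsv \
         --k auto --seed 7 --out results
wsnf evaluate --subtypes results/subtypes.tsv \
              --fused results/fused_similarity.tsv \
              --survival fix/survival.csv --out eval
```

prints

```
wrote fixture (200 features, 343 edges, 90 samples) to fix
ranked 200 features (converged=True, iterations=114)
identified 3 subtypes for 90 samples -> results
average silhouette width 0.330; 90 core samples {1: 30, 2: 35, 3: 25}; log-rank chi2=10.568 (df=2), p=0.005073
```

The eigengap picked k = 3 (the planted number); all 90 samples have
nonnegative silhouette width, so all are core samples; and the three
subtypes separate in survival (log-rank p ≈ 0.005), as expected since
the generator gave them different hazards. `results/` also contains
the fused similarity matrix, the per-feature weight table and a YAML
snapshot of every parameter used.

The same pipeline is available as a library:

```python
import wsnf
cfg = wsnf.SimulationConfig(seed=7)
net = wsnf.simulate_network(cfg)
genes, mirna, truth = wsnf.simulate_expression(net, cfg)
result = wsnf.run_wsnf(genes, mirna, net, k=3, seed=7)
```

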