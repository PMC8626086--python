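# drgsn

Analysis toolkit for single-nucleus RNA-seq of dorsal root ganglion (DRG)
sensory neurons: per-nucleus quality control, shared-nearest-neighbor (SNN)
graph clustering with marker-based cluster merging, cross-species
co-embedding of human and mouse neurons, k-nearest-neighbor estimation of
Kullback–Leibler (KL) divergence between cluster distributions, and
neighborhood-composition statistics for spatially mapped cell types.  A
synthetic-data module generates negative-binomial count matrices and labeled
point maps with known ground truth, so every stage is testable without any
external download.

## Who this is for

Researchers comparing transcriptomic cell classes across species (e.g. human
DRG neuron classes H1–H15 against mouse classes such as NP1–NP3 or cLTMRs),
and anyone quantifying whether annotated cell types are spatially clustered
in tissue sections.

## The models and statistics at the core

**Clustering.** Counts are log-CP10K normalized, `x = ln(1 + 10⁴·c/total)`;
highly variable genes are selected by CP10K-scale dispersion (var/mean);
per-gene z-scored values (clipped at ±10) are decomposed by PCA; a k-NN graph
in PC space is symmetrized to an SNN graph with Jaccard weights and clustered
by Leiden modularity optimization at a chosen resolution.  Clusters that are
mutual nearest neighbors in PC space and have no distinguishing marker
(two-sided Wilcoxon rank-sum, Bonferroni-adjusted, detection prefilters
`min.pct`, `min.diff.pct`) are merged.  Non-neuronal clusters are triaged by
comparing mean expression of a neuronal panel (SNAP25, SCN9A, SCN10A, PIEZO2,
NEFH) against a glial/non-neuronal panel (PLP1, MBP, QKI, LPAR1, APOE).

**Cross-species KL divergence.**  After case-insensitive gene-name
harmonization and within-dataset z-scoring, both species are jointly embedded
by PCA (default 30 dimensions).  For a query cluster sample
P = {x₁…x_n} and reference cluster sample Q = {y₁…y_m} in d dimensions,

    D̂(P‖Q) = (d/n) Σᵢ ln( ν_k(xᵢ) / ρ_k(xᵢ) ) + ln( m/(n−1) )

where ρ_k is the distance from xᵢ to its k-th nearest neighbor within P
(self excluded) and ν_k its k-th nearest neighbor distance in Q.  The
human × mouse matrix of ln KL values is rendered as a heatmap; each row's
minimum is the best mouse match of that human cluster.

**Spatial neighborhood analysis.**  For each annotated single-positive cell,
the proportion of each label among its n nearest neighbors (n = 1…40,
Euclidean, within section) is compared between center labels with a
one-tailed Mann–Whitney U test (exact enumeration for small groups,
tie-corrected normal approximation otherwise), summarized by the maximum p
over the n range, alongside the random-mixing expectation
(n_t − 1{center is t})/(N − 1) and a label-permutation null.

## Worked example

```python
import numpy as np
from drgsn import (SimCountConfig, simulate_two_species, RunConfig,
                   run_cross_species)

ca = SimCountConfig(n_genes=2000, n_cells=750, n_clusters=5, doublet_rate=0.0, seed=51)
cb = SimCountConfig(n_genes=2000, n_cells=750, n_clusters=5, doublet_rate=0.0, seed=52)
a, b, truth = simulate_two_species(ca, cb, [(i, i) for i in range(5)],
                                   divergence_frac=0.3)
res = run_cross_species(a, b,
                        truth["cells_a"]["true_cluster"].to_numpy(),
                        truth["cells_b"]["true_cluster"].to_numpy(),
                        RunConfig(seed=0))
print(res["divergence"].ln_kl.round(2))
best = res["divergence"].ln_kl.astype(float).idxmin(axis=1)
print("recovered pairings:", dict(best))
```

prints

```
      0     1     2     3     4
0 -0.03  2.10  2.02  2.03  2.06
1  1.93 -0.78  1.91  1.91  1.94
2  2.03  2.03  0.44  2.04  2.05
3  2.04  2.04  2.03 -0.57  2.06
4  1.97  2.00  1.96  1.95 -0.11
recovered pairings: {0: 0, 1: 1, 2: 2, 3: 3, 4: 4}
```

Each entry is ln D̂(human cluster ‖ mouse cluster) in the joint 30-PC space.
The diagonal (the true pairings, since cluster i of species A was simulated
to share 70% of its marker program with cluster i of species B) is several
ln-units below the off-diagonal entries, so the per-row argmin recovers all
five pairings.

The same pipeline runs from the shell:

```bash
drgsn simulate counts --out bundle/ --seed 1
drgsn qc bundle/ --preset human --out qc.csv
drgsn cluster bundle/ --pcs 16 --resolution 2.0 --out run/ --seed 1
drgsn simulate spatial --mode thomas --out pts.csv --seed 2
drgsn spatial pts.csv --n-max 40 --out spatial_out/
```

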