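# Methods

This note records the models, defaults, and numerical conventions behind
`drgsn`, and what the synthetic-data tests do and do not demonstrate about
real data.

## Synthetic count model

Counts are negative binomial parameterized by mean and shape,
`var = μ + μ²/θ`, sampled as Gamma–Poisson — the standard overdispersed
noise model for UMI counts.  Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_genes` / `n_cells` | 2000 / 1000 | panel and sample size of a desk-scale experiment |
| `n_clusters` | 5 | planted cell classes, equal proportions |
| `base_mean` | 0.5 | baseline expected UMI per gene per cell |
| `marker_genes_per_cluster` | 20 | disjoint marker programs |
| `marker_fold` | 8 | fold elevation of marker means in their cluster |
| `dispersion` θ | 2.0 | NB shape; smaller = more overdispersed |
| `libsize_sigma` | 0.35 | log-normal library-size spread (mean-one) |
| `mito_gene_frac` / `mito_mean_frac` | 0.01 / 0.05 | mitochondrial gene count and expected UMI fraction |
| `doublet_rate` | 0.05 | droplet co-encapsulation rate (a field convention; the source data report no measured rate) |

Doublets are formed by *summing* two singlet profiles (physical
co-encapsulation adds transcripts), heterotypic with probability 0.75 —
the assumption artificial-doublet detectors themselves make.  Mitochondrial
gene means are scaled per cluster so the expected mitochondrial UMI fraction
matches `mito_mean_frac`.

The two-species generator gives both "species" the same gene stems, upper
case in species A and title case in species B, so orthology reduces to
case-insensitive matching and the harmonization step is exercised without an
ortholog table.  Paired clusters share their marker stems except a
`divergence_frac` fraction swapped for species-specific markers.

What the generator does **not** emulate: batch/donor structure, ambient RNA,
gene–gene correlation within programs beyond shared cluster membership,
gene-length or capture biases, and the long-tailed expression distribution of
real transcriptomes.  Passing recovery tests therefore demonstrates that the
pipeline machinery is correct and well-calibrated under its stated noise
model, not that real tissue will cluster this cleanly.

## Quality control

Per-nucleus metrics are the number of detected genes (≥1 UMI), total UMI,
and mitochondrial fraction (0 for empty cells).  Filtering keeps
`min_genes ≤ detected ≤ max_genes` (closed interval — "500–10,000 retained"
is read as inclusive) and `mito_frac < max_mito_frac` (strict, "<10%
retained").  Presets: human (500, 10 000, 0.10), mouse (400, 12 000, 0.01).
Mitochondrial genes are identified by the `MT-` name prefix
(case-insensitive) or an explicit mask.

Doublet scoring is a deliberately reduced artificial-nearest-neighbor
scheme: artificial doublets (one per real cell by default) are summed random
cell pairs; score = fraction of artificial profiles among a cell's 30
nearest neighbors in a 10-PC co-embedding; the top `expected_rate` fraction
is called.  The parameter-sweep and homotypic-adjustment stages of full
doublet detectors are omitted because the score is diagnostic here — calls
are reported, not used to drop cells.  On the default synthetic conditions
(10% doublets, 1000 cells) the score separates true doublets with AUROC
≈ 0.97.

## Normalization, HVG selection, PCA

Normalization is log-CP10K.  It is an explicit, testable surrogate for
regularized-NB variance stabilization; the downstream quantities reproduced
here (cluster structure, rank-based markers, KL geometry) are robust to this
substitution, and the divergence module accepts externally computed
embeddings for users who want a different upstream.

Highly variable genes are ranked by dispersion (variance/mean) of the
back-transformed CP10K values — the log scale compresses exactly the
bimodality that makes a marker gene variable.  Ranking is global by default.
The classic within-mean-bin standardization is available (`n_bins > 1`) but
is not the default: when a substantial set of co-regulated genes occupies
its own mean range (as planted marker programs do), binning normalizes those
genes against each other and suppresses them; global ranking recovers 100%
of planted markers where binned variants recover under 20%.  For genome-wide
matrices with a strong mean–dispersion trend, enable binning and raise
`n_hvg` to the conventional 2000 (the default 500 is sized to the
2000-gene synthetic panel).

PCA operates on per-gene z-scores clipped at ±10.  Components carry a
deterministic sign (largest-|loading| entry positive) so embeddings are
bit-reproducible.  Note one consequence of z-scoring: variance that lives in
a *single* feature is normalized away; separations must span correlated
features (as gene programs do) to dominate a PC.

## Graph clustering and merging

The k-NN graph (k = 20, Euclidean in PC space, self excluded, ties broken
by cell index) is symmetrized to an SNN graph with Jaccard weights over the
self-inclusive neighbor lists; edges below 1/15 are pruned.  Communities are
found with Leiden (RB-configuration modularity) at the configured
resolution, seeded.  Defaults mirror the human analysis: 16 PCs, resolution
2.0 (mouse: 20 PCs, 3.5; joint: 30 PCs, 0.5).  Because modularity never
fuses disconnected components, the number of communities is bounded below by
the number of SNN components regardless of resolution.

Merging formalizes "closely related clusters without distinguishing markers
were merged": repeatedly take the closest mutually-nearest cluster pair
(centroid distance in PC space); if a two-sided Wilcoxon marker scan in
both directions (min.pct = min.diff.pct = 0.25) yields no gene with
Bonferroni-adjusted p < 0.05, merge and restart.  This is one defensible
automation of a partly judgment-based step, not a claim about the original
authors' exact procedure.

Neuronal triage scores each cluster by mean normalized expression of a
neuronal panel versus a non-neuronal panel and removes clusters where the
non-neuronal score strictly wins (ties retain).  The default non-neuronal
panel uses PLP1 — the oligodendrocyte proteolipid gene — alongside MBP,
QKI, LPAR1, APOE; both panels are fully configurable.

## Marker statistics

The rank-sum core computes U with midranks.  For group sizes with
n₁ + n₂ ≤ 16 the p-value is an exact enumeration over all C(n₁+n₂, n₁)
assignments of the pooled values — correct under ties; two-sided p counts
assignments with |U − μ| at least the observed.  Larger groups use the
tie-corrected normal approximation with continuity correction (verified
identical to 1e-12 against the standard asymptotic implementation).
Bonferroni adjustment runs over the genes actually tested after the
`min.pct` / `min.diff.pct` detection prefilters.  Log fold change is
`ln(mean expm1(in)/mean expm1(out))` with a 1e-9 pseudocount.

## Cross-species embedding

Gene names are uppercased; both matrices are restricted to the shared set in
a stable order; name collisions keep the higher-count row with a warning.
Each dataset is log-CP10K normalized and z-scored per gene *within* dataset
— removing dataset-specific location and scale, the minimal harmonization
that places both species on comparable axes — then concatenated and jointly
decomposed by PCA (30 dims).  This replaces anchor-based integration
internals with a reproducible linear construction; an externally produced
embedding CSV (cell_id, species, orig_label, PC1..PCk) is accepted
everywhere downstream for users who prefer the anchor-based space.  The
larger dataset is subsampled to the size of the smaller before embedding
(logged, configurable) because a strongly unbalanced joint decomposition is
dominated by the bigger dataset.

## KL divergence estimation

The k-NN estimator (k = 1 by default, exposed) is

    D̂(P‖Q) = (d/n) Σᵢ ln(ν_k(xᵢ)/ρ_k(xᵢ)) + ln(m/(n−1)).

It is asymptotically unbiased; finite-sample estimates may be negative.
Raw estimates are reported unclamped; only the logarithm for the heatmap
clamps at ε = 1e-6.  Zero nearest-neighbor distances (duplicate points) are
replaced by the smallest positive observed distance × 1e-12.  Clusters with
fewer than `min_cells` (default 5) cells are reported missing, never as 0.
The matrix is asymmetric by construction and no symmetrization is applied.
Measured accuracy: mean estimate over 20 seeds within 0.03 of the
closed-form KL = 1.0 for a unit-shifted 2-D Gaussian at n = m = 5000, and
exact agreement (1e-10) with a brute-force evaluation of the same formula.

## Spatial statistics

The neighbor universe is the annotated single-positive cells themselves;
neighborhoods never cross section boundaries; centers are pooled across
sections.  The per-n test compares per-center proportions of a target label
between same-label and other-label centers, one-tailed (same-label
enrichment), summarized by the **maximum p over n = 1…40** — the bound
style used when clustering is significant "across the complete range".  No
multiplicity correction beyond the max is applied.

Two null-calibration routes are provided, with different properties:

* `clustering_test` (Mann–Whitney, centers as units): powerful — on
  Thomas-process maps (10 parents/label, σ = 50 µm, 800 points) the max-p
  over n = 1–40 is below 1e-6 in effectively all simulations — but
  **anti-conservative under complete spatial randomness**, because nearby
  centers share neighborhood members and are not independent units.  At the
  default sizes the measured type-I rate at α = 0.05 and n = 10 is ≈ 0.08
  rather than 0.05 (the standardized U has sd ≈ 1.3).  SEM shading in the
  curves inherits the same caveat.
* `permutation_null` (label permutation over fixed coordinates, within
  section): exact by construction — it conditions on the observed geometry —
  with measured type-I ≈ 0.05.  Use it whenever calibrated p-values matter;
  use the Mann–Whitney route for comparability with the max-p reporting
  convention.

The random-mixing expectation around a center of label c for target t in a
section of N cells is `(n_t − 1{c = t})/(N − 1)`, averaged over centers —
the minus-one center correction is negligible at N ≈ 800 but included.

## Problem sizes and determinism

Acceptance-scale runs use 1000-cell single-species data, 750 cells per
species for co-embedding, 1000 CSR maps of two 400-cell sections for
calibration, and 100 Thomas maps for power — sizes at which every reported
quantity is stable across seeds while a full recomputation stays
desk-scale.  All stochastic stages consume a single seed per run; identical
config + seed reproduces identical outputs (manifest hashes included).

## Known limitations

* Log-CP10K is a coarser variance stabilization than regularized NB
  regression; absolute PC geometry (hence absolute KL values) differs from
  an sctransform-based upstream, though cluster-level comparisons are stable.
* The merge rule and triage rule are automated formalizations of
  judgment-based steps; on real data they should be reviewed cluster by
  cluster.
* The KL estimator variant is fixed (Perez-Cruz-family, k configurable);
  absolute divergence values depend on k and on the embedding, so
  cross-study comparisons should hold both fixed.
* The Mann–Whitney spatial test's miscalibration under CSR is documented
  above; its max-p summary is best read as a power statement, with the
  permutation p as the calibrated complement.
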