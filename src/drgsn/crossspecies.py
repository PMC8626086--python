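"""Cross-species gene harmonization and joint embedding.

Gene names are uppercased and the two matrices restricted to the shared
set (case-insensitive orthology).  Each dataset is log-CP10K normalized and
per-gene z-scored *within* dataset — removing dataset-specific location and
scale — then the cell blocks are concatenated and jointly decomposed by PCA
into the shared space consumed by the divergence module.  An externally
computed embedding (e.g. exported from an anchor-based integration) can be
substituted via :func:`drgsn.io.read_embedding_csv`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, Embedding
from .preprocessing import ZScorePCA, normalize_log_cp10k


@dataclass
class IntegrationConfig:
    n_pcs_joint: int = 30
    resolution_joint: float = 0.5
    dims_hint: int = 15  # recorded for provenance only; unused by the embedding
    subsample_b: Optional[int] = None  # cells to draw from dataset B (None: match A)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs_joint < 2:
            raise ValueError("n_pcs_joint must be >= 2")
        if self.resolution_joint <= 0:
            raise ValueError("resolution_joint must be positive")


def harmonize_genes(a: CountMatrix, b: CountMatrix) -> Tuple[CountMatrix, CountMatrix]:
    """Uppercase gene names and restrict both matrices to the shared set.

    Rows are ordered identically (order of first appearance in ``a``).  If
    two distinct genes collide onto one uppercase name, the row with the
    higher total count is kept (with a warning).
    """

    def dedupe(m: CountMatrix) -> Tuple[dict, CountMatrix]:
        upper = np.array([str(g).upper() for g in m.gene_ids], dtype=object)
        totals = np.asarray(m.counts.sum(axis=1)).ravel()
        best: dict = {}
        for i, name in enumerate(upper):
            if name not in best or totals[i] > totals[best[name]]:
                if name in best:
                    warnings.warn(
                        f"gene name collision after uppercasing: {name}; "
                        "keeping the higher-total-count row"
                    )
                best[name] = i
        return best, m

    best_a, _ = dedupe(a)
    best_b, _ = dedupe(b)
    upper_a = [str(g).upper() for g in a.gene_ids]
    seen = set()
    shared = []
    for name in upper_a:
        if name in best_b and name not in seen:
            seen.add(name)
            shared.append(name)
    if not shared:
        raise ValueError("no shared genes between the two matrices")

    idx_a = np.array([best_a[n] for n in shared])
    idx_b = np.array([best_b[n] for n in shared])
    out_a = a.subset_genes(idx_a)
    out_b = b.subset_genes(idx_b)
    out_a.gene_ids = np.array(shared, dtype=object)
    out_b.gene_ids = np.array(shared, dtype=object)
    return out_a, out_b


def _zscore_within(norm: sp.spmatrix, clip: float = 10.0) -> np.ndarray:
    """Per-gene z-score of a genes x cells matrix, clipped; needs >= 2 cells."""
    X = np.asarray(sp.csr_matrix(norm).todense())
    if X.shape[1] < 2:
        raise ValueError("z-scoring within a dataset requires >= 2 cells")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return np.clip((X - mu) / sd, -clip, clip)


def co_embed(
    a: CountMatrix,
    b: CountMatrix,
    config: IntegrationConfig = IntegrationConfig(),
    labels_a: Optional[Sequence] = None,
    labels_b: Optional[Sequence] = None,
) -> Embedding:
    """Joint PCA embedding of two harmonized matrices.

    Both matrices must carry identical gene rows (run
    :func:`harmonize_genes` first).  ``labels_a``/``labels_b`` attach the
    original single-species cluster labels to the embedding metadata.
    """
    if a.n_genes != b.n_genes or not np.array_equal(a.gene_ids, b.gene_ids):
        raise ValueError("gene rows differ; harmonize_genes first")
    za = _zscore_within(normalize_log_cp10k(a))
    zb = _zscore_within(normalize_log_cp10k(b))
    X = np.concatenate([za.T, zb.T], axis=0)  # cells x genes
    n_pcs = min(config.n_pcs_joint, X.shape[1], X.shape[0] - 1)
    scores = ZScorePCA(n_pcs=n_pcs, seed=config.seed).fit_transform(X)

    cell_ids = np.concatenate([a.cell_ids, b.cell_ids])
    species = np.array([a.species] * a.n_cells + [b.species] * b.n_cells, dtype=object)
    orig = np.concatenate(
        [
            np.asarray(labels_a if labels_a is not None else ["NA"] * a.n_cells, dtype=object),
            np.asarray(labels_b if labels_b is not None else ["NA"] * b.n_cells, dtype=object),
        ]
    )
    meta = pd.DataFrame({"species": species, "orig_label": orig})
    return Embedding(
        coords=scores, cell_ids=cell_ids, source="pca_joint", meta=meta
    )


def joint_cluster_crosstab(
    joint_labels: Sequence, orig_labels: Sequence
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Joint-cluster x original-label contingency counts and row proportions."""
    joint_labels = np.asarray(joint_labels)
    orig_labels = np.asarray(orig_labels)
    if len(joint_labels) != len(orig_labels):
        raise ValueError("label vectors must have equal length")
    counts = pd.crosstab(
        pd.Series(joint_labels, name="joint_cluster"),
        pd.Series(orig_labels, name="orig_label"),
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    return counts, props
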