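"""Graph clustering in PC space, data-driven cluster merging, and
neuronal / non-neuronal cluster triage.

Clustering builds a k-nearest-neighbor graph (Euclidean in PC space, self
excluded, ties broken by cell index), symmetrizes it to a shared-nearest-
neighbor (SNN) graph with Jaccard edge weights, and optimizes modularity
with the Leiden algorithm at a given resolution.
"""

from __future__ import annotations

import warnings
from typing import Sequence, Tuple

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import NearestNeighbors

from .containers import ClusterPartition, Embedding
from .markers import find_markers

SNN_PRUNE = 1.0 / 15.0  # drop SNN edges with Jaccard weight below this


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors per point (self excluded, ties by point index)."""
    n = coords.shape[0]
    if k >= n:
        raise ValueError("knn_k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=min(k + 2, n)).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # stable tie-break: re-sort each row by (distance, index), then drop self
    out = np.empty((n, k), dtype=int)
    for r in range(n):
        order = np.lexsort((idx[r], np.round(dist[r], 12)))
        row = idx[r][order]
        row = row[row != r]
        out[r] = row[:k]
    return out


def snn_graph(coords: np.ndarray, k: int, prune: float = SNN_PRUNE) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard weights.

    Neighbor sets include the cell itself (so two mutual neighbors with a
    fully shared list get weight 1); edges with weight < ``prune`` are
    dropped.  Returns a symmetric sparse adjacency with weights in (0, 1].
    """
    n = coords.shape[0]
    knn = _knn_indices(coords, k)
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([knn, np.arange(n)[:, None]], axis=1).ravel()
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    inter = (A @ A.T).tocoo()
    union = 2 * (k + 1) - inter.data
    w = inter.data / union
    keep = (w >= prune) & (inter.row != inter.col)
    return sp.csr_matrix((w[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))


class SNNLeiden(ClusterMixin, BaseEstimator):
    """SNN-graph Leiden clustering estimator (cells x dims input).

    Parameters mirror the Seurat-style workflow: ``knn_k`` neighbors,
    modularity (RB configuration) optimization at ``resolution``; ``seed``
    fixes the Leiden refinement randomness.
    """

    def __init__(self, knn_k: int = 20, resolution: float = 2.0, seed: int = 0,
                 prune: float = SNN_PRUNE):
        self.knn_k = knn_k
        self.resolution = resolution
        self.seed = seed
        self.prune = prune

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        n = X.shape[0]
        if np.allclose(X, X[0]):  # all points identical: one community
            self.labels_ = np.zeros(n, dtype=int)
            return self
        adj = snn_graph(X, self.knn_k, self.prune)
        coo = sp.triu(adj, k=1).tocoo()
        g = ig.Graph(
            n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
        )
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=coo.data.tolist(),
            resolution_parameter=self.resolution,
            seed=self.seed,
            n_iterations=-1,
        )
        self.labels_ = _relabel_by_size(np.asarray(part.membership))
        return self


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 0..K-1 by decreasing size (ties by old label)."""
    vals, counts = np.unique(labels, return_counts=True)
    order = vals[np.lexsort((vals, -counts))]
    lut = {old: new for new, old in enumerate(order)}
    return np.array([lut[v] for v in labels], dtype=int)


def cluster_graph(
    e: Embedding, knn_k: int = 20, resolution: float = 2.0, seed: int = 0
) -> ClusterPartition:
    """Cluster an embedding; see :class:`SNNLeiden`."""
    model = SNNLeiden(knn_k=knn_k, resolution=resolution, seed=seed).fit(e.coords)
    return ClusterPartition(labels=model.labels_, stage="raw")


def merge_indistinct_clusters(
    normalized: sp.spmatrix,
    partition: ClusterPartition,
    embedding: Embedding,
    gene_ids: Sequence[str],
    alpha: float = 0.05,
    min_pct: float = 0.25,
    min_diff_pct: float = 0.25,
    max_iter: int = 100,
) -> ClusterPartition:
    """Iteratively merge mutually-nearest cluster pairs lacking markers.

    At each step the mutually-nearest pair of clusters (centroid Euclidean
    distance in PC space) is tested with :func:`find_markers` in both
    directions; if no gene reaches ``adjusted_p < alpha`` at the given
    pct thresholds the pair is merged and the search restarts.  Stops when
    every mutually-nearest pair is distinguishable (or one cluster remains).
    """
    labels = np.asarray(partition.labels).copy()
    norm = sp.csr_matrix(normalized)
    tested_distinct: set = set()

    for _ in range(max_iter):
        uniq = np.unique(labels)
        if len(uniq) < 2:
            break
        cents = np.vstack([embedding.coords[labels == c].mean(axis=0) for c in uniq])
        d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nearest = d.argmin(axis=1)
        pairs = [
            (uniq[i], uniq[nearest[i]], d[i, nearest[i]])
            for i in range(len(uniq))
            if nearest[nearest[i]] == i and i < nearest[i]
        ]
        pairs.sort(key=lambda t: t[2])
        merged = False
        for ca, cb, _dist in pairs:
            if (ca, cb) in tested_distinct:
                continue
            distinct = False
            for a, b in ((ca, cb), (cb, ca)):
                t = find_markers(
                    norm, labels, a, b, gene_ids=gene_ids,
                    min_pct=min_pct, min_diff_pct=min_diff_pct,
                )
                if len(t) and (t["adjusted_p"] < alpha).any():
                    distinct = True
                    break
            if distinct:
                tested_distinct.add((ca, cb))
                continue
            labels[labels == cb] = ca
            tested_distinct = set()
            merged = True
            break
        if not merged:
            break
    return ClusterPartition(labels=_relabel_by_size(labels), stage="merged")


DEFAULT_NEURONAL_PANEL = ("SNAP25", "SCN9A", "SCN10A", "PIEZO2", "NEFH")
DEFAULT_NONNEURONAL_PANEL = ("PLP1", "MBP", "QKI", "LPAR1", "APOE")


def triage_neuronal(
    normalized: sp.spmatrix,
    partition: ClusterPartition,
    gene_ids: Sequence[str],
    neuronal_genes: Sequence[str] = DEFAULT_NEURONAL_PANEL,
    nonneuronal_genes: Sequence[str] = DEFAULT_NONNEURONAL_PANEL,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Call clusters neuronal vs non-neuronal by panel mean expression.

    Per cluster, the neuronal score is the mean normalized expression over
    the neuronal gene panel (genes missing from the matrix are skipped with
    a warning), likewise for the non-neuronal panel.  A cluster is removed
    when its non-neuronal score strictly exceeds its neuronal score (ties
    retain).  Returns the per-cluster call table and a boolean mask of
    retained cells.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    lut = {g: i for i, g in enumerate(gene_ids)}

    def panel_idx(panel, name):
        idx = [lut[g] for g in panel if g in lut]
        missing = [g for g in panel if g not in lut]
        if missing:
            warnings.warn(f"{name} panel genes missing from matrix: {missing}")
        return np.array(idx, dtype=int)

    neu = panel_idx(neuronal_genes, "neuronal")
    non = panel_idx(nonneuronal_genes, "non-neuronal")
    if len(neu) == 0 and len(non) == 0:
        raise ValueError("both gene panels are entirely absent from the matrix")

    norm = sp.csr_matrix(normalized)
    labels = np.asarray(partition.labels)
    rows = []
    for c in np.unique(labels):
        cells = np.flatnonzero(labels == c)
        neu_score = float(norm[neu][:, cells].mean()) if len(neu) else 0.0
        non_score = float(norm[non][:, cells].mean()) if len(non) else 0.0
        rows.append(
            {
                "cluster": c,
                "neuronal_score": neu_score,
                "nonneuronal_score": non_score,
                "neuronal": not (non_score > neu_score),
            }
        )
    calls = pd.DataFrame(rows)
    keep_clusters = set(calls.loc[calls["neuronal"], "cluster"])
    keep_mask = np.array([l in keep_clusters for l in labels], dtype=bool)
    return calls, keep_mask
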