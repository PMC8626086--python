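"""SNN/Leiden clustering, cluster merging, and neuronal triage."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from drgsn import (
    ClusterPartition,
    Embedding,
    SNNLeiden,
    cluster_graph,
    merge_indistinct_clusters,
    normalize_log_cp10k,
    triage_neuronal,
)
from drgsn.clustering import snn_graph


def blob_embedding(n_per=100, centers=((0, 0), (10, 0), (0, 10)), sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.concatenate(
        [rng.normal(c, sd, size=(n_per, 2)) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    return Embedding(pts, [f"c{i}" for i in range(len(pts))]), labels


class TestClusterGraph:
    def test_three_separated_blobs_pure(self):
        # disconnected SNN components are never fused by modularity, so a low
        # resolution yields exactly the three blobs
        emb, truth = blob_embedding()
        part = cluster_graph(emb, knn_k=15, resolution=0.2, seed=0)
        assert part.n_clusters == 3
        assert adjusted_rand_score(truth, part.labels) == 1.0

    def test_identical_coordinates_single_community(self):
        emb = Embedding(np.zeros((50, 3)), [f"c{i}" for i in range(50)])
        part = cluster_graph(emb, knn_k=10, resolution=2.0, seed=0)
        assert part.n_clusters == 1

    def test_deterministic_given_seed(self):
        emb, _ = blob_embedding(sd=2.0)
        a = cluster_graph(emb, knn_k=15, resolution=2.0, seed=3)
        b = cluster_graph(emb, knn_k=15, resolution=2.0, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_resolution_monotone_community_count(self):
        # on a fixed graph, higher resolution should not produce fewer
        # communities (checked over a grid; any violation would be a
        # library-level artifact worth knowing about)
        rng = np.random.default_rng(7)
        X = np.concatenate([rng.normal(c * 3, 1.0, size=(80, 4)) for c in range(4)])
        emb = Embedding(X, [f"c{i}" for i in range(len(X))])
        counts = [
            cluster_graph(emb, knn_k=15, resolution=r, seed=0).n_clusters
            for r in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_rejects_bad_k(self):
        emb, _ = blob_embedding(n_per=10)
        with pytest.raises(ValueError):
            cluster_graph(emb, knn_k=0)
        with pytest.raises(ValueError):
            SNNLeiden(knn_k=30).fit(np.random.default_rng(0).normal(size=(10, 2)))

    def test_snn_graph_symmetric_jaccard(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        A = snn_graph(X, k=8)
        assert (abs(A - A.T) > 1e-12).nnz == 0
        assert A.data.max() <= 1.0 and A.data.min() > 0


class TestMerge:
    def _norm_and_emb(self, labels, n_genes=300, marker_lookup=None, seed=0):
        """Counts with per-cluster markers per marker_lookup (cluster->gene idx)."""
        rng = np.random.default_rng(seed)
        n_cells = len(labels)
        mu = np.full((n_genes, n_cells), 0.5)
        if marker_lookup:
            for c, idx in marker_lookup.items():
                cells = np.flatnonzero(labels == c)
                for g in idx:
                    mu[g, cells] = 4.0
        counts = rng.poisson(mu)
        from test_qc import toy_matrix

        m = toy_matrix(counts, gene_ids=[f"g{i}" for i in range(n_genes)])
        norm = normalize_log_cp10k(m)
        from drgsn import run_pca, select_hvg

        hvg = select_hvg(norm, m.gene_ids, 100)
        emb = run_pca(norm, hvg, 10, seed=0)
        return m, norm, emb

    def test_random_split_of_one_blob_merged(self):
        labels_true = np.zeros(200, dtype=int)
        m, norm, emb = self._norm_and_emb(labels_true)
        fake = np.array([0, 1] * 100)  # arbitrary split with no real structure
        merged = merge_indistinct_clusters(
            norm, ClusterPartition(fake), emb, m.gene_ids
        )
        assert merged.n_clusters == 1

    def test_marker_separated_clusters_not_merged(self):
        labels = np.repeat([0, 1], 150)
        lookup = {0: range(0, 20), 1: range(20, 40)}
        m, norm, emb = self._norm_and_emb(labels, marker_lookup=lookup)
        merged = merge_indistinct_clusters(
            norm, ClusterPartition(labels), emb, m.gene_ids
        )
        assert merged.n_clusters == 2

    def test_single_cluster_unchanged(self):
        labels = np.zeros(50, dtype=int)
        m, norm, emb = self._norm_and_emb(labels)
        merged = merge_indistinct_clusters(norm, ClusterPartition(labels), emb, m.gene_ids)
        assert merged.n_clusters == 1

    def test_never_increases_cluster_count(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 4, 240)
        m, norm, emb = self._norm_and_emb(labels)
        merged = merge_indistinct_clusters(norm, ClusterPartition(labels), emb, m.gene_ids)
        assert merged.n_clusters <= 4


class TestTriage:
    def _panel_matrix(self, cluster_panel_level):
        """Two clusters x 100 cells; expression of the two panels set per cluster.

        ``cluster_panel_level``: {cluster: (neuronal_mean, nonneuronal_mean)}
        """
        from test_qc import toy_matrix

        genes = ["SNAP25", "SCN9A", "PLP1", "APOE", "OTHER"]
        rng = np.random.default_rng(0)
        labels = np.repeat(sorted(cluster_panel_level), 100)
        mu = np.ones((len(genes), len(labels)))
        for c, (neu, non) in cluster_panel_level.items():
            cells = np.flatnonzero(labels == c)
            mu[np.ix_([0, 1], cells)] = neu
            mu[np.ix_([2, 3], cells)] = non
        m = toy_matrix(rng.poisson(mu * 5), gene_ids=genes)
        return m, normalize_log_cp10k(m), labels

    def test_nonneuronal_cluster_removed(self):
        m, norm, labels = self._panel_matrix({0: (4.0, 0.1), 1: (0.1, 4.0)})
        calls, keep = triage_neuronal(norm, ClusterPartition(labels), m.gene_ids)
        assert calls.set_index("cluster")["neuronal"].to_dict() == {0: True, 1: False}
        assert set(labels[keep]) == {0}

    def test_tie_retains(self):
        from test_qc import toy_matrix

        m = toy_matrix(np.zeros((5, 20)), gene_ids=["SNAP25", "SCN9A", "PLP1", "APOE", "x"])
        norm = normalize_log_cp10k(m)
        calls, keep = triage_neuronal(norm, ClusterPartition(np.zeros(20, int)), m.gene_ids)
        assert calls["neuronal"].all() and keep.all()

    def test_shared_gene_counts_in_both_panels(self):
        m, norm, labels = self._panel_matrix({0: (4.0, 0.1)})
        calls, _ = triage_neuronal(
            norm, ClusterPartition(labels), m.gene_ids,
            neuronal_genes=("SNAP25", "PLP1"), nonneuronal_genes=("PLP1", "APOE"),
        )
        assert np.isfinite(calls[["neuronal_score", "nonneuronal_score"]]).all().all()

    def test_missing_panel_genes_warn_and_absent_panels_fail(self):
        m, norm, labels = self._panel_matrix({0: (4.0, 0.1)})
        with pytest.warns(UserWarning):
            triage_neuronal(
                norm, ClusterPartition(labels), m.gene_ids,
                neuronal_genes=("SNAP25", "NOTAGENE"),
            )
        with pytest.raises(ValueError):
            triage_neuronal(
                norm, ClusterPartition(labels), m.gene_ids,
                neuronal_genes=("NOPE",), nonneuronal_genes=("NADA",),
            )

    def test_elevated_neuronal_cluster_never_removed(self, five_cluster_normalized):
        # synthetic clusters carry no non-neuronal program: triage must retain all
        m, norm, hvg, emb, labels = five_cluster_normalized
        genes = list(m.gene_ids[:4])
        calls, keep = triage_neuronal(
            norm, ClusterPartition(labels), m.gene_ids,
            neuronal_genes=genes, nonneuronal_genes=("ABSENT1", "ABSENT2"),
        )
        assert keep.all()
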