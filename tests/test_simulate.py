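"""Generator contracts: determinism, NB moments, marker structure, spatial nulls."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from drgsn import (
    SimCountConfig,
    SimSpatialConfig,
    simulate_counts,
    simulate_spatial_map,
    simulate_two_species,
)
from conftest import true_marker_indices


class TestSimulateCounts:
    def test_deterministic_given_seed(self):
        cfg = SimCountConfig(n_genes=300, n_cells=200, n_clusters=3, seed=11)
        a = simulate_counts(cfg)
        b = simulate_counts(SimCountConfig(n_genes=300, n_cells=200, n_clusters=3, seed=11))
        assert (a[0].counts != b[0].counts).nnz == 0
        assert np.array_equal(a[1], b[1]) and np.array_equal(a[2], b[2])
        c = simulate_counts(SimCountConfig(n_genes=300, n_cells=200, n_clusters=3, seed=12))
        assert (a[0].counts != c[0].counts).nnz > 0

    def test_zero_rate_is_degenerate_at_zero(self):
        cfg = SimCountConfig(
            n_genes=100, n_cells=50, n_clusters=2, base_mean=0.0,
            mito_mean_frac=0.0, doublet_rate=0.0, seed=0,
        )
        m, _, doublets = simulate_counts(cfg)
        assert m.counts.nnz == 0
        assert not doublets.any()

    def test_nb_mean_recovery(self):
        # single cluster, no library noise: empirical per-gene mean should sit
        # within 3 standard errors of the configured mean for nearly all genes
        mu, theta, n = 0.5, 2.0, 2000
        cfg = SimCountConfig(
            n_genes=500, n_cells=n, n_clusters=1, base_mean=mu, dispersion=theta,
            marker_genes_per_cluster=0, libsize_sigma=0.0, mito_gene_frac=0.0,
            mito_mean_frac=0.0, doublet_rate=0.0, seed=1,
        )
        m, _, _ = simulate_counts(cfg)
        means = np.asarray(m.counts.mean(axis=1)).ravel()
        se = np.sqrt((mu + mu**2 / theta) / n)
        frac_ok = np.mean(np.abs(means - mu) <= 3 * se)
        assert frac_ok >= 0.99

    def test_nb_variance_recovery(self):
        mu, theta = 2.0, 0.5
        cfg = SimCountConfig(
            n_genes=200, n_cells=5000, n_clusters=1, base_mean=mu, dispersion=theta,
            marker_genes_per_cluster=0, libsize_sigma=0.0, mito_gene_frac=0.0,
            mito_mean_frac=0.0, doublet_rate=0.0, seed=2,
        )
        m, _, _ = simulate_counts(cfg)
        X = np.asarray(m.counts.todense(), dtype=float)
        expected_var = mu + mu**2 / theta
        assert np.median(X.var(axis=1)) == pytest.approx(expected_var, rel=0.15)

    def test_mito_fraction_targets_config(self):
        cfg = SimCountConfig(
            n_genes=1000, n_cells=500, n_clusters=2, mito_gene_frac=0.02,
            mito_mean_frac=0.10, doublet_rate=0.0, seed=3,
        )
        m, _, _ = simulate_counts(cfg)
        total = np.asarray(m.counts.sum(axis=0)).ravel()
        mito = np.asarray(m.counts[m.mito_mask].sum(axis=0)).ravel()
        assert np.mean(mito / total) == pytest.approx(0.10, abs=0.02)

    def test_marker_sets_disjoint(self):
        cfg = SimCountConfig(n_genes=500, n_cells=10, n_clusters=4, seed=5)
        markers = true_marker_indices(cfg)
        pooled = np.concatenate(list(markers.values()))
        assert len(pooled) == len(set(pooled))

    def test_doublet_rate_and_flags(self):
        cfg = SimCountConfig(n_genes=200, n_cells=400, n_clusters=3,
                             doublet_rate=0.1, seed=6)
        _, _, doublets = simulate_counts(cfg)
        assert doublets.sum() == 40

    def test_rejects_marker_overflow(self):
        with pytest.raises(ValueError):
            SimCountConfig(n_genes=50, n_clusters=5, marker_genes_per_cluster=20)

    def test_rejects_bad_props(self):
        with pytest.raises(ValueError):
            SimCountConfig(n_clusters=2, cluster_props=[0.7, 0.7])


class TestSimulateTwoSpecies:
    def test_case_encoded_orthology(self):
        ca = SimCountConfig(n_genes=300, n_cells=50, n_clusters=2, seed=1)
        cb = SimCountConfig(n_genes=300, n_cells=50, n_clusters=2, seed=2)
        a, b, _ = simulate_two_species(ca, cb, [(0, 0)], divergence_frac=0.5)
        stems_a = {g.lower() for g in a.gene_ids}
        stems_b = {g.lower() for g in b.gene_ids}
        assert all(g == g.upper() for g in a.gene_ids)
        assert all(g[:1] == g[:1].upper() and g[1:] == g[1:].lower() for g in b.gene_ids)
        assert stems_a.intersection(stems_b)  # same stems, different case

    @pytest.mark.parametrize("div,expect_shared", [(0.0, "all"), (1.0, "none")])
    def test_divergence_extremes(self, div, expect_shared):
        ca = SimCountConfig(n_genes=500, n_cells=50, n_clusters=3, seed=1)
        cb = SimCountConfig(n_genes=500, n_cells=50, n_clusters=3, seed=2)
        _, _, truth = simulate_two_species(ca, cb, [(0, 0), (1, 1)], divergence_frac=div)
        ma = truth["markers_a"]
        mb = truth["markers_b"]
        for pair in [(0, 0), (1, 1)]:
            sa = {g.lower() for g in ma.loc[ma.cluster == pair[0], "gene"]}
            sb = {g.lower() for g in mb.loc[mb.cluster == pair[1], "gene"]}
            if expect_shared == "all":
                assert sa == sb
            else:
                assert not sa & sb

    def test_rejects_missing_cluster(self):
        ca = SimCountConfig(n_genes=300, n_cells=20, n_clusters=2, seed=1)
        cb = SimCountConfig(n_genes=300, n_cells=20, n_clusters=2, seed=2)
        with pytest.raises(ValueError):
            simulate_two_species(ca, cb, [(0, 5)])

    def test_deterministic(self):
        ca = SimCountConfig(n_genes=300, n_cells=40, n_clusters=2, seed=9)
        cb = SimCountConfig(n_genes=300, n_cells=40, n_clusters=2, seed=10)
        a1, b1, _ = simulate_two_species(ca, cb, [(0, 0)], 0.2)
        a2, b2, _ = simulate_two_species(ca, cb, [(0, 0)], 0.2)
        assert (a1.counts != a2.counts).nnz == 0
        assert (b1.counts != b2.counts).nnz == 0


class TestSimulateSpatial:
    def test_label_fractions_csr(self):
        pts = simulate_spatial_map(
            SimSpatialConfig(n_points=10_000, mode="csr", seed=0)
        )
        frac_a = (pts["label"] == "A").mean()
        assert 0.48 <= frac_a <= 0.52

    def test_single_label(self):
        pts = simulate_spatial_map(
            SimSpatialConfig(n_points=100, labels=["only"], mode="csr", seed=1)
        )
        assert (pts["label"] == "only").all()

    def test_thomas_aggregates_same_labels(self):
        # same-label nearest-neighbor excess under clustering, none under CSR
        def same_label_nn_frac(pts):
            from sklearn.neighbors import NearestNeighbors

            xy = pts[["x_um", "y_um"]].to_numpy()
            _, idx = NearestNeighbors(n_neighbors=2).fit(xy).kneighbors(xy)
            return (pts["label"].to_numpy()[idx[:, 1]] == pts["label"].to_numpy()).mean()

        thomas = simulate_spatial_map(
            SimSpatialConfig(n_points=800, mode="thomas", n_parents=10,
                             parent_sigma=50.0, seed=2)
        )
        csr = simulate_spatial_map(SimSpatialConfig(n_points=800, mode="csr", seed=2))
        wide = simulate_spatial_map(
            SimSpatialConfig(n_points=800, mode="thomas", n_parents=10,
                             parent_sigma=1e6, seed=2)
        )
        f_thomas, f_csr, f_wide = map(same_label_nn_frac, (thomas, csr, wide))
        assert f_thomas > f_csr + 0.15  # strong same-label excess
        assert abs(f_csr - 0.5) < 0.1
        # parent_sigma -> infinity limit behaves like CSR (excess vanishes)
        assert abs(f_wide - 0.5) < 0.1

    def test_label_position_independence_csr(self):
        # chi-square of label vs spatial quadrant: non-significant at 1% in
        # nearly all seeded runs
        nonsig = 0
        runs = 100
        for s in range(runs):
            pts = simulate_spatial_map(
                SimSpatialConfig(n_points=400, mode="csr", seed=1000 + s)
            )
            qx = (pts["x_um"] > 500).astype(int)
            qy = (pts["y_um"] > 500).astype(int)
            quad = qx * 2 + qy
            table = np.array(
                [[(quad[pts.label == l] == q).sum() for q in range(4)] for l in ("A", "B")]
            )
            _, p, _, _ = chi2_contingency(table)
            nonsig += p > 0.01
        assert nonsig >= 0.98 * runs

    def test_deterministic(self):
        cfg = SimSpatialConfig(n_points=500, mode="thomas", seed=3)
        assert simulate_spatial_map(cfg).equals(simulate_spatial_map(cfg))
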