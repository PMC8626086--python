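import numpy as np
import pytest

from drgsn import (
    SimCountConfig,
    normalize_log_cp10k,
    run_pca,
    select_hvg,
    simulate_counts,
)


@pytest.fixture(scope="session")
def five_cluster_data():
    """Well-separated 5-cluster NB dataset with known labels (no doublets)."""
    cfg = SimCountConfig(
        n_genes=2000, n_cells=1000, n_clusters=5, marker_genes_per_cluster=20,
        marker_fold=8.0, doublet_rate=0.0, seed=7,
    )
    m, labels, doublets = simulate_counts(cfg)
    return cfg, m, labels, doublets


@pytest.fixture(scope="session")
def five_cluster_normalized(five_cluster_data):
    cfg, m, labels, _ = five_cluster_data
    norm = normalize_log_cp10k(m)
    hvg = select_hvg(norm, m.gene_ids, 200)
    emb = run_pca(norm, hvg, 16, cell_ids=m.cell_ids, seed=0)
    return m, norm, hvg, emb, labels


def true_marker_indices(cfg: SimCountConfig) -> dict:
    """Recompute the generator's planted marker assignment (same RNG protocol)."""
    from drgsn.simulate import _marker_assignment

    rng = np.random.default_rng(cfg.seed)
    n_mito = int(round(cfg.mito_gene_frac * cfg.n_genes))
    non_mito = np.arange(cfg.n_genes - n_mito)
    return _marker_assignment(cfg, non_mito, rng)
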