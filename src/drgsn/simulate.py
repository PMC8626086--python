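"""Synthetic data generators.

Two families of generators mirror the statistical structure the downstream
analyses assume:

* negative-binomial, cluster-structured UMI count matrices (optionally for a
  pair of "species" with partially shared marker programs), including
  library-size variation, mitochondrial genes and co-encapsulation doublets;
* labeled 2-D cell maps, either completely spatially random (CSR) or
  aggregated via a Thomas cluster process.

All generators are deterministic given their config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix


def _check_probs(p: Sequence[float], name: str, n: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if len(p) != n:
        raise ValueError(f"{name} must have length {n}")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be non-negative and sum to 1")
    return p


@dataclass
class SimCountConfig:
    """Parameters of the negative-binomial cluster-structured count generator.

    The NB is parameterized by mean and shape theta: var = mu + mu^2/theta.
    Marker genes are disjoint across clusters and elevated ``marker_fold``-fold
    in their cluster.  Mitochondrial gene means are scaled so the expected
    mitochondrial UMI fraction per cell is ``mito_mean_frac``.
    """

    n_genes: int = 2000
    n_cells: int = 1000
    n_clusters: int = 5
    cluster_props: Optional[Sequence[float]] = None
    base_mean: float = 0.5
    marker_genes_per_cluster: int = 20
    marker_fold: float = 8.0
    dispersion: float = 2.0
    libsize_sigma: float = 0.35
    mito_gene_frac: float = 0.01
    mito_mean_frac: float = 0.05
    doublet_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cells, self.n_clusters) < 1:
            raise ValueError("n_genes, n_cells, n_clusters must be positive")
        if self.cluster_props is None:
            self.cluster_props = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.cluster_props = _check_probs(self.cluster_props, "cluster_props", self.n_clusters)
        if self.base_mean < 0 or self.dispersion <= 0 or self.libsize_sigma < 0:
            raise ValueError("base_mean >= 0, dispersion > 0, libsize_sigma >= 0 required")
        if self.marker_genes_per_cluster < 0:
            raise ValueError("marker_genes_per_cluster must be non-negative")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        for name in ("mito_gene_frac", "mito_mean_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must lie in [0, 1)")
        n_mito = int(round(self.mito_gene_frac * self.n_genes))
        if self.marker_genes_per_cluster * self.n_clusters > self.n_genes - n_mito:
            raise ValueError("marker_genes_per_cluster x n_clusters exceeds available genes")


@dataclass
class SimSpatialConfig:
    """Parameters of the labeled point-map generator (CSR or Thomas process)."""

    n_points: int = 800
    labels: Sequence[str] = ("A", "B")
    label_props: Optional[Sequence[float]] = None
    mode: str = "csr"
    n_parents: int = 10
    parent_sigma: float = 50.0
    domain: Tuple[float, float] = (1000.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be positive")
        self.labels = list(self.labels)
        if self.label_props is None:
            self.label_props = np.full(len(self.labels), 1.0 / len(self.labels))
        self.label_props = _check_probs(self.label_props, "label_props", len(self.labels))
        if self.mode not in ("csr", "thomas"):
            raise ValueError("mode must be 'csr' or 'thomas'")
        if self.mode == "thomas":
            if self.n_parents < 1:
                raise ValueError("n_parents must be positive")
            if self.parent_sigma <= 0:
                raise ValueError("parent_sigma must be positive in thomas mode")
        if min(self.domain) <= 0:
            raise ValueError("domain sides must be positive")


def _marker_assignment(cfg: SimCountConfig, non_mito: np.ndarray, rng) -> Dict[int, np.ndarray]:
    """Disjoint marker gene index sets per cluster, drawn from non-mito genes."""
    m = cfg.marker_genes_per_cluster
    chosen = rng.choice(non_mito, size=m * cfg.n_clusters, replace=False)
    return {c: np.sort(chosen[c * m : (c + 1) * m]) for c in range(cfg.n_clusters)}


def _mean_matrix(cfg: SimCountConfig, markers: Dict[int, np.ndarray], mito_idx: np.ndarray) -> np.ndarray:
    """Genes x clusters expected-count matrix before library-size scaling."""
    mu = np.full((cfg.n_genes, cfg.n_clusters), cfg.base_mean)
    for c, idx in markers.items():
        mu[idx, c] *= cfg.marker_fold
    if len(mito_idx) and cfg.mito_mean_frac > 0:
        non_mito = np.setdiff1d(np.arange(cfg.n_genes), mito_idx)
        for c in range(cfg.n_clusters):
            s = mu[non_mito, c].sum()
            total_mito = s * cfg.mito_mean_frac / (1.0 - cfg.mito_mean_frac)
            mu[mito_idx, c] = total_mito / len(mito_idx)
    return mu


def _sample_nb(rng, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mean`` and shape ``theta``."""
    lam = np.where(mean > 0, rng.gamma(theta, np.maximum(mean, 0) / theta), 0.0)
    return rng.poisson(lam)


def simulate_counts(
    config: SimCountConfig,
) -> Tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Simulate a cluster-structured UMI count matrix.

    Returns ``(matrix, true_labels, true_doublet_flags)``.  Doublets are
    formed by adding the counts of a second, independently drawn singlet
    profile (heterotypic with probability 0.75); their recorded label is the
    first parent's cluster.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_mito = int(round(cfg.mito_gene_frac * cfg.n_genes))
    mito_idx = np.arange(cfg.n_genes - n_mito, cfg.n_genes)
    non_mito = np.arange(cfg.n_genes - n_mito)
    markers = (
        _marker_assignment(cfg, non_mito, rng)
        if cfg.marker_genes_per_cluster > 0
        else {c: np.array([], dtype=int) for c in range(cfg.n_clusters)}
    )
    mu = _mean_matrix(cfg, markers, mito_idx)

    labels = rng.choice(cfg.n_clusters, size=cfg.n_cells, p=cfg.cluster_props)
    lib = np.exp(rng.normal(-cfg.libsize_sigma**2 / 2, cfg.libsize_sigma, cfg.n_cells))
    counts = _sample_nb(rng, mu[:, labels] * lib, cfg.dispersion)

    n_doublets = int(round(cfg.doublet_rate * cfg.n_cells))
    doublet = np.zeros(cfg.n_cells, dtype=bool)
    if n_doublets > 0:
        which = rng.choice(cfg.n_cells, size=n_doublets, replace=False)
        doublet[which] = True
        for i in which:
            if cfg.n_clusters > 1 and rng.random() < 0.75:  # heterotypic bias
                other = rng.choice(np.setdiff1d(np.arange(cfg.n_clusters), labels[i]))
            else:
                other = labels[i]
            lib2 = np.exp(rng.normal(-cfg.libsize_sigma**2 / 2, cfg.libsize_sigma))
            counts[:, i] += _sample_nb(rng, mu[:, other] * lib2, cfg.dispersion)

    gene_ids = np.array(
        [f"GENE{i:05d}" for i in range(len(non_mito))] + [f"MT-G{i:03d}" for i in range(n_mito)],
        dtype=object,
    )
    cell_ids = np.array([f"cell{i:05d}" for i in range(cfg.n_cells)], dtype=object)
    mito_mask = np.zeros(cfg.n_genes, dtype=bool)
    mito_mask[mito_idx] = True
    m = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        species="synthetic",
        mito_mask=mito_mask,
    )
    m.obs = pd.DataFrame(
        {"cell_id": cell_ids, "true_cluster": labels, "true_doublet": doublet}
    )
    return m, labels, doublet


def _stem_names(prefix: str, indices: np.ndarray) -> List[str]:
    return [f"{prefix}{i:05d}" for i in indices]


def simulate_two_species(
    config_a: SimCountConfig,
    config_b: SimCountConfig,
    shared_cluster_map: Sequence[Tuple[int, int]],
    divergence_frac: float = 0.2,
) -> Tuple[CountMatrix, CountMatrix, Dict[str, pd.DataFrame]]:
    """Simulate two "species" with partially shared marker programs.

    Paired clusters (``shared_cluster_map`` of (cluster_in_a, cluster_in_b))
    share their marker gene *stems* except a ``divergence_frac`` fraction,
    which is swapped for species-specific markers.  Species A gene names are
    ALL-CAPS, species B title-case with the identical stem, so orthology
    reduces to case-insensitive matching.  Unlisted clusters are
    species-private.

    Returns ``(matrix_a, matrix_b, truth)`` where ``truth`` holds per-cell
    tables for both species and the cluster pairing.
    """
    if not 0 <= divergence_frac <= 1:
        raise ValueError("divergence_frac must lie in [0, 1]")
    pairs = [tuple(p) for p in shared_cluster_map]
    for ca, cb in pairs:
        if not (0 <= ca < config_a.n_clusters and 0 <= cb < config_b.n_clusters):
            raise ValueError(f"shared_cluster_map references missing cluster ({ca}, {cb})")

    m = config_a.marker_genes_per_cluster
    if config_b.marker_genes_per_cluster != m:
        raise ValueError("both configs must use the same marker_genes_per_cluster")
    rng = np.random.default_rng(config_a.seed)

    def build(cfg: SimCountConfig, marker_map: Dict[int, np.ndarray]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        sub_rng = np.random.default_rng(cfg.seed + 1)
        n_mito = int(round(cfg.mito_gene_frac * cfg.n_genes))
        mito_idx = np.arange(cfg.n_genes - n_mito, cfg.n_genes)
        mu = _mean_matrix(cfg, marker_map, mito_idx)
        labels = sub_rng.choice(cfg.n_clusters, size=cfg.n_cells, p=cfg.cluster_props)
        lib = np.exp(sub_rng.normal(-cfg.libsize_sigma**2 / 2, cfg.libsize_sigma, cfg.n_cells))
        counts = _sample_nb(sub_rng, mu[:, labels] * lib, cfg.dispersion)
        return counts, labels, mito_idx

    # shared stem universe: both species carry all non-mito stems; markers are
    # drawn disjointly so that swapped markers exist in both gene lists.
    if config_a.n_genes != config_b.n_genes:
        raise ValueError("two-species simulation expects equal n_genes")
    n_mito = int(round(config_a.mito_gene_frac * config_a.n_genes))
    non_mito = np.arange(config_a.n_genes - n_mito)

    n_div = int(round(divergence_frac * m))
    n_shared = m - n_div
    # stems needed: per pair shared + 2x divergent; per private cluster m
    private_a = [c for c in range(config_a.n_clusters) if c not in {p[0] for p in pairs}]
    private_b = [c for c in range(config_b.n_clusters) if c not in {p[1] for p in pairs}]
    need = len(pairs) * (n_shared + 2 * n_div) + m * (len(private_a) + len(private_b))
    if need > len(non_mito):
        raise ValueError("not enough genes for the requested marker structure")
    pool = rng.choice(non_mito, size=need, replace=False)
    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        out = pool[pos : pos + k]
        pos += k
        return np.sort(out)

    markers_a: Dict[int, np.ndarray] = {}
    markers_b: Dict[int, np.ndarray] = {}
    pairing_rows = []
    for ca, cb in pairs:
        shared = take(n_shared)
        div_a = take(n_div)
        div_b = take(n_div)
        markers_a[ca] = np.sort(np.concatenate([shared, div_a]))
        markers_b[cb] = np.sort(np.concatenate([shared, div_b]))
        pairing_rows.append(
            {"cluster_a": ca, "cluster_b": cb, "n_shared_markers": n_shared, "n_divergent": n_div}
        )
    for c in private_a:
        markers_a[c] = take(m)
    for c in private_b:
        markers_b[c] = take(m)

    counts_a, labels_a, mito_a = build(config_a, markers_a)
    counts_b, labels_b, mito_b = build(config_b, markers_b)

    stems = _stem_names("gene", np.arange(len(non_mito)))
    genes_a = np.array(
        [s.upper() for s in stems] + [f"MT-G{i:03d}" for i in range(len(mito_a))], dtype=object
    )
    genes_b = np.array(
        [s.capitalize() for s in stems] + [f"Mt-g{i:03d}" for i in range(len(mito_b))],
        dtype=object,
    )

    def wrap(counts, genes, mito_idx, species, prefix) -> CountMatrix:
        mask = np.zeros(counts.shape[0], dtype=bool)
        mask[mito_idx] = True
        return CountMatrix(
            counts=sp.csr_matrix(counts),
            gene_ids=genes,
            cell_ids=np.array([f"{prefix}{i:05d}" for i in range(counts.shape[1])], dtype=object),
            species=species,
            mito_mask=mask,
        )

    ma = wrap(counts_a, genes_a, mito_a, "human", "a_cell")
    mb = wrap(counts_b, genes_b, mito_b, "mouse", "b_cell")
    truth = {
        "pairing": pd.DataFrame(pairing_rows),
        "cells_a": pd.DataFrame({"cell_id": ma.cell_ids, "true_cluster": labels_a}),
        "cells_b": pd.DataFrame({"cell_id": mb.cell_ids, "true_cluster": labels_b}),
        "markers_a": pd.DataFrame(
            [(c, genes_a[g]) for c, idx in markers_a.items() for g in idx],
            columns=["cluster", "gene"],
        ),
        "markers_b": pd.DataFrame(
            [(c, genes_b[g]) for c, idx in markers_b.items() for g in idx],
            columns=["cluster", "gene"],
        ),
    }
    return ma, mb, truth


def simulate_spatial_map(config: SimSpatialConfig) -> pd.DataFrame:
    """Simulate a labeled 2-D cell map.

    ``csr`` mode places points uniformly with labels i.i.d. from
    ``label_props`` (labels independent of position).  ``thomas`` mode
    scatters each label's points (Gaussian, sd ``parent_sigma``) around
    label-specific parent points, producing same-label aggregation.

    Returns a DataFrame with columns ``x_um, y_um, label``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.domain
    labels = rng.choice(len(cfg.labels), size=cfg.n_points, p=cfg.label_props)
    if cfg.mode == "csr":
        x = rng.uniform(0, w, cfg.n_points)
        y = rng.uniform(0, h, cfg.n_points)
    else:
        x = np.empty(cfg.n_points)
        y = np.empty(cfg.n_points)
        for li in range(len(cfg.labels)):
            px = rng.uniform(0, w, cfg.n_parents)
            py = rng.uniform(0, h, cfg.n_parents)
            idx = np.flatnonzero(labels == li)
            parent = rng.integers(cfg.n_parents, size=len(idx))
            x[idx] = px[parent] + rng.normal(0, cfg.parent_sigma, len(idx))
            y[idx] = py[parent] + rng.normal(0, cfg.parent_sigma, len(idx))
    return pd.DataFrame(
        {"x_um": x, "y_um": y, "label": np.asarray(cfg.labels, dtype=object)[labels]}
    )
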