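"""End-to-end orchestration: single-species analysis (QC -> cluster ->
triage -> re-cluster -> merge -> markers) and cross-species analysis
(harmonize -> co-embed -> joint cluster -> KL matrix -> heatmap), with a
run manifest recording configuration, versions and output hashes."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    DEFAULT_NEURONAL_PANEL,
    DEFAULT_NONNEURONAL_PANEL,
    cluster_graph,
    merge_indistinct_clusters,
    triage_neuronal,
)
from .containers import ClusterPartition, CountMatrix
from .crossspecies import IntegrationConfig, co_embed, harmonize_genes, joint_cluster_crosstab
from .divergence import DivergenceConfig, kl_matrix, render_heatmap
from .io import write_embedding_csv
from .markers import find_all_markers
from .preprocessing import normalize_log_cp10k, run_pca, select_hvg
from .qc import DoubletScoreConfig, QCConfig, compute_qc_metrics, doublet_score, filter_nuclei

log = logging.getLogger("drgsn")


@dataclass
class ClusterConfig:
    # top quarter of a 2,000-gene panel; raise to the conventional 2,000 for
    # genome-wide (~20-30k gene) matrices
    n_hvg: int = 500
    n_pcs: int = 16
    resolution: float = 2.0
    knn_k: int = 20
    seed: int = 0


@dataclass
class RunConfig:
    """Nested configuration of all pipeline stages; defaults are the human
    analysis settings (QC 500-10,000 genes / <10% mito; 16 PCs; resolution
    2.0; joint space of 30 PCs at resolution 0.5; neighborhoods n = 1-40)."""

    qc: QCConfig = field(default_factory=QCConfig)
    doublets: DoubletScoreConfig = field(default_factory=DoubletScoreConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    divergence: DivergenceConfig = field(default_factory=DivergenceConfig)
    merge_alpha: float = 0.05
    merge_min_pct: float = 0.25
    marker_min_pct: float = 0.25
    marker_min_diff_pct: float = 0.25
    neuronal_panel: tuple = DEFAULT_NEURONAL_PANEL
    nonneuronal_panel: tuple = DEFAULT_NONNEURONAL_PANEL
    triage: bool = True
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    def __init__(self, config: RunConfig, out_dir: Path):
        self.out_dir = Path(out_dir)
        self.data: Dict = {
            "version": __version__,
            "started": datetime.now(timezone.utc).isoformat(),
            "config": json.loads(json.dumps(asdict(config), default=str)),
            "outputs": {},
        }

    def record(self, name: str, path: Path) -> None:
        self.data["outputs"][name] = {
            "path": str(path.relative_to(self.out_dir)),
            "sha256": _sha256(path),
        }

    def write(self) -> Path:
        self.data["finished"] = datetime.now(timezone.utc).isoformat()
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        return path


def _stage(name):
    """Re-raise stage errors tagged with the stage name."""

    class _ctx:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _ctx()


def _cluster_once(m: CountMatrix, cfg: ClusterConfig, stage_seed: int):
    norm = normalize_log_cp10k(m)
    n_hvg = min(cfg.n_hvg, m.n_genes)
    hvg = select_hvg(norm, m.gene_ids, n_hvg)
    n_pcs = min(cfg.n_pcs, len(hvg), m.n_cells - 1)
    emb = run_pca(norm, hvg, n_pcs, cell_ids=m.cell_ids, seed=stage_seed)
    part = cluster_graph(emb, knn_k=min(cfg.knn_k, m.n_cells - 1),
                         resolution=cfg.resolution, seed=stage_seed)
    return norm, emb, part


def run_single_species(
    m: CountMatrix, config: RunConfig = RunConfig(), out_dir: Optional[Path] = None
) -> Dict:
    """QC-filter, cluster, triage non-neuronal clusters, re-cluster the
    retained nuclei, merge indistinct clusters and find markers.

    Returns a dict of in-memory artifacts; when ``out_dir`` is given, also
    writes partition/marker/embedding/QC CSVs and a manifest.
    """
    cfg = config
    log.info(
        "QC thresholds: genes [%d, %d], mito < %.2f",
        cfg.qc.min_genes, cfg.qc.max_genes, cfg.qc.max_mito_frac,
    )
    with _stage("qc"):
        metrics = compute_qc_metrics(m)
        filtered = filter_nuclei(m, metrics, cfg.qc)
        if filtered.n_cells < 2:
            raise ValueError("fewer than 2 nuclei survive QC")
        doublets = doublet_score(filtered, cfg.doublets)

    log.info("clustering: %d PCs, resolution %.2f", cfg.cluster.n_pcs, cfg.cluster.resolution)
    with _stage("cluster_raw"):
        norm, emb, raw_part = _cluster_once(filtered, cfg.cluster, cfg.seed)

    with _stage("triage_neuronal"):
        if cfg.triage:
            calls, keep_mask = triage_neuronal(
                norm, raw_part, filtered.gene_ids,
                cfg.neuronal_panel, cfg.nonneuronal_panel,
            )
            neurons = filtered.subset_cells(keep_mask)
        else:
            calls = None
            keep_mask = np.ones(filtered.n_cells, dtype=bool)
            neurons = filtered
        if neurons.n_cells < 2:
            raise ValueError("fewer than 2 nuclei retained after triage")

    with _stage("recluster"):
        norm2, emb2, part2 = _cluster_once(neurons, cfg.cluster, cfg.seed + 1)

    with _stage("merge"):
        merged = merge_indistinct_clusters(
            norm2, part2, emb2, neurons.gene_ids,
            alpha=cfg.merge_alpha, min_pct=cfg.merge_min_pct,
            min_diff_pct=cfg.merge_min_pct,
        )

    with _stage("markers"):
        markers = find_all_markers(
            norm2, merged.labels, gene_ids=neurons.gene_ids,
            min_pct=cfg.marker_min_pct, min_diff_pct=cfg.marker_min_diff_pct,
        )

    result = {
        "qc_metrics": metrics.assign(
            qc_pass=metrics["cell_id"].isin(filtered.cell_ids)
        ).merge(doublets, on="cell_id", how="left"),
        "triage_calls": calls,
        "matrix": neurons,
        "embedding": emb2,
        "raw_partition": ClusterPartition(part2.labels, stage="raw"),
        "partition": merged,
        "markers": markers,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        man = Manifest(cfg, out_dir)
        result["qc_metrics"].to_csv(out_dir / "qc_metrics.csv", index=False)
        man.record("qc_metrics", out_dir / "qc_metrics.csv")
        pd.DataFrame(
            {"cell_id": neurons.cell_ids, "cluster": merged.labels, "stage": merged.stage}
        ).to_csv(out_dir / "partition.csv", index=False)
        man.record("partition", out_dir / "partition.csv")
        markers.to_csv(out_dir / "markers.csv", index=False)
        man.record("markers", out_dir / "markers.csv")
        write_embedding_csv(emb2, out_dir / "embedding.csv")
        man.record("embedding", out_dir / "embedding.csv")
        result["manifest"] = man.write()
    return result


def run_cross_species(
    a: CountMatrix,
    b: CountMatrix,
    labels_a,
    labels_b,
    config: RunConfig = RunConfig(),
    out_dir: Optional[Path] = None,
) -> Dict:
    """Harmonize genes, co-embed, jointly cluster, cross-tabulate and
    compute the query x reference KL divergence matrix.

    ``labels_a``/``labels_b`` are the original single-species cluster labels
    used both for identity transfer and as the groups between which KL is
    estimated.  Dataset B is subsampled to ``config.integration.subsample_b``
    cells (default: the size of dataset A) before embedding, since a large
    imbalance lets the bigger dataset dominate the joint space.
    """
    cfg = config
    with _stage("harmonize"):
        ha, hb = harmonize_genes(a, b)
    with _stage("subsample"):
        labels_a = np.asarray(labels_a)
        labels_b = np.asarray(labels_b)
        target = cfg.integration.subsample_b or ha.n_cells
        if hb.n_cells > target:
            rng = np.random.default_rng(cfg.seed)
            idx = np.sort(rng.choice(hb.n_cells, size=target, replace=False))
            hb = hb.subset_cells(idx)
            labels_b = labels_b[idx]
            log.info("subsampled dataset B to %d cells", target)
    with _stage("co_embed"):
        emb = co_embed(ha, hb, cfg.integration, labels_a=labels_a, labels_b=labels_b)
    with _stage("joint_cluster"):
        joint = cluster_graph(
            emb, knn_k=min(cfg.cluster.knn_k, emb.coords.shape[0] - 1),
            resolution=cfg.integration.resolution_joint, seed=cfg.seed,
        )
        counts, props = joint_cluster_crosstab(
            joint.labels,
            np.array([f"{s}:{l}" for s, l in zip(emb.meta["species"], emb.meta["orig_label"])]),
        )
    with _stage("kl_matrix"):
        dm = kl_matrix(emb, cfg.divergence)

    result = {
        "embedding": emb,
        "joint_partition": ClusterPartition(joint.labels, stage="joint"),
        "crosstab_counts": counts,
        "crosstab_props": props,
        "divergence": dm,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        man = Manifest(cfg, out_dir)
        write_embedding_csv(emb, out_dir / "joint_embedding.csv")
        man.record("joint_embedding", out_dir / "joint_embedding.csv")
        counts.to_csv(out_dir / "crosstab_counts.csv")
        man.record("crosstab_counts", out_dir / "crosstab_counts.csv")
        fig = render_heatmap(dm, csv_path=out_dir / "ln_kl.csv", fig_path=out_dir / "ln_kl.png")
        import matplotlib.pyplot as plt

        plt.close(fig)
        man.record("ln_kl_csv", out_dir / "ln_kl.csv")
        man.record("ln_kl_png", out_dir / "ln_kl.png")
        result["manifest"] = man.write()
    return result
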