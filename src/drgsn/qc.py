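"""Per-nucleus quality control: detected-gene / mitochondrial-fraction
metrics, threshold filtering, and a simplified artificial-doublet scorer.

The filtering rule retains nuclei with ``min_genes <= n_genes_detected <=
max_genes`` (closed interval) and ``mito_frac < max_mito_frac`` (strict
upper bound); the human preset is (500, 10000, 0.10) and the mouse preset
(400, 12000, 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix

SPECIES_PRESETS = {
    "human": dict(min_genes=500, max_genes=10_000, max_mito_frac=0.10),
    "mouse": dict(min_genes=400, max_genes=12_000, max_mito_frac=0.01),
}


@dataclass
class QCConfig:
    min_genes: int = 500
    max_genes: int = 10_000
    max_mito_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must not exceed max_genes")
        if not 0 <= self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must lie in [0, 1]")

    @classmethod
    def preset(cls, species: str) -> "QCConfig":
        if species not in SPECIES_PRESETS:
            raise KeyError(f"no preset for species {species!r}")
        return cls(**SPECIES_PRESETS[species])


def compute_qc_metrics(m: CountMatrix) -> pd.DataFrame:
    """Per-cell ``n_genes_detected`` (genes with count > 0), ``total_umi``
    and ``mito_frac`` (0 for cells with zero total)."""
    counts = m.counts.tocsc()
    n_genes = counts.getnnz(axis=0)
    total = np.asarray(counts.sum(axis=0)).ravel()
    mito = np.asarray(counts[m.mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "n_genes_detected": n_genes.astype(int),
            "total_umi": total.astype(int),
            "mito_frac": mito_frac,
        }
    )


def qc_pass_mask(metrics: pd.DataFrame, config: QCConfig) -> np.ndarray:
    return (
        (metrics["n_genes_detected"].to_numpy() >= config.min_genes)
        & (metrics["n_genes_detected"].to_numpy() <= config.max_genes)
        & (metrics["mito_frac"].to_numpy() < config.max_mito_frac)
    )


def filter_nuclei(
    m: CountMatrix, metrics: pd.DataFrame, config: QCConfig
) -> CountMatrix:
    """Retain exactly the cells passing the closed gene-count interval and the
    strict mitochondrial bound; gene set and cell order preserved."""
    mask = qc_pass_mask(metrics, config)
    if m.n_cells > 0 and not mask.any():
        warnings.warn("no nuclei survive QC filtering")
    return m.subset_cells(mask)


@dataclass
class DoubletScoreConfig:
    n_artificial: int | None = None  # None => one artificial doublet per real cell
    k_neighbors: int = 30
    n_pcs: int = 10
    expected_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_artificial is not None and self.n_artificial < 1:
            raise ValueError("n_artificial must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if not 0 <= self.expected_rate < 1:
            raise ValueError("expected_rate must lie in [0, 1)")


class KNNDoubletScorer(BaseEstimator):
    """Artificial-doublet nearest-neighbor doublet scoring.

    ``n_artificial`` synthetic doublets are formed by summing random real
    cell pairs; real and artificial profiles are co-embedded by shared
    log-CP10K normalization and PCA, and each real cell is scored by the
    fraction of artificial profiles among its ``k_neighbors`` nearest
    neighbors (self excluded).  The top ``expected_rate`` fraction by score
    is called doublet.  This is a deliberately reduced variant of the
    artificial-nearest-neighbor family of doublet detectors: no pK sweep, no
    homotypic-proportion adjustment — the score is diagnostic.

    Attributes (after :meth:`fit`)
    ------------------------------
    scores_ : ndarray of shape (n_cells,), in [0, 1]
    calls_ : boolean ndarray of shape (n_cells,)
    """

    def __init__(self, n_artificial: int | None = None, k_neighbors: int = 30,
                 n_pcs: int = 10, expected_rate: float = 0.05, seed: int = 0):
        self.n_artificial = n_artificial
        self.k_neighbors = k_neighbors
        self.n_pcs = n_pcs
        self.expected_rate = expected_rate
        self.seed = seed

    def fit(self, X, y=None):
        """``X``: cells x genes count matrix (array or sparse)."""
        from .preprocessing import cp10k_log_normalize_cells, ZScorePCA

        X = sp.csr_matrix(X)
        n = X.shape[0]
        if n < 2:
            raise ValueError("doublet scoring needs at least 2 cells")
        if self.n_artificial is not None and self.n_artificial < 1:
            raise ValueError("n_artificial must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        n_art = self.n_artificial if self.n_artificial is not None else n
        rng = np.random.default_rng(self.seed)
        i = rng.integers(n, size=n_art)
        j = (i + 1 + rng.integers(n - 1, size=n_art)) % n  # j != i
        artificial = X[i] + X[j]
        combined = sp.vstack([X, artificial])
        norm = cp10k_log_normalize_cells(combined)
        n_pcs = min(self.n_pcs, norm.shape[1], combined.shape[0] - 1)
        emb = ZScorePCA(n_pcs=n_pcs, seed=self.seed).fit_transform(
            np.asarray(norm.todense())
        )
        k = min(self.k_neighbors, combined.shape[0] - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
        _, idx = nn.kneighbors(emb[:n])
        idx = np.array([row[row != r][:k] for r, row in enumerate(idx)])
        self.scores_ = (idx >= n).mean(axis=1)
        n_calls = int(np.floor(self.expected_rate * n))
        self.calls_ = np.zeros(n, dtype=bool)
        if n_calls > 0:
            order = np.argsort(-self.scores_, kind="stable")
            self.calls_[order[:n_calls]] = True
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).calls_


def doublet_score(m: CountMatrix, config: DoubletScoreConfig) -> pd.DataFrame:
    """Functional wrapper over :class:`KNNDoubletScorer` for a :class:`CountMatrix`."""
    scorer = KNNDoubletScorer(
        n_artificial=config.n_artificial,
        k_neighbors=config.k_neighbors,
        n_pcs=config.n_pcs,
        expected_rate=config.expected_rate,
        seed=config.seed,
    ).fit(m.counts.T)
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "doublet_score": scorer.scores_,
            "doublet_call": scorer.calls_,
        }
    )
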