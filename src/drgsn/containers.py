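"""Core in-memory containers shared across the pipeline stages.

Counts are stored genes x cells (the CellRanger/Matrix-Market orientation);
estimator classes that follow the scikit-learn convention transpose to
cells x genes internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

VALID_SPECIES = ("human", "mouse", "synthetic")


def _as_str_array(values: Sequence[str], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if len(set(arr)) != len(arr):
        raise ValueError(f"duplicate entries in {name}")
    return arr


@dataclass
class CountMatrix:
    """Sparse UMI count matrix (genes x cells) with identifiers and species tag.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes in rows, cells in columns.
    gene_ids, cell_ids
        Unique string identifiers for rows / columns.
    species
        One of ``"human"``, ``"mouse"`` or ``"synthetic"``.
    mito_mask
        Boolean vector over genes flagging mitochondrial genes.  When omitted
        it is inferred from gene names with the ``MT-``/``mt-`` prefix
        (case-insensitive).
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    species: str = "synthetic"
    mito_mask: Optional[np.ndarray] = None
    obs: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.species not in VALID_SPECIES:
            raise ValueError(f"species must be one of {VALID_SPECIES}")
        if self.mito_mask is None:
            self.mito_mask = infer_mito_mask(self.gene_ids)
        else:
            self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
            if self.mito_mask.shape != (len(self.gene_ids),):
                raise ValueError("mito_mask length must equal number of genes")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        obs = self.obs.iloc[idx].reset_index(drop=True) if self.obs is not None else None
        return replace(
            self,
            counts=self.counts[:, idx],
            cell_ids=self.cell_ids[idx],
            obs=obs,
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            counts=self.counts[idx, :],
            gene_ids=self.gene_ids[idx],
            mito_mask=self.mito_mask[idx],
        )

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells x genes). Optional dependency."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(
                {"mito": self.mito_mask}, index=pd.Index(self.gene_ids, name="gene_id")
            ),
        )
        adata.uns["species"] = self.species
        return adata


def infer_mito_mask(gene_ids: Sequence[str]) -> np.ndarray:
    """Flag genes whose name starts with ``MT-`` (any case) as mitochondrial."""
    return np.array([str(g).upper().startswith("MT-") for g in gene_ids], dtype=bool)


@dataclass
class Embedding:
    """Cells x latent-dimensions coordinates (PC space) with optional metadata.

    ``meta`` carries per-cell columns such as ``species`` and ``orig_label``
    when produced by the cross-species co-embedding.
    """

    coords: np.ndarray
    cell_ids: np.ndarray
    dim_names: Sequence[str] = ()
    source: str = "pca_single"
    meta: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D (cells x dims)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("cell_ids length must match number of rows")
        if not self.dim_names:
            self.dim_names = [f"PC{i + 1}" for i in range(self.coords.shape[1])]
        if len(self.dim_names) != self.coords.shape[1]:
            raise ValueError("dim_names length must match number of dims")
        if self.meta is not None and len(self.meta) != self.coords.shape[0]:
            raise ValueError("meta must have one row per cell")

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, columns=list(self.dim_names))
        df.insert(0, "cell_id", self.cell_ids)
        if self.meta is not None:
            for col in self.meta.columns:
                df.insert(1, col, self.meta[col].to_numpy())
        return df


@dataclass
class ClusterPartition:
    """Per-cell categorical labels plus the pipeline stage that produced them."""

    labels: np.ndarray
    stage: str = "raw"

    STAGES = ("raw", "merged", "neuron_filtered", "joint")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.stage not in self.STAGES:
            raise ValueError(f"stage must be one of {self.STAGES}")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()
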