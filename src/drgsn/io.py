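"""Reading and writing the on-disk formats: Matrix-Market count bundles
(CellRanger v3 layout), embedding CSVs and spatial point CSVs."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, Embedding

PathLike = Union[str, Path]


def write_count_bundle(m: CountMatrix, out_dir: PathLike) -> Path:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` (uncompressed).

    ``features.tsv`` follows the CellRanger v3 column order
    (gene_id, gene_name, feature_type); gene_id and gene_name coincide here.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(m.counts), field="integer")
    feats = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "gene_name": m.gene_ids,
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    return out


def read_count_bundle(
    in_dir: PathLike, species: str = "synthetic", mito_mask: Optional[np.ndarray] = None
) -> CountMatrix:
    """Read a CellRanger-style Matrix-Market bundle into a :class:`CountMatrix`."""
    in_dir = Path(in_dir)
    mtx_path = in_dir / "matrix.mtx"
    if not mtx_path.exists():
        raise FileNotFoundError(f"no matrix.mtx in {in_dir}")
    counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    if counts.nnz and not np.allclose(counts.data, np.round(counts.data)):
        warnings.warn("non-integer values in count matrix; rounding")
    counts.data = np.round(counts.data)
    feats = pd.read_csv(in_dir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", sep="\t", header=None)
    gene_ids = feats.iloc[:, 0].astype(str).to_numpy()
    return CountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=barcodes.iloc[:, 0].astype(str).to_numpy(),
        species=species,
        mito_mask=mito_mask,
    )


def write_embedding_csv(e: Embedding, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    e.to_frame().to_csv(path, index=False)
    return path


def read_embedding_csv(path: PathLike) -> Embedding:
    """Read an embedding CSV (cell_id[, species, orig_label], PC1..PCk).

    Accepts embeddings exported from external tools (e.g. a Seurat
    integration) as long as the coordinate columns are named ``PC*``.
    """
    df = pd.read_csv(path)
    pc_cols = [c for c in df.columns if c.upper().startswith("PC")]
    if not pc_cols:
        raise ValueError(f"no PC columns found in {path}")
    meta_cols = [c for c in df.columns if c not in pc_cols and c != "cell_id"]
    meta = df[meta_cols].reset_index(drop=True) if meta_cols else None
    source = "pca_joint" if meta is not None and "species" in meta.columns else "pca_single"
    return Embedding(
        coords=df[pc_cols].to_numpy(float),
        cell_ids=df["cell_id"].astype(str).to_numpy(),
        dim_names=pc_cols,
        source=source,
        meta=meta,
    )


def write_spatial_csv(points: pd.DataFrame, path: PathLike) -> Path:
    cols = ["x_um", "y_um", "label"] + (
        ["section_id"] if "section_id" in points.columns else []
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    points[cols].to_csv(path, index=False)
    return path


def read_spatial_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("x_um", "y_um", "label"):
        if col not in df.columns:
            raise ValueError(f"spatial CSV missing required column {col!r}")
    return df
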