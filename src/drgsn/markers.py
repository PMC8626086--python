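"""Wilcoxon rank-sum marker detection with detection-fraction prefilters.

Candidate genes must be detected in at least ``min_pct`` of the positive
group and exceed the negative group's detection fraction by at least
``min_diff_pct``; surviving genes are tested two-sided (exact enumeration
for tiny groups, tie-corrected normal otherwise) and Bonferroni-adjusted
over the genes actually tested.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .stats import rank_sum_test_genes

LOGFC_PSEUDOCOUNT = 1e-9


def find_markers(
    normalized: sp.spmatrix,
    labels: Union[np.ndarray, Sequence],
    cluster_a,
    cluster_b=None,
    gene_ids: Optional[Sequence[str]] = None,
    min_pct: float = 0.1,
    min_diff_pct: float = 0.0,
) -> pd.DataFrame:
    """Differential markers of ``cluster_a`` versus ``cluster_b`` (or the rest).

    ``normalized`` is genes x cells log-CP10K expression.  Returns a table
    with columns gene, cluster, log_fold_change (natural log of expm1-mean
    ratio with pseudocount), pct_in, pct_out, p_value, adjusted_p — sorted
    by adjusted p then gene.
    """
    norm = sp.csr_matrix(normalized)
    labels = np.asarray(labels)
    in_mask = labels == cluster_a
    out_mask = ~in_mask if cluster_b is None else labels == cluster_b
    if not in_mask.any():
        raise ValueError(f"cluster {cluster_a!r} is empty")
    if not out_mask.any():
        raise ValueError("comparison group is empty")
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(norm.shape[0])], dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)

    n_in, n_out = int(in_mask.sum()), int(out_mask.sum())
    pct_in = norm[:, in_mask].getnnz(axis=1) / n_in
    pct_out = norm[:, out_mask].getnnz(axis=1) / n_out
    cand = np.flatnonzero((pct_in >= min_pct) & ((pct_in - pct_out) >= min_diff_pct))
    if len(cand) == 0:
        return pd.DataFrame(
            columns=[
                "gene", "cluster", "log_fold_change", "pct_in", "pct_out",
                "p_value", "adjusted_p",
            ]
        )

    cells = np.flatnonzero(in_mask | out_mask)
    sub = np.asarray(norm[cand][:, cells].todense())
    grp = in_mask[cells]
    p = rank_sum_test_genes(sub, grp)
    adj = np.minimum(1.0, p * len(cand))

    mean_in = np.expm1(sub[:, grp]).mean(axis=1)
    mean_out = np.expm1(sub[:, ~grp]).mean(axis=1)
    lfc = np.log((mean_in + LOGFC_PSEUDOCOUNT) / (mean_out + LOGFC_PSEUDOCOUNT))

    table = pd.DataFrame(
        {
            "gene": gene_ids[cand],
            "cluster": cluster_a,
            "log_fold_change": lfc,
            "pct_in": pct_in[cand],
            "pct_out": pct_out[cand],
            "p_value": p,
            "adjusted_p": adj,
        }
    )
    return table.sort_values(["adjusted_p", "gene"]).reset_index(drop=True)


def find_all_markers(
    normalized: sp.spmatrix,
    labels,
    gene_ids: Optional[Sequence[str]] = None,
    min_pct: float = 0.1,
    min_diff_pct: float = 0.0,
) -> pd.DataFrame:
    """Markers of every cluster against the rest, concatenated."""
    labels = np.asarray(labels)
    tables = [
        find_markers(
            normalized, labels, c, None, gene_ids=gene_ids,
            min_pct=min_pct, min_diff_pct=min_diff_pct,
        )
        for c in np.unique(labels)
    ]
    return pd.concat(tables, ignore_index=True)
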