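"""Normalization, highly-variable-gene selection, and PCA embedding.

Normalization is log-CP10K, ``ln(1 + 1e4 * count / cell_total)`` — a simple,
explicit variance-stabilization surrogate.  PCA is run on per-gene z-scored
(clipped at +/-10) values of the selected genes, with a deterministic sign
convention so embeddings are reproducible bit-for-bit at a fixed seed.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .containers import CountMatrix, Embedding


def cp10k_log_normalize_cells(X: sp.spmatrix) -> sp.csr_matrix:
    """Log-CP10K normalize a cells x genes sparse matrix.

    Cells with zero total are passed through as all-zero rows.
    """
    X = sp.csr_matrix(X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.where(totals > 0, 1e4 / np.maximum(totals, 1e-300), 0.0)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return X


class CP10KLogNormalizer(TransformerMixin, BaseEstimator):
    """Stateless log-CP10K transformer (cells x genes, sklearn orientation)."""

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return cp10k_log_normalize_cells(X)


def normalize_log_cp10k(m: CountMatrix) -> sp.csr_matrix:
    """Log-CP10K normalized expression of a :class:`CountMatrix`, genes x cells."""
    return cp10k_log_normalize_cells(m.counts.T).T.tocsr()


def _mean_var(X: sp.spmatrix, axis: int):
    """Mean and (population) variance of a sparse matrix along ``axis``."""
    X = sp.csr_matrix(X)
    n = X.shape[axis]
    mean = np.asarray(X.mean(axis=axis)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=axis)).ravel()
    var = np.maximum(ex2 - mean**2, 0.0)
    return mean, var, n


class HighlyVariableGenes(SelectorMixin, BaseEstimator):
    """Dispersion-based highly-variable-gene selector (cells x genes input).

    Expects log-CP10K input.  The dispersion (variance / mean) is computed
    on the back-transformed (expm1, i.e. CP10K) values — the log scale
    compresses exactly the bimodality that makes a marker variable — and the
    top ``n_top`` genes by dispersion are kept.  With ``n_bins > 1`` the
    dispersion is first z-scored within equal-width mean bins (the classic
    trend correction for data whose technical variance grows with the mean);
    the default is a single global bin, which is the right choice when the
    mean-variance relationship is homogeneous, as it is for NB counts with a
    shared dispersion.  Ties break lexicographically by gene name when names
    are supplied to :meth:`fit`, else by column index.
    """

    def __init__(self, n_top: int = 2000, n_bins: int = 1):
        self.n_top = n_top
        self.n_bins = n_bins

    def fit(self, X, y=None, gene_names=None):
        n_genes = X.shape[1]
        if self.n_top > n_genes:
            raise ValueError("n_top exceeds number of genes")
        cp10k = sp.csr_matrix(X, dtype=float).copy()
        cp10k.data = np.expm1(cp10k.data)
        mean, var, _ = _mean_var(cp10k, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

        # z-score dispersions within equal-width mean bins; sparsely populated
        # bins are folded into the nearest well-populated bin so a handful of
        # high-mean genes is normalized against the bulk trend, not itself
        edges = np.linspace(mean.min(), mean.max(), min(self.n_bins, n_genes) + 1)
        bin_of = np.clip(np.digitize(mean, edges[1:-1]), 0, len(edges) - 2)
        min_pop = max(2, min(30, n_genes // 4))
        pops = np.bincount(bin_of, minlength=len(edges) - 1)
        good = np.flatnonzero(pops >= min_pop)
        if len(good):
            for bi in np.flatnonzero((pops > 0) & (pops < min_pop)):
                bin_of[bin_of == bi] = good[np.abs(good - bi).argmin()]
        norm_disp = np.zeros(n_genes)
        for bi in np.unique(bin_of):
            b = np.flatnonzero(bin_of == bi)
            mu, sd = disp[b].mean(), disp[b].std()
            norm_disp[b] = (disp[b] - mu) / (sd if sd > 0 else 1.0)

        names = (
            np.asarray(gene_names, dtype=object)
            if gene_names is not None
            else np.array([f"{i:09d}" for i in range(n_genes)], dtype=object)
        )
        rank = np.lexsort((names, -norm_disp))  # descending dispersion, lexical ties
        self.dispersions_ = disp
        self.dispersions_norm_ = norm_disp
        self.support_ = np.zeros(n_genes, dtype=bool)
        self.support_[rank[: self.n_top]] = True
        self.n_features_in_ = n_genes
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def select_hvg(normalized: sp.spmatrix, gene_ids, n_hvg: int) -> np.ndarray:
    """Indices (sorted) of the top ``n_hvg`` genes by binned dispersion.

    ``normalized`` is genes x cells (pipeline orientation).
    """
    sel = HighlyVariableGenes(n_top=n_hvg).fit(
        sp.csr_matrix(normalized).T, gene_names=gene_ids
    )
    return np.flatnonzero(sel.support_)


class ZScorePCA(TransformerMixin, BaseEstimator):
    """Per-feature z-scoring (clipped at +/-10) followed by PCA.

    Components carry a deterministic sign: the largest-magnitude loading of
    each component is made positive.  Constant features are left at zero
    after centering.
    """

    def __init__(self, n_pcs: int = 16, clip: float = 10.0, seed: int = 0):
        self.n_pcs = n_pcs
        self.clip = clip
        self.seed = seed

    def _scale(self, X):
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return np.clip(Z, -self.clip, self.clip)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        if self.n_pcs > min(n, d):
            raise ValueError(f"n_pcs={self.n_pcs} exceeds rank bound min{n, d}")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = self._scale(X)
        pca = PCA(n_components=self.n_pcs, svd_solver="full", random_state=self.seed)
        scores = pca.fit_transform(Z)
        flip = np.sign(
            pca.components_[
                np.arange(self.n_pcs), np.argmax(np.abs(pca.components_), axis=1)
            ]
        )
        flip[flip == 0] = 1.0
        self.components_ = pca.components_ * flip[:, None]
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self._pca_mean_ = pca.mean_
        self.n_features_in_ = d
        self._train_scores_ = scores * flip[None, :]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        Z = self._scale(X)
        return (Z - self._pca_mean_) @ self.components_.T

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self._train_scores_


def run_pca(
    normalized: sp.spmatrix,
    gene_idx,
    n_pcs: int,
    cell_ids=None,
    seed: int = 0,
    source: str = "pca_single",
) -> Embedding:
    """PCA embedding of selected genes of a genes x cells normalized matrix."""
    sub = sp.csr_matrix(normalized)[np.asarray(gene_idx), :]
    X = np.asarray(sub.T.todense())
    scores = ZScorePCA(n_pcs=n_pcs, seed=seed).fit_transform(X)
    if cell_ids is None:
        cell_ids = np.array([f"cell{i:05d}" for i in range(X.shape[0])], dtype=object)
    emb = Embedding(coords=scores, cell_ids=np.asarray(cell_ids, dtype=object), source=source)
    return emb
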