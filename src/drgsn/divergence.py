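"""Sample-based k-NN Kullback-Leibler divergence between cell clusters.

For samples ``P = {x_1..x_n}`` and ``Q = {y_1..y_m}`` in d dimensions the
divergence D(P||Q) is estimated from nearest-neighbor distance ratios:

    D_hat = (d / n) * sum_i ln( nu_k(x_i) / rho_k(x_i) ) + ln( m / (n - 1) )

where ``rho_k`` is the distance from ``x_i`` to its k-th nearest neighbor
within P (self excluded) and ``nu_k`` the distance to its k-th nearest
neighbor in Q.  The estimate is asymptotically unbiased but may be negative
at finite samples; the natural log reported for heatmaps clamps at a small
epsilon while the raw estimate is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import Embedding

ZERO_DIST_FACTOR = 1e-12


@dataclass
class DivergenceConfig:
    k: int = 1
    min_cells: int = 5
    epsilon_clamp: float = 1e-6
    dims: int = 30

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        if self.epsilon_clamp <= 0:
            raise ValueError("epsilon_clamp must be positive")
        if self.dims < 1:
            raise ValueError("dims must be >= 1")


def _regularize_zeros(rho: np.ndarray, nu: np.ndarray):
    """Replace zero distances (duplicate points) by a tiny positive value,
    a common epsilon derived from the smallest positive distance seen."""
    pool = np.concatenate([rho.ravel(), nu.ravel()])
    positive = pool[pool > 0]
    if positive.size == 0:
        return rho, nu  # fully degenerate; ratios become 1 downstream
    eps = positive.min() * ZERO_DIST_FACTOR
    rho, nu = rho.copy(), nu.copy()
    rho[rho == 0] = eps
    nu[nu == 0] = eps
    return rho, nu


def kl_knn(p_sample: np.ndarray, q_sample: np.ndarray, k: int = 1) -> float:
    """k-NN estimate of KL divergence D(P||Q) from two point samples."""
    P = np.atleast_2d(np.asarray(p_sample, dtype=float))
    Q = np.atleast_2d(np.asarray(q_sample, dtype=float))
    if P.shape[1] != Q.shape[1]:
        raise ValueError("dimension mismatch between samples")
    n, d = P.shape
    m = Q.shape[0]
    if n <= k:
        raise ValueError(f"need n > k (n={n}, k={k})")
    if m < k:
        raise ValueError(f"need m >= k (m={m}, k={k})")

    rho = cKDTree(P).query(P, k=k + 1)[0][:, k]  # k-th NN excluding self
    nu = cKDTree(Q).query(P, k=k)[0]
    nu = nu[:, k - 1] if nu.ndim == 2 else nu
    rho, nu = _regularize_zeros(rho, nu)
    return float(d / n * np.sum(np.log(nu / rho)) + np.log(m / (n - 1)))


@dataclass
class DivergenceMatrix:
    """Query-cluster x reference-cluster KL estimates and their natural logs.

    ``kl`` holds the raw (possibly negative) estimates; ``ln_kl`` holds
    ``ln(max(kl, epsilon_clamp))``.  Clusters with fewer than ``min_cells``
    cells are listed in ``missing`` rather than reported as zero.
    """

    kl: pd.DataFrame
    ln_kl: pd.DataFrame
    n_p: pd.Series
    m_q: pd.Series
    missing: List[Tuple[str, object]] = field(default_factory=list)


def kl_matrix(e: Embedding, config: DivergenceConfig = DivergenceConfig()) -> DivergenceMatrix:
    """KL divergence of every query (first-species) cluster against every
    reference (second-species) cluster in the first ``config.dims`` embedding
    dimensions.

    The query species is the first species appearing in the embedding
    metadata (rows of the matrix); the other species provides the reference
    distributions (columns).
    """
    if e.meta is None or "species" not in e.meta or "orig_label" not in e.meta:
        raise ValueError("embedding must carry species and orig_label metadata")
    species = e.meta["species"].to_numpy()
    labels = e.meta["orig_label"].to_numpy()
    uniq_species = list(dict.fromkeys(species))
    if len(uniq_species) != 2:
        raise ValueError(f"expected exactly 2 species, got {uniq_species}")
    sp_q, sp_r = uniq_species
    dims = min(config.dims, e.coords.shape[1])
    coords = e.coords[:, :dims]

    def cluster_points(sp_name):
        mask = species == sp_name
        out, missing = {}, []
        for lab in np.unique(labels[mask]):
            pts = coords[mask & (labels == lab)]
            if pts.shape[0] >= config.min_cells:
                out[lab] = pts
            else:
                missing.append((sp_name, lab))
        if not out:
            raise ValueError(f"species {sp_name!r} has no clusters with >= min_cells cells")
        return out, missing

    qclusters, miss_q = cluster_points(sp_q)
    rclusters, miss_r = cluster_points(sp_r)

    kl = pd.DataFrame(index=list(qclusters), columns=list(rclusters), dtype=float)
    for ql, qpts in qclusters.items():
        for rl, rpts in rclusters.items():
            kl.loc[ql, rl] = kl_knn(qpts, rpts, k=config.k)
    ln_kl = np.log(kl.clip(lower=config.epsilon_clamp).astype(float))
    return DivergenceMatrix(
        kl=kl,
        ln_kl=ln_kl,
        n_p=pd.Series({l: len(p) for l, p in qclusters.items()}),
        m_q=pd.Series({l: len(p) for l, p in rclusters.items()}),
        missing=miss_q + miss_r,
    )


def render_heatmap(
    dm: DivergenceMatrix,
    csv_path: Optional[Path] = None,
    fig_path: Optional[Path] = None,
):
    """ln-KL heatmap figure plus CSV; row/column order preserved."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if csv_path is not None:
        Path(csv_path).parent.mkdir(parents=True, exist_ok=True)
        dm.ln_kl.to_csv(csv_path, float_format="%.12g")

    fig, ax = plt.subplots(
        figsize=(1.0 + 0.5 * dm.ln_kl.shape[1], 1.0 + 0.5 * dm.ln_kl.shape[0])
    )
    im = ax.imshow(dm.ln_kl.to_numpy(float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(dm.ln_kl.shape[1]), [str(c) for c in dm.ln_kl.columns], rotation=90)
    ax.set_yticks(range(dm.ln_kl.shape[0]), [str(r) for r in dm.ln_kl.index])
    ax.set_xlabel("reference cluster")
    ax.set_ylabel("query cluster")
    fig.colorbar(im, ax=ax, label="ln KL divergence")
    fig.tight_layout()
    if fig_path is not None:
        Path(fig_path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(fig_path, dpi=150)
    return fig


def read_ln_kl_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
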