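"""Mann-Whitney / Wilcoxon rank-sum machinery.

A single core serves both marker detection (two-sided) and the spatial
neighborhood comparison (one-tailed).  Small problems are solved by exact
enumeration over all group assignments of the pooled observations, which is
correct in the presence of ties; larger problems use the tie-corrected
normal approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np
from scipy.special import erfc as erfc_vec
from scipy.stats import rankdata

# exact path whenever the full enumeration is cheap; covers every case the
# approximation is questionable for (both groups <= 8 => <= C(16,8)=12870 splits)
EXACT_MAX_TOTAL = 16


@dataclass
class RankSumResult:
    u: float  # U statistic of the first sample
    p: float
    method: str  # "exact" or "asymptotic"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{x_i > y_j} + 0.5 #{x_i = y_j} via midranks."""
    n1, n2 = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_p(pooled: np.ndarray, n1: int, u_obs: float, alternative: str) -> float:
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0
    total = comb(n, n1)
    idx = np.arange(n)
    count = 0
    for first in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(first)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if alternative == "greater":
            hit = u >= u_obs - 1e-12
        elif alternative == "less":
            hit = u <= u_obs + 1e-12
        else:  # two-sided
            hit = abs(u - mu) >= abs(u_obs - mu) - 1e-12
        count += hit
    return count / total


def _asymptotic_p(
    x: np.ndarray, y: np.ndarray, u: float, alternative: str, continuity: bool = True
) -> float:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations tied
        return 1.0
    sd = sqrt(var)
    cc = 0.5 if continuity else 0.0
    if alternative == "greater":
        z = (u - mu - cc) / sd
        return erfc(z / sqrt(2)) / 2.0
    if alternative == "less":
        z = (u - mu + cc) / sd
        return erfc(-z / sqrt(2)) / 2.0
    z = (abs(u - mu) - cc) / sd
    return min(1.0, erfc(max(z, 0.0) / sqrt(2)))


def rank_sum_test(x, y, alternative: str = "two-sided") -> RankSumResult:
    """Mann-Whitney U test of ``x`` against ``y``.

    ``alternative='greater'`` tests whether values in ``x`` tend to exceed
    those in ``y``.  For both groups of size <= 8 the p-value is computed by
    exact enumeration of all :math:`\\binom{n_1+n_2}{n_1}` assignments (valid
    under ties); otherwise the tie-corrected normal approximation with
    continuity correction is used.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if len(x) + len(y) <= EXACT_MAX_TOTAL:
        p = _exact_p(np.concatenate([x, y]), len(x), u, alternative)
        return RankSumResult(u=u, p=p, method="exact")
    return RankSumResult(u=u, p=_asymptotic_p(x, y, u, alternative), method="asymptotic")


def rank_sum_test_genes(
    values: np.ndarray, in_group: np.ndarray, alternative: str = "two-sided"
) -> np.ndarray:
    """Vectorized rank-sum p-values, one per row of ``values``.

    ``values`` is genes x cells; ``in_group`` a boolean cell mask defining the
    first sample.  Rows are routed through the same exact/asymptotic rule as
    :func:`rank_sum_test` (group sizes are shared across rows, so the route is
    common; the asymptotic branch is computed without a Python-level loop).
    """
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    n1 = int(in_group.sum())
    n2 = int((~in_group).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 + n2 <= EXACT_MAX_TOTAL:
        return np.array(
            [
                rank_sum_test(row[in_group], row[~in_group], alternative).p
                for row in values
            ]
        )

    n = n1 + n2
    ranks = rankdata(values, axis=1)
    r1 = ranks[:, in_group].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    # per-row tie correction: sum over tie groups of (t^3 - t)
    srt = np.sort(values, axis=1)
    new_grp = np.ones_like(srt, dtype=bool)
    new_grp[:, 1:] = srt[:, 1:] != srt[:, :-1]
    tie_term = np.empty(values.shape[0])
    for i in range(values.shape[0]):  # cheap: O(n_genes * n_cells)
        t = np.diff(np.append(np.flatnonzero(new_grp[i]), n))
        tie_term[i] = (t**3 - t).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    p = np.ones(values.shape[0])
    ok = var > 0
    sd = np.sqrt(var[ok])
    if alternative == "greater":
        z = (u[ok] - mu - 0.5) / sd
        p[ok] = 0.5 * erfc_vec(z / sqrt(2))
    elif alternative == "less":
        z = (u[ok] - mu + 0.5) / sd
        p[ok] = 0.5 * erfc_vec(-z / sqrt(2))
    else:
        z = np.maximum(np.abs(u[ok] - mu) - 0.5, 0.0) / sd
        p[ok] = np.minimum(1.0, erfc_vec(z / sqrt(2)))
    return p
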