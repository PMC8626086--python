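"""Neighborhood-composition analysis of labeled cell centroids.

For every annotated single-positive cell the n nearest other annotated
cells (Euclidean, self excluded, ties by point index, never across
sections) are found for n in a configured range, and the proportion of
each label among them recorded.  Curves (mean +/- SEM over centers) are
compared against the random-mixing expectation, and same-label enrichment
is tested per n with a one-tailed Mann-Whitney U test; the summary across
the range is the maximum p.  A label-permutation null over fixed
coordinates is provided as a nonparametric complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .stats import rank_sum_test


@dataclass
class SpatialConfig:
    n_min: int = 1
    n_max: int = 40
    alternative: str = "greater"

    def __post_init__(self) -> None:
        if not 1 <= self.n_min <= self.n_max:
            raise ValueError("need 1 <= n_min <= n_max")
        if self.alternative not in ("greater", "less"):
            raise ValueError("alternative must be 'greater' or 'less'")


@dataclass
class NeighborhoodCurve:
    """Per-(center label, target label, n) summary plus per-center raw data.

    ``summary`` columns: center_label, target_label, n, mean, sem, expected.
    ``raw[(center_label, target_label)]`` is a centers x n-range matrix of
    per-center proportions.  ``center_labels`` records the label of each
    pooled center row.
    """

    summary: pd.DataFrame
    raw: Dict[Tuple[str, str], np.ndarray]
    n_range: np.ndarray
    expected: pd.DataFrame
    labels: Tuple[str, ...] = field(default_factory=tuple)


def _check_points(s: pd.DataFrame) -> pd.DataFrame:
    for col in ("x_um", "y_um", "label"):
        if col not in s.columns:
            raise ValueError(f"point set missing column {col!r}")
    if not np.all(np.isfinite(s[["x_um", "y_um"]].to_numpy(float))):
        raise ValueError("coordinates must be finite")
    if "section_id" not in s.columns:
        s = s.assign(section_id=0)
    return s


def _neighbor_matrix(xy: np.ndarray, n_max: int) -> np.ndarray:
    """Index matrix of the n_max nearest neighbors per point (self excluded,
    ties broken by point index)."""
    n = xy.shape[0]
    if n <= n_max:
        raise ValueError(f"section has {n} points; need > n_max={n_max}")
    k = min(n_max + 2, n)
    dist, idx = NearestNeighbors(n_neighbors=k).fit(xy).kneighbors(xy)
    out = np.empty((n, n_max), dtype=int)
    for r in range(n):
        order = np.lexsort((idx[r], np.round(dist[r], 9)))
        row = idx[r][order]
        row = row[row != r]
        out[r] = row[:n_max]
    return out


def neighborhood_composition(
    s: pd.DataFrame, config: SpatialConfig = SpatialConfig()
) -> NeighborhoodCurve:
    """Label composition of the n nearest neighbors around every center.

    Neighborhoods are computed within section; centers are pooled across
    sections.  Every point acts both as a center and as a potential
    neighbor (the neighbor universe is the annotated single-positive cells).
    """
    s = _check_points(s.reset_index(drop=True))
    labels_all = sorted(s["label"].astype(str).unique())
    n_range = np.arange(config.n_min, config.n_max + 1)

    center_labels = []
    # neighbor labels per center, per rank 1..n_max, pooled across sections
    neigh_labels = []
    for _, sec in s.groupby("section_id", sort=True):
        xy = sec[["x_um", "y_um"]].to_numpy(float)
        lab = sec["label"].astype(str).to_numpy()
        nm = _neighbor_matrix(xy, config.n_max)
        center_labels.append(lab)
        neigh_labels.append(lab[nm])
    center_labels = np.concatenate(center_labels)
    neigh_labels = np.concatenate(neigh_labels, axis=0)

    raw: Dict[Tuple[str, str], np.ndarray] = {}
    rows = []
    expected = expected_random_proportion(s)
    exp_lut = {
        (r.center_label, r.target_label): r.expected for r in expected.itertuples()
    }
    for target in labels_all:
        hits = (neigh_labels == target).astype(float)
        cum = np.cumsum(hits, axis=1)
        props_all_n = cum[:, n_range - 1] / n_range  # centers x n-range
        for center in labels_all:
            mask = center_labels == center
            block = props_all_n[mask]
            raw[(center, target)] = block
            mean = block.mean(axis=0)
            sem = (
                block.std(axis=0, ddof=1) / np.sqrt(block.shape[0])
                if block.shape[0] > 1
                else np.zeros(len(n_range))
            )
            for i, n in enumerate(n_range):
                rows.append(
                    {
                        "center_label": center,
                        "target_label": target,
                        "n": int(n),
                        "mean": mean[i],
                        "sem": sem[i],
                        "expected": exp_lut[(center, target)],
                    }
                )
    return NeighborhoodCurve(
        summary=pd.DataFrame(rows),
        raw=raw,
        n_range=n_range,
        expected=expected,
        labels=tuple(labels_all),
    )


def expected_random_proportion(s: pd.DataFrame) -> pd.DataFrame:
    """Random-mixing expectation of target-label proportions.

    For a center of label c in a section of N annotated cells of which
    ``n_t`` carry target label t, the expected proportion of t among any
    neighborhood is ``(n_t - [c == t]) / (N - 1)`` — independent of the
    coordinates.  Values are averaged over centers (pooled across
    sections); returned per (center_label, target_label) pair plus a pooled
    ``center_label='any'`` row per target.
    """
    s = _check_points(s.reset_index(drop=True))
    labels_all = sorted(s["label"].astype(str).unique())
    acc: Dict[Tuple[str, str], list] = {}
    pooled: Dict[str, list] = {t: [] for t in labels_all}
    for _, sec in s.groupby("section_id", sort=True):
        lab = sec["label"].astype(str).to_numpy()
        N = len(lab)
        counts = {t: int((lab == t).sum()) for t in labels_all}
        for c in labels_all:
            n_c = counts[c]
            if n_c == 0:
                continue
            for t in labels_all:
                e = (counts[t] - (1 if c == t else 0)) / (N - 1) if N > 1 else 0.0
                acc.setdefault((c, t), []).extend([e] * n_c)
                pooled[t].extend([e] * n_c)
    rows = [
        {"center_label": c, "target_label": t, "expected": float(np.mean(v))}
        for (c, t), v in sorted(acc.items())
    ]
    rows += [
        {"center_label": "any", "target_label": t, "expected": float(np.mean(v))}
        for t, v in pooled.items()
    ]
    return pd.DataFrame(rows)


def clustering_test(
    curve: NeighborhoodCurve, config: SpatialConfig = SpatialConfig()
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-n one-tailed Mann-Whitney U comparison of neighborhoods.

    For each target label t, the per-center proportions of t around
    t-labeled centers are compared with those around the other label's
    centers (alternative: greater around same-label centers).  Requires a
    two-label analysis.  Returns the per-n table (target_label, n, U, p) and
    the max-p summary per target label.
    """
    if len(curve.labels) != 2:
        raise ValueError("clustering_test requires exactly two labels")
    a, b = curve.labels
    rows = []
    summary: Dict[str, float] = {}
    for target, other in ((a, b), (b, a)):
        same = curve.raw[(target, target)]
        cross = curve.raw[(other, target)]
        if same.shape[0] == 0 or cross.shape[0] == 0:
            raise ValueError(f"empty center group for label {target!r}")
        pmax = 0.0
        for i, n in enumerate(curve.n_range):
            res = rank_sum_test(same[:, i], cross[:, i], alternative=config.alternative)
            rows.append(
                {"target_label": target, "n": int(n), "U": res.u, "p": res.p,
                 "method": res.method}
            )
            pmax = max(pmax, res.p)
        summary[target] = pmax
    return pd.DataFrame(rows), summary


def permutation_null(
    s: pd.DataFrame,
    config: SpatialConfig = SpatialConfig(),
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Label-permutation null for same-label neighborhood enrichment.

    Labels are permuted over the fixed coordinates (within section);
    the observed mean same-label proportion at each n is compared to its
    permutation distribution: one-sided
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    s = _check_points(s.reset_index(drop=True))
    rng = np.random.default_rng(seed)
    n_range = np.arange(config.n_min, config.n_max + 1)

    sections = []
    for _, sec in s.groupby("section_id", sort=True):
        xy = sec[["x_um", "y_um"]].to_numpy(float)
        lab = sec["label"].astype(str).to_numpy()
        sections.append((lab, _neighbor_matrix(xy, config.n_max)))

    def same_label_stat(labels_per_sec):
        num = np.zeros(len(n_range))
        n_centers = 0
        for lab, nm in labels_per_sec:
            same = (lab[nm] == lab[:, None]).astype(float)
            cum = np.cumsum(same, axis=1)[:, n_range - 1] / n_range
            num += cum.sum(axis=0)
            n_centers += len(lab)
        return num / n_centers

    obs = same_label_stat(sections)
    exceed = np.zeros(len(n_range))
    for _ in range(n_perm):
        perm = [(rng.permutation(lab), nm) for lab, nm in sections]
        exceed += same_label_stat(perm) >= obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({"n": n_range.astype(int), "observed": obs, "p": p})
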