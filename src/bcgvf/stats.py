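"""Feature relevance testing and redundancy-driven selection.

Relevance: per-feature two-sided Mann-Whitney U tests for the three class
contrasts (VF-SR, VF-MA, SR-MA), adjusted per contrast with the
Benjamini-Yekutieli step-up procedure (valid under arbitrary dependence;
adjusted values are deliberately not clipped at 1).

Redundancy: Pearson correlation between z-scored features, distance
``d = sqrt(2 (1 - r))``, average-linkage hierarchical clustering.

Selection: either the published 13-feature subset, or a data-driven rerun
of testing + clustering on a supplied feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

CONTRASTS = (("VF", "SR"), ("VF", "MA"), ("SR", "MA"))

#: 1-based indices of the published selected feature subset.
PAPER_SELECTED = (1, 2, 3, 4, 7, 10, 11, 14, 16, 17, 19, 21, 22)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact distribution for small tie-free samples (m + n <= 20), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not ties) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def by_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values, in input order.

    ``q_(i) = m c(m) p_(i) / i`` with ``c(m) = sum_{k=1..m} 1/k`` on the
    ascending order statistics, followed by the step-down cumulative
    minimum from the largest rank; not clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    q = m * c_m * p[order] / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(q[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted


def relevance_table(X: np.ndarray, labels: np.ndarray, fdr_adjust: bool = True) -> pd.DataFrame:
    """Per-feature raw and BY-adjusted p-values for each class contrast.

    Returns a DataFrame indexed by feature name with columns like
    ``VF-SR_p`` and ``VF-SR_adj``; BY is applied column-wise (one family
    of m = n_features tests per contrast).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    names = list(FEATURE_NAMES) if X.shape[1] == len(FEATURE_NAMES) else [
        f"f{j + 1:02d}" for j in range(X.shape[1])
    ]
    out = pd.DataFrame(index=names)
    for ca, cb in CONTRASTS:
        key = f"{ca}-{cb}"
        raw = np.array(
            [mann_whitney(X[labels == ca, j], X[labels == cb, j]) for j in range(X.shape[1])]
        )
        out[f"{key}_p"] = raw
        if fdr_adjust:
            out[f"{key}_adj"] = by_adjust(raw)
    return out


@dataclass
class ClusterResult:
    correlation: np.ndarray  # (m, m) Pearson matrix
    linkage_tree: np.ndarray  # scipy linkage matrix
    cluster_labels: np.ndarray  # flat labels at the cut height
    cut_height: float


def feature_correlation(X: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of z-scored feature columns.

    Zero-variance columns get correlation 0 with everything (diagonal 1)
    and are logged.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    sd = X.std(axis=0)
    dead = sd == 0
    if np.any(dead):
        logger.warning("zero-variance feature columns: %s", np.nonzero(dead)[0].tolist())
    Z = (X - X.mean(axis=0)) / np.where(dead, 1.0, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(Z, rowvar=False)
    R[dead, :] = 0.0
    R[:, dead] = 0.0
    np.fill_diagonal(R, 1.0)
    return R


def cluster_features(
    R: np.ndarray, cut_height: float = 1.0, distance: str = "sqrt2"
) -> ClusterResult:
    """Average-linkage hierarchical clustering of features.

    Distance ``sqrt(2 (1 - r))`` by default (the Euclidean distance
    between z-scored columns, up to a 1/sqrt(n) factor); ``"abs"`` uses
    ``1 - |r|`` instead.
    """
    R = np.asarray(R, dtype=float)
    if distance == "sqrt2":
        D = np.sqrt(np.clip(2.0 * (1.0 - R), 0.0, None))
    elif distance == "abs":
        D = 1.0 - np.abs(R)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    tree = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(tree, t=cut_height, criterion="distance")
    return ClusterResult(R, tree, labels, cut_height)


def select_features(
    mode: str,
    X: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    fdr_level: float = 0.05,
    cut_height: float = 1.0,
) -> list[int]:
    """Return 1-based indices of the selected feature subset.

    ``"paper"`` returns the fixed published 13-element list.
    ``"data_driven"`` reruns Mann-Whitney + BY per contrast on the given
    matrix, keeps features significant (adjusted p < fdr_level) for at
    least one contrast, clusters the correlation structure, and retains
    one representative per cluster: the member with the smallest minimum
    adjusted p across contrasts (ties broken by lowest index).
    """
    if mode == "paper":
        return list(PAPER_SELECTED)
    if mode != "data_driven":
        raise ValueError("mode must be 'paper' or 'data_driven'")
    if X is None or labels is None:
        raise ValueError("data_driven selection needs a feature matrix and labels")
    X = np.asarray(X, dtype=float)
    table = relevance_table(X, np.asarray(labels))
    adj = table[[c for c in table.columns if c.endswith("_adj")]].to_numpy()
    best_adj = adj.min(axis=1)
    significant = best_adj < fdr_level
    clusters = cluster_features(feature_correlation(X), cut_height).cluster_labels
    selected: list[int] = []
    for c in np.unique(clusters):
        members = np.nonzero((clusters == c) & significant)[0]
        if members.size:
            selected.append(int(members[np.argmin(best_adj[members])]) + 1)
    return sorted(selected)
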