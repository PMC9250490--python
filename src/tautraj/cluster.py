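"""Hierarchical agglomerative clustering of latent features and cluster-level
statistics (diagnosis contingency, ANOVA with Tukey post hoc)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.stats import chi2_contingency
from statsmodels.stats.multicomp import pairwise_tukeyhsd

LINKAGES = ("ward", "average", "complete")


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # per-subject cluster id in 0..k-1
    k: int
    linkage_name: str
    centers: np.ndarray         # (k, d) per-cluster mean of latent means

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.centers = np.asarray(self.centers, dtype=float)
        counts = np.bincount(self.labels, minlength=self.k)
        if np.any(counts == 0):
            raise ValueError("every cluster must be non-empty")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("cluster centers must be finite")

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def _as_matrix(latents) -> np.ndarray:
    X = np.asarray(latents, dtype=float)
    if X.ndim != 2:
        raise ValueError("latents must be a 2-D array (n subjects x latent dim)")
    if not np.all(np.isfinite(X)):
        raise ValueError("latents contain non-finite values")
    return X


def cluster_latents(latents, k: int, linkage: str = "ward") -> ClusterAssignment:
    """Cut the agglomerative merge tree at k clusters (Euclidean metric).

    Deterministic: merge ties are broken by scipy's index-order convention.
    Cluster ids are relabeled 0..k-1 in order of first appearance.
    """
    X = _as_matrix(latents)
    n = X.shape[0]
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds number of points n = {n}")
    Z = scipy_linkage(X, method=linkage)
    raw = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise ValueError(f"merge-tree cut produced {len(np.unique(raw))} clusters "
                         f"instead of {k} (degenerate ties)")
    # relabel in order of first appearance for stable ids
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    centers = np.stack([X[labels == c].mean(axis=0) for c in range(k)])
    return ClusterAssignment(labels=labels, k=k, linkage_name=linkage, centers=centers)


@dataclass
class KSelectionDiagnostics:
    merge_heights: np.ndarray     # ascending dendrogram merge distances
    gap_by_k: dict = field(default_factory=dict)
    selected_k: int = 0
    overridden: bool = False


def select_k(latents, k_range=(2, 8), linkage: str = "ward",
             override: int | None = None) -> tuple[int, KSelectionDiagnostics]:
    """Pick k by the largest relative gap between successive merge distances.

    Cutting into k clusters is admissible for any threshold between the
    (n-k)-th and (n-k+1)-th merge heights; the score of k is the ratio of
    those two heights, and the k with the largest ratio (smallest k on ties)
    wins.  An explicit ``override`` always wins but diagnostics are still
    computed for inspection, mirroring manual dendrogram reading.
    """
    X = _as_matrix(latents)
    n = X.shape[0]
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo > hi:
        raise ValueError("empty k_range")
    if lo < 2 or hi > n - 1:
        raise ValueError(f"k_range must lie within [2, n-1] = [2, {n - 1}]")
    heights = scipy_linkage(X, method=linkage)[:, 2]
    gaps: dict[int, float] = {}
    for k in range(lo, hi + 1):
        num, den = heights[n - k], heights[n - k - 1]
        gaps[k] = float(num / den) if den > 0 else (np.inf if num > 0 else 1.0)
    best = min(gaps, key=lambda k: (-gaps[k], k))
    diag = KSelectionDiagnostics(merge_heights=heights, gap_by_k=gaps,
                                 selected_k=best, overridden=override is not None)
    if override is not None:
        diag.selected_k = int(override)
        return int(override), diag
    return best, diag


@dataclass
class ContingencyResult:
    counts: pd.DataFrame       # k x c counts
    row_ratios: pd.DataFrame   # rows sum to 1
    statistic: float
    p_value: float
    dof: int
    dropped_categories: list = field(default_factory=list)


def cluster_contingency(assignment: ClusterAssignment, labels) -> ContingencyResult:
    """Pearson chi-squared test of cluster membership vs a categorical label."""
    labels = pd.Series(list(labels), name="label")
    if len(labels) != len(assignment.labels):
        raise ValueError("labels length must equal cohort size")
    counts = pd.crosstab(pd.Series(assignment.labels, name="cluster"), labels)
    dropped = [c for c in counts.columns if counts[c].sum() == 0]
    if dropped:
        warnings.warn(f"dropping zero-total categories: {dropped}")
        counts = counts.drop(columns=dropped)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 label categories present")
    stat, p, dof, _ = chi2_contingency(counts.to_numpy(), correction=False)
    ratios = counts.div(counts.sum(axis=1), axis=0)
    return ContingencyResult(counts=counts, row_ratios=ratios, statistic=float(stat),
                             p_value=float(p), dof=int(dof), dropped_categories=dropped)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    significant_pairs: list      # [(i, j), ...] cluster pairs differing at alpha
    note: str = ""


def compare_clusters_continuous(values, assignment: ClusterAssignment,
                                alpha: float = 0.05,
                                tukey: bool = True) -> AnovaResult:
    """One-way ANOVA across clusters followed by Tukey's HSD at ``alpha``.

    ``tukey=False`` skips the post hoc pairwise test (useful in simulation
    loops that only need the omnibus F)."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(assignment.labels):
        raise ValueError("values length must equal cohort size")
    groups = [values[assignment.members(c)] for c in range(assignment.k)]
    for c, g in enumerate(groups):
        if len(g) < 2 or not np.all(np.isfinite(g)):
            raise ValueError(f"cluster {c} needs >= 2 finite values for ANOVA")
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = assignment.k - 1
    df_w = len(values) - assignment.k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, [], note="no variation between or within clusters")
        return AnovaResult(float("inf"), 0.0,
                           [(i, j) for i in range(assignment.k)
                            for j in range(i + 1, assignment.k)
                            if groups[i][0] != groups[j][0]],
                           note="zero within-cluster variance; F unbounded")
    F = (ssb / df_b) / (ssw / df_w)
    from scipy.stats import f as f_dist
    p = float(f_dist.sf(F, df_b, df_w))
    if not tukey:
        return AnovaResult(float(F), p, [], note="tukey skipped")
    hsd = pairwise_tukeyhsd(values, assignment.labels, alpha=alpha)
    uniq = np.asarray(hsd.groupsunique)
    i_idx, j_idx = hsd._multicomp.pairindices
    pairs = [(int(uniq[a]), int(uniq[b]))
             for a, b, rej in zip(i_idx, j_idx, hsd.reject) if rej]
    return AnovaResult(float(F), p, pairs)
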