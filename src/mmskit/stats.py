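"""Cohort-level comparisons: rank tests, EMD clustering, ΔNSR linear fits.

All group comparisons are non-parametric (the Gamma-process descriptors are
skewed): pairwise Wilcoxon rank-sum matrices, Kruskal–Wallis with a
Tukey–Kramer-style mean-rank follow-up, and a tie-corrected Friedman test
for complete within-participant blocks.  Empirical spike-magnitude
distributions are compared with the 1-D earth mover's (Wasserstein-1)
distance and grouped by average-linkage hierarchical clustering.  The
face–heart relationship is summarized by an OLS fit of the face ΔNSR on the
heart ΔNSR (pain minus control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "PairwisePMatrix",
    "KruskalResult",
    "EMDMatrix",
    "ClusterAssignment",
    "DeltaFitResult",
    "ranksum_matrix",
    "kruskal_multcompare",
    "friedman_test",
    "emd_matrix",
    "cluster_tree",
    "delta_linear_fit",
]


@dataclass(frozen=True)
class PairwisePMatrix:
    """Symmetric matrix of two-sided rank-sum p-values (diagonal = 1)."""

    labels: tuple[str, ...]
    p_values: np.ndarray
    test: str = "ranksum"


@dataclass(frozen=True)
class KruskalResult:
    """Kruskal–Wallis omnibus plus pairwise mean-rank comparisons.

    A pair is flagged significant when the Tukey–Kramer-style intervals
    around the two mean ranks are disjoint at the 5% family level.
    """

    chi2: float
    p_value: float
    labels: tuple[str, ...]
    mean_ranks: np.ndarray
    halfwidths: np.ndarray
    significant: np.ndarray  # boolean matrix, True where intervals disjoint


@dataclass(frozen=True)
class EMDMatrix:
    labels: tuple
    distances: np.ndarray


@dataclass(frozen=True)
class ClusterAssignment:
    """Hierarchical-tree clustering cut at k groups.

    ``composition`` maps cluster id -> {condition: percentage} computed from
    the supplied condition labels (percentages within a cluster sum to 100).
    """

    k: int
    labels: np.ndarray  # cluster ids in 1..k, aligned with the EMD matrix rows
    composition: dict


@dataclass(frozen=True)
class DeltaFitResult:
    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    rmse: float
    n: int


def ranksum_matrix(groups: dict[str, np.ndarray], min_n: int = 3) -> PairwisePMatrix:
    """Two-sided tie-corrected Wilcoxon rank-sum p-values for every pair.

    Groups smaller than ``min_n`` are excluded with a warning.  No
    multiple-testing correction is applied: entries are raw pairwise
    p-values (a Benjamini–Hochberg pass can be applied downstream).
    """
    kept = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < min_n:
            warnings.warn(f"group {name!r} below size floor ({len(v)} < {min_n}); excluded")
            continue
        kept[name] = v
    labels = tuple(kept)
    k = len(labels)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.mannwhitneyu(
                kept[labels[i]], kept[labels[j]], alternative="two-sided",
                method="asymptotic",
            )
            p[i, j] = p[j, i] = res.pvalue
    return PairwisePMatrix(labels=labels, p_values=p)


def kruskal_multcompare(groups: dict[str, np.ndarray], alpha: float = 0.05) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis with mean-rank pairwise follow-up.

    The omnibus chi-square comes from the rank-based ANOVA on pooled ranks.
    The follow-up places an interval of half-width
    q_{alpha,k,inf}/2 * sqrt(S^2 (1/n_i + 1/n_j)) / sqrt(2) around each mean
    rank (S^2 = tie-corrected rank variance N(N+1)/12); a pair differs when
    its intervals are disjoint, mirroring the classical multiple-comparison
    display.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use ranksum_matrix for two")
    labels = tuple(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:  # all observations tied: no evidence of any effect
        k = len(labels)
        return KruskalResult(
            chi2=0.0, p_value=1.0, labels=labels,
            mean_ranks=np.full(k, (len(pooled) + 1) / 2.0),
            halfwidths=np.zeros(k), significant=np.zeros((k, k), dtype=bool),
        )
    chi2, p = stats.kruskal(*samples)
    ranks = stats.rankdata(pooled)
    sizes = np.array([len(s) for s in samples])
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = np.array([r.mean() for r in np.split(ranks, splits)])
    n_total = len(pooled)
    # tie-corrected rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    s2 = (n_total * (n_total + 1) / 12.0) * (1 - tie_term / (n_total**3 - n_total))
    q = stats.studentized_range.ppf(1 - alpha, len(labels), np.inf) / np.sqrt(2)
    k = len(labels)
    half = np.empty(k)
    sig = np.zeros((k, k), dtype=bool)
    # per-group halfwidth uses the average pairwise SE (equal-n exact)
    for i in range(k):
        ses = [
            np.sqrt(s2 * (1 / sizes[i] + 1 / sizes[j])) for j in range(k) if j != i
        ]
        half[i] = q * np.mean(ses) / 2.0
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(s2 * (1 / sizes[i] + 1 / sizes[j]))
            differ = abs(mean_ranks[i] - mean_ranks[j]) > q * se
            sig[i, j] = sig[j, i] = differ
    return KruskalResult(
        chi2=float(chi2), p_value=float(p), labels=labels,
        mean_ranks=mean_ranks, halfwidths=half, significant=sig,
    )


def friedman_test(blocked: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square for a participants x conditions block.

    Rows are participants (blocks), columns the repeated conditions; no
    missing cells are allowed.  Unlike scipy's implementation, k = 2
    conditions are accepted (the statistic then carries the sign-test's
    information).  Returns (chi2, p) with k - 1 degrees of freedom.
    """
    x = np.asarray(blocked, dtype=float)
    if x.ndim != 2:
        raise ValueError("blocked data must be a 2-D participants x conditions array")
    if np.any(~np.isfinite(x)):
        raise ValueError("incomplete block: missing cells are not allowed")
    n, k = x.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 conditions and 2 blocks")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction: average over blocks of the tie term
    correction = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        correction += np.sum(counts**3 - counts)
    denom = 1.0 - correction / (n * k * (k**2 - 1))
    if denom <= 0:  # all rows fully tied
        return 0.0, 1.0
    chi2 /= denom
    p = float(stats.chi2.sf(chi2, k - 1))
    return float(chi2), p


def emd_matrix(samples: dict, min_n: int = 30) -> EMDMatrix:
    """Pairwise 1-D Wasserstein-1 distances between empirical distributions.

    Operands are raw MMS spike-magnitude samples (not binned or parametric
    densities); records below the size floor are excluded with a warning.
    """
    kept = {}
    for name, vals in samples.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < min_n:
            warnings.warn(f"record {name!r} below sample floor ({len(v)} < {min_n}); excluded")
            continue
        kept[name] = v
    labels = tuple(kept)
    k = len(labels)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = stats.wasserstein_distance(kept[labels[i]], kept[labels[j]])
    return EMDMatrix(labels=labels, distances=d)


def cluster_tree(
    emd: EMDMatrix, k: int = 8, conditions: dict | None = None, linkage: str = "average"
) -> ClusterAssignment:
    """Agglomerative clustering of the EMD matrix cut at k clusters.

    ``conditions`` maps record label -> condition tag; per-cluster
    composition percentages are computed from it (100% "unknown" otherwise).
    """
    n = len(emd.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} outside 1..{n}")
    if k == n:
        assign = np.arange(1, n + 1)
    else:
        z = hierarchy.linkage(squareform(emd.distances, checks=False), method=linkage)
        assign = hierarchy.fcluster(z, t=k, criterion="maxclust")
    composition: dict[int, dict[str, float]] = {}
    for cid in range(1, int(assign.max()) + 1):
        members = [emd.labels[i] for i in np.flatnonzero(assign == cid)]
        tags = [
            (conditions or {}).get(m, "unknown") for m in members
        ]
        composition[cid] = {
            t: 100.0 * tags.count(t) / len(tags) for t in sorted(set(tags))
        }
    return ClusterAssignment(k=k, labels=assign, composition=composition)


def delta_linear_fit(delta_face: np.ndarray, delta_heart: np.ndarray) -> DeltaFitResult:
    """OLS of face ΔNSR on heart ΔNSR with goodness-of-fit summaries."""
    yf = np.asarray(delta_face, dtype=float)
    xh = np.asarray(delta_heart, dtype=float)
    if yf.shape != xh.shape or yf.ndim != 1:
        raise ValueError("delta vectors must be paired one-dimensional arrays")
    n = len(yf)
    if n < 3:
        raise ValueError("need at least 3 paired deltas")
    model = sm.OLS(yf, sm.add_constant(xh)).fit()
    resid = model.resid
    return DeltaFitResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        adjusted_r_squared=float(model.rsquared_adj),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=n,
    )
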