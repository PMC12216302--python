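"""K-means morphological typing and the study's statistical tests.

Tests: two-sided Wilcoxon rank-sum (exact for small tie-free samples),
pooled-variance two-sample t, Benjamini-Hochberg FDR, and Pearson
correlation with a t-transform p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

__all__ = [
    "StatResult",
    "TypeAssignment",
    "kmeans_two_types",
    "rank_sum_test",
    "signed_rank_test",
    "pooled_t_test",
    "bh_fdr",
    "pearson_correlation",
]

#: Exact rank-sum enumeration below this combined sample size (no ties).
_EXACT_LIMIT = 12


@dataclass
class StatResult:
    statistic: float
    p_value: float
    df: float | None = None
    p_adjusted: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class TypeAssignment:
    """Two-cluster typing of neurons by arbor size and complexity.

    Type 1 is the more populous cluster (tie broken toward the smaller mean
    length); cluster means are reported in original feature units.
    """

    labels: dict[str, int]
    cluster_means: dict[int, tuple[float, float]]
    cluster_sizes: dict[int, int]
    seed: int

    @property
    def type_of(self) -> dict[str, int]:
        return self.labels


def kmeans_two_types(
    features: pd.DataFrame | np.ndarray,
    seed: int,
    restarts: int = 50,
) -> TypeAssignment:
    """Cluster (total_length, branch_count) feature rows into two types.

    Features are z-scored per column before clustering; the best of
    ``restarts`` initializations (by within-cluster sum of squares) is kept
    and the result is deterministic given ``seed``.
    """
    if isinstance(features, pd.DataFrame):
        data = features[["total_length", "branch_count"]].to_numpy(float)
        names = [str(i) for i in features.index]
    else:
        data = np.asarray(features, dtype=float)
        names = [str(i) for i in range(len(data))]
    if len(np.unique(data, axis=0)) < 2:
        raise ValueError("need at least 2 distinct feature vectors")
    mu = data.mean(axis=0)
    sd = data.std(axis=0)
    sd[sd == 0] = 1.0
    z = (data - mu) / sd
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed)
    raw = km.fit_predict(z)
    sizes = {k: int(np.sum(raw == k)) for k in (0, 1)}
    mean_len = {k: float(data[raw == k, 0].mean()) for k in (0, 1)}
    # type 1 = more populous; tie broken toward the smaller mean length
    order = sorted((0, 1), key=lambda k: (-sizes[k], mean_len[k]))
    remap = {order[0]: 1, order[1]: 2}
    labels = {name: remap[k] for name, k in zip(names, raw)}
    cluster_means = {
        remap[k]: (
            float(data[raw == k, 0].mean()),
            float(data[raw == k, 1].mean()),
        )
        for k in (0, 1)
    }
    cluster_sizes = {remap[k]: sizes[k] for k in (0, 1)}
    if min(cluster_sizes.values()) == 0:
        raise ValueError("k-means produced an empty cluster")
    return TypeAssignment(labels, cluster_means, cluster_sizes, seed)


def rank_sum_test(a, b) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the U distribution when the combined sample size is
    at most 12 and there are no ties; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    if a.size + b.size <= _EXACT_LIMIT and no_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "rank-sum (exact)"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        )
        method = "rank-sum (normal approximation)"
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method=method,
    )


def signed_rank_test(a, b) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples (completeness)."""
    res = sps.wilcoxon(np.asarray(a, float), np.asarray(b, float))
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="signed-rank",
    )


def pooled_t_test(a, b) -> StatResult:
    """Pooled-variance two-sample t-test with df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return StatResult(0.0, 1.0, df=float(a.size + b.size - 2),
                              method="pooled t")
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=True)
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(a.size + b.size - 2),
        method="pooled t",
    )


def bh_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return [float(v) for v in out]


def pearson_correlation(x, y) -> StatResult:
    """Sample Pearson r with a two-sided t-transform p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a correlation input")
    res = sps.pearsonr(x, y)
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(x.size - 2),
        method="pearson",
    )
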