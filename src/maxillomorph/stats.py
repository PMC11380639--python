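"""Cohort statistics for the region summaries and segment measurements.

Thin, contract-checked wrappers over scipy.stats and scikit-learn: Tukey
IQR outlier fences (1.5x normal / 3x extreme), Welch's t, one-way ANOVA,
chi-square on contingency counts, Pearson correlation, and univariate
k-means with elbow-criterion model selection.  Quantiles use the
linear-interpolation convention.  No multiple-testing correction is applied
by default; Bonferroni / Benjamini-Hochberg adjustment is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans

__all__ = [
    "OutlierFlags",
    "TestResult",
    "ClusterResult",
    "iqr_outliers",
    "welch_t",
    "anova_oneway",
    "chi_square",
    "pearson_r",
    "kmeans_1d",
    "wss_curve",
    "select_elbow_from_curve",
    "elbow_select",
    "adjust_pvalues",
]


class StatsError(ValueError):
    pass


def _arr(values) -> np.ndarray:
    a = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise StatsError("non-finite values")
    return a


@dataclass
class OutlierFlags:
    """Tukey-fence outlier labels: 'none', 'normal' (beyond k_normal x IQR)
    or 'extreme' (beyond k_extreme x IQR)."""

    flags: np.ndarray
    q1: float
    q3: float
    iqr: float
    inner_fences: Tuple[float, float]
    outer_fences: Tuple[float, float]


@dataclass
class TestResult:
    statistic: float
    df: Union[float, Tuple[float, float]]
    p_value: float


@dataclass
class ClusterResult:
    k: int
    centers: np.ndarray          # sorted ascending
    assignments: np.ndarray      # indices into centers
    wss: float                   # within-cluster sum of squares


def iqr_outliers(values, k_normal: float = 1.5, k_extreme: float = 3.0) -> OutlierFlags:
    """Flag values outside Tukey fences at ``k * IQR`` beyond the quartiles."""
    a = _arr(values)
    if a.size < 4:
        raise StatsError("need at least 4 values for IQR fences")
    q1, q3 = np.percentile(a, [25, 75])  # linear-interpolation quantiles
    iqr = q3 - q1
    inner = (q1 - k_normal * iqr, q3 + k_normal * iqr)
    outer = (q1 - k_extreme * iqr, q3 + k_extreme * iqr)
    flags = np.full(a.shape, "none", dtype=object)
    flags[(a < inner[0]) | (a > inner[1])] = "normal"
    flags[(a < outer[0]) | (a > outer[1])] = "extreme"
    return OutlierFlags(flags, float(q1), float(q3), float(iqr), inner, outer)


def welch_t(sample_a, sample_b) -> TestResult:
    """Welch's unequal-variance t test, two-sided, Welch-Satterthwaite df."""
    a, b = _arr(sample_a), _arr(sample_b)
    if a.size < 2 or b.size < 2:
        raise StatsError("each sample needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult(0.0, float(a.size + b.size - 2), 1.0)
        raise StatsError("both samples have zero variance; Welch statistic undefined")
    r = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(r.statistic), float(r.df), float(r.pvalue))


def anova_oneway(groups: Sequence) -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within, df = (g-1, N-g)."""
    gs = [_arr(g) for g in groups]
    if len(gs) < 2:
        raise StatsError("need >= 2 groups")
    if any(g.size < 2 for g in gs):
        raise StatsError("every group needs >= 2 values")
    n_total = sum(g.size for g in gs)
    df = (float(len(gs) - 1), float(n_total - len(gs)))
    if np.ptp(np.concatenate(gs)) == 0:  # all observations identical
        return TestResult(0.0, df, 1.0)
    r = sps.f_oneway(*gs)
    return TestResult(float(r.statistic), df, float(r.pvalue))


def chi_square(table, yates: bool = False) -> TestResult:
    """Pearson chi-square on an r x c contingency table of counts."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.min() < 0:
        raise StatsError("table must be a 2D array of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise StatsError("zero row/column margin: expected counts are 0")
    r = sps.chi2_contingency(t, correction=yates)
    return TestResult(float(r.statistic), float(r.dof), float(r.pvalue))


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    xa, ya = _arr(x), _arr(y)
    if xa.size != ya.size or xa.size < 3:
        raise StatsError("need paired samples of length >= 3")
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise StatsError("constant input: correlation undefined")
    return float(sps.pearsonr(xa, ya).statistic)


def kmeans_1d(values, k: int, seed: int = 0, n_init: int = 10) -> ClusterResult:
    """Best-of-``n_init`` k-means on 1-D values; centers sorted ascending."""
    a = _arr(values)
    n_distinct = np.unique(a).size
    if k < 1:
        raise StatsError("k must be >= 1")
    if k > n_distinct:
        raise StatsError(f"k={k} exceeds the number of distinct values ({n_distinct})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed)).fit(a.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusterResult(
        k=k,
        centers=km.cluster_centers_.ravel()[order],
        assignments=relabel[km.labels_],
        wss=float(km.inertia_),
    )


def wss_curve(values, k_max: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Within-cluster sum of squares for k = 1..k_max."""
    return np.array([kmeans_1d(values, k, seed, n_init).wss for k in range(1, k_max + 1)])


def select_elbow_from_curve(wss: Sequence[float]) -> int:
    """k with the largest second difference of the WSS curve; ties -> smaller k."""
    w = np.asarray(wss, dtype=float)
    if w.size < 3:
        raise StatsError("need WSS for at least k = 1..3")
    second = w[:-2] - 2 * w[1:-1] + w[2:]   # index i -> k = i + 2
    return int(np.argmax(second)) + 2       # argmax keeps the smaller k on ties


def elbow_select(values, k_max: int = 6, seed: int = 0, n_init: int = 10) -> int:
    """Elbow-criterion cluster count over k = 1..k_max.

    When no elbow dominates (flat curve, e.g. one tight cluster) the tie rule
    yields the smallest candidate, k = 2 — treat such a selection as
    low-confidence.
    """
    if k_max < 3:
        raise StatsError("k_max must be >= 3")
    a = _arr(values)
    n_distinct = np.unique(a).size
    if n_distinct < 3:
        raise StatsError("too few distinct values for elbow selection")
    return select_elbow_from_curve(wss_curve(a, min(k_max, n_distinct), seed, n_init))


def adjust_pvalues(p_values, method: Optional[str] = None) -> np.ndarray:
    """Optional multiple-testing adjustment ('bonferroni' or 'bh'); default none."""
    p = _arr(p_values)
    if method is None:
        return p
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(adj, 1.0)
        return out
    raise StatsError(f"unknown adjustment method {method!r}")
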