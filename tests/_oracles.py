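"""Independent brute-force textbook implementations of the cohort statistics.

These deliberately avoid scipy.stats' test functions (only distribution
CDFs are shared) so the package's wrappers are checked against a second,
hand-written route.
"""

import math

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist


def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va = sum((x - a.mean()) ** 2 for x in a) / (na - 1)
    vb = sum((x - b.mean()) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


def anova_oracle(groups):
    groups = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    F = (ss_between / df1) / (ss_within / df2)
    return F, (df1, df2), f_dist.sf(F, df1, df2)


def chi_square_oracle(table):
    t = np.asarray(table, float)
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            exp = rows[i] * cols[j] / n
            stat += (t[i, j] - exp) ** 2 / exp
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, df, chi2_dist.sf(stat, df)


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def quantile_oracle(values, q):
    """Linear-interpolation quantile, computed from the sorted sample."""
    v = np.sort(np.asarray(values, float))
    h = (len(v) - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def iqr_fences_oracle(values, k_normal=1.5, k_extreme=3.0):
    q1 = quantile_oracle(values, 0.25)
    q3 = quantile_oracle(values, 0.75)
    iqr = q3 - q1
    return (
        (q1 - k_normal * iqr, q3 + k_normal * iqr),
        (q1 - k_extreme * iqr, q3 + k_extreme * iqr),
    )
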