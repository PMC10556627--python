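"""Association and group-comparison statistics for the residence-time analyses.

Pearson/Spearman correlation (occupancy vs dwell-time), the Mann-Whitney
rank-sum comparison (RP-regulating vs other sites), and one-way ANOVA with
Tukey's HSD (occupancy level across dwell-time quartiles). The rank-sum test
is computed by exact enumeration for small tie-free samples and by the
tie- and continuity-corrected normal approximation otherwise. p-values are
stored at full precision; "< 2.2e-16" is a display convention only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TestResult", "correlate", "rank_sum_test", "anova_tukey"]

EXACT_MAX_N = 12  # exact Mann-Whitney enumeration limit (total sample size)


@dataclass
class TestResult:
    method: str
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    undefined: bool = False
    extra: dict = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None


def correlate(x, y, method: str = "pearson") -> TestResult:
    """Product-moment or rank correlation with two-sided t-approximation p.

    Zero variance in either vector yields an undefined (flagged) result rather
    than an exception. Spearman uses average ranks for ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(method, float("nan"), float("nan"), (len(x),), undefined=True)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return TestResult(method, float(r), float(p), (len(x),))


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def rank_sum_test(a, b) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact p by full enumeration of labelings when n_a + n_b <= 12 with no
    ties; otherwise the normal approximation with tie correction and
    continuity correction. The reported statistic is U for sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples need >= 1 observation")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # average ranks for ties
    u_obs = _u_statistic(ranks[:n_a], n_a)
    has_ties = len(np.unique(pooled)) < len(pooled)
    mu = n_a * n_b / 2.0
    if n_a + n_b <= EXACT_MAX_N and not has_ties:
        # enumerate all C(n, n_a) assignments of pooled ranks to sample a
        dev_obs = abs(u_obs - mu)
        total = 0
        extreme = 0
        all_ranks = np.arange(1, n_a + n_b + 1, dtype=float)
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            u = _u_statistic(all_ranks[list(combo)], n_a)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                extreme += 1
        return TestResult("mann-whitney-exact", u_obs, extreme / total, (n_a, n_b))
    # normal approximation with tie correction + continuity correction
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return TestResult("mann-whitney-normal", u_obs, 1.0, (n_a, n_b))
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return TestResult("mann-whitney-normal", u_obs, p, (n_a, n_b))


def anova_tukey(groups: dict[str, np.ndarray]) -> TestResult:
    """One-way fixed-effects ANOVA with Tukey HSD pairwise adjusted p-values.

    The pairwise table has one row per unordered group pair with the mean
    difference and the adjusted p from the studentized-range distribution with
    pooled within-group variance. A group with zero variance is allowed; if all
    values are identical overall, F = 0 and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = sorted(groups)
    data = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs >= 2 values")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {g!r} contains non-finite values")
    k = len(labels)
    ns = {g: len(v) for g, v in data.items()}
    n_total = sum(ns.values())
    grand = float(np.concatenate(list(data.values())).mean())
    means = {g: float(v.mean()) for g, v in data.items()}
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in labels)
    ss_within = sum(float(np.sum((data[g] - means[g]) ** 2)) for g in labels)
    df_between, df_within = k - 1, n_total - k
    if ss_between <= 0 and ss_within <= 0:
        f_stat, p = 0.0, 1.0
    elif ss_within <= 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f_stat, df_between, df_within))
    s2 = ss_within / df_within if df_within > 0 else float("nan")
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        diff = means[g2] - means[g1]
        if s2 > 0:
            se = math.sqrt(s2 / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_within))
        else:
            p_adj = 1.0 if diff == 0 else 0.0
        rows.append({"group1": g1, "group2": g2, "mean_diff": diff, "p_adj": p_adj})
    pairwise = pd.DataFrame(rows)
    return TestResult(
        "anova-tukey",
        f_stat,
        p,
        tuple(ns[g] for g in labels),
        extra={"df_between": df_between, "df_within": df_within, "groups": labels},
        pairwise=pairwise,
    )
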