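"""Cohort comparison statistics: Welch t, Wilcoxon rank sum, effect size r.

These back the descriptive group-comparison table (feature means +/- SD per
group with two-sided p values and an effect size). The rank-sum test uses
midranks for ties, a tie-corrected normal approximation with continuity
correction, and exact enumeration for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WelchResult",
    "RankSumResult",
    "welch_t",
    "wilcoxon_rank_sum",
    "effect_size_r",
    "compare_groups",
]


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


@dataclass
class RankSumResult:
    W: float       # rank sum of the first sample
    U: float       # Mann-Whitney U of the first sample
    Z: float       # tie- and continuity-corrected normal deviate
    p: float       # two-sided
    method: str    # 'exact' | 'normal'


def _as_sample(x, min_n: int) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size < min_n or not np.all(np.isfinite(a)):
        raise ValueError(f"need at least {min_n} finite observations per sample")
    return a


def welch_t(a, b) -> WelchResult:
    """Welch's unequal-variance t test, two-sided.

    ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with
    Welch-Satterthwaite degrees of freedom. Two samples with zero variance
    and equal means give t = 0, p = 1.
    """
    a, b = _as_sample(a, 2), _as_sample(b, 2)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(W, U, Z) with midranks, tie-corrected variance, continuity correction."""
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, u, 0.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var) if u != mu else 0.0
    return w, u, float(z)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by enumerating all group assignments of the pooled
    midranks (feasible for n1 + n2 <= 12)."""
    n1 = a.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    n = ranks.size
    total = comb(n, n1)
    offset = n1 * (n1 + 1) / 2.0
    us = np.fromiter(
        (ranks[list(idx)].sum() - offset for idx in combinations(range(n), n1)),
        dtype=float, count=total)
    lo = np.sum(us <= u_obs + 1e-9) / total
    hi = np.sum(us >= u_obs - 1e-9) / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(a, b, method: str = "auto") -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    ``method``: 'exact' enumerates all rank assignments (default for
    n1 + n2 <= 12), 'normal' uses the tie-corrected continuity-corrected
    normal approximation, 'auto' picks between them.
    """
    a, b = _as_sample(a, 1), _as_sample(b, 1)
    w, u, z = _rank_sum_z(a, b)
    if np.all(np.concatenate([a, b]) == a[0]):
        return RankSumResult(W=w, U=u, Z=0.0, p=1.0, method="degenerate")
    if method == "auto":
        method = "exact" if a.size + b.size <= 12 else "normal"
    if method == "exact":
        p = _exact_two_sided_p(a, b, u)
    elif method == "normal":
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method: {method!r}")
    return RankSumResult(W=w, U=u, Z=z, p=min(1.0, p), method=method)


def effect_size_r(result, n_total: int, kind: str = "rank") -> float:
    """Effect size r for a group comparison.

    ``kind='rank'`` (default): ``r = Z / sqrt(N)`` from the rank-sum normal
    deviate — the standard companion to the Wilcoxon test. ``kind='t'``:
    ``r = sqrt(t^2 / (t^2 + df))`` from a Welch result. The magnitude is
    bounded by 1.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if kind == "rank":
        if not isinstance(result, RankSumResult):
            raise TypeError("kind='rank' expects a RankSumResult")
        r = result.Z / np.sqrt(n_total)
    elif kind == "t":
        if not isinstance(result, WelchResult):
            raise TypeError("kind='t' expects a WelchResult")
        r = np.sqrt(result.t**2 / (result.t**2 + result.df))
    else:
        raise ValueError(f"unknown kind: {kind!r}")
    return float(np.clip(r, -1.0, 1.0))


def compare_groups(df: pd.DataFrame, features=None, label_col: str = "label",
                   group_a: str = "HV", group_b: str = "ACM") -> pd.DataFrame:
    """Group-comparison table: means +/- SD per group, Welch and rank-sum p,
    effect size |r| = |Z|/sqrt(N), one row per feature."""
    if features is None:
        from .features import FEATURE_COLUMNS
        features = [f for f in FEATURE_COLUMNS if f in df.columns]
    a_df, b_df = df[df[label_col] == group_a], df[df[label_col] == group_b]
    if a_df.empty or b_df.empty:
        raise ValueError("both groups must be present")
    rows = []
    for feat in features:
        a, b = a_df[feat].to_numpy(float), b_df[feat].to_numpy(float)
        wt = welch_t(a, b)
        ws = wilcoxon_rank_sum(a, b)
        rows.append({
            "feature": feat,
            f"mean_{group_a}": a.mean(), f"sd_{group_a}": a.std(ddof=1),
            f"mean_{group_b}": b.mean(), f"sd_{group_b}": b.std(ddof=1),
            "t": wt.t, "df_welch": wt.df, "p_welch": wt.p,
            "W": ws.W, "Z": ws.Z, "p_wilcoxon": ws.p,
            "effect_size_r": abs(effect_size_r(ws, a.size + b.size)),
        })
    return pd.DataFrame(rows)
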