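"""Univariate group statistics for ITPR records.

One-way ANOVA with Tukey's honest-significant-difference post-hoc test,
and Levene's test of homogeneity of variances.  Statistics are computed
from explicit sums of squares; only the reference distributions (F,
studentized range) come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .errors import SpineCongruenceError

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "anova_oneway",
    "tukey_hsd",
    "levene",
    "summarize",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: tuple[float, ...]
    group_counts: tuple[int, ...]


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[int, int]
    mean_difference: float
    q: float
    p: float
    significant: bool


def _validate_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise SpineCongruenceError("need at least two groups")
    for g in gs:
        if len(g) < 2:
            raise SpineCongruenceError("every group needs at least two observations")
        if not np.all(np.isfinite(g)):
            raise SpineCongruenceError("observations must be finite")
    return gs


def _sums_of_squares(gs: list[np.ndarray]):
    all_obs = np.concatenate(gs)
    grand = all_obs.mean()
    means = np.array([g.mean() for g in gs])
    ns = np.array([len(g) for g in gs])
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(gs, means)))
    return ssb, ssw, means, ns


def anova_oneway(groups) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA.

    F = MS_between / MS_within; the p-value is the upper tail of the
    F(k-1, N-k) distribution.  Zero within-group variance makes F
    undefined and raises.
    """
    gs = _validate_groups(groups)
    ssb, ssw, means, ns = _sums_of_squares(gs)
    k = len(gs)
    n_total = int(ns.sum())
    df_b, df_w = k - 1, n_total - k
    if ssw <= 0:
        raise SpineCongruenceError("zero within-group variance: F undefined")
    f_stat = (ssb / df_b) / (ssw / df_w)
    return AnovaResult(
        F=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p=float(f_dist.sf(f_stat, df_b, df_w)),
        group_means=tuple(means),
        group_counts=tuple(int(n) for n in ns),
    )


def tukey_hsd(groups, alpha: float = 0.05) -> list[PairwiseComparison]:
    """All-pairs Tukey HSD comparisons.

    Uses the Tukey–Kramer standard error sqrt(MS_within/2 * (1/n_i + 1/n_j))
    for unbalanced groups; adjusted p-values come from the studentized-range
    distribution with (k, N-k).
    """
    if not 0 < alpha < 1:
        raise SpineCongruenceError("alpha must be in (0, 1)")
    gs = _validate_groups(groups)
    _, ssw, means, ns = _sums_of_squares(gs)
    k = len(gs)
    df_w = int(ns.sum()) - k
    if ssw <= 0:
        raise SpineCongruenceError("zero within-group variance: q undefined")
    msw = ssw / df_w
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p = float(studentized_range.sf(q, k, df_w)) if q > 0 else 1.0
            p = min(max(p, 0.0), 1.0)
            out.append(
                PairwiseComparison(
                    pair=(i, j),
                    mean_difference=diff,
                    q=float(q),
                    p=p,
                    significant=bool(p < alpha),
                )
            )
    return out


def levene(groups, center: str = "mean"):
    """Levene's test of homogeneity of variances.

    W is the one-way ANOVA F statistic computed on absolute deviations
    from each group's center (classic Levene uses the mean; ``median``
    gives the Brown–Forsythe variant).  Returns ``(W, p)``.  By
    convention W = 0 (p = 1) when the deviation means are identical
    across groups, even if the deviations have no within-group spread.
    """
    if center not in ("mean", "median"):
        raise SpineCongruenceError("center must be 'mean' or 'median'")
    gs = _validate_groups(groups)
    cfun = np.mean if center == "mean" else np.median
    devs = [np.abs(g - cfun(g)) for g in gs]
    ssb, ssw, _, ns = _sums_of_squares(devs)
    k = len(gs)
    df_b, df_w = k - 1, int(ns.sum()) - k
    if ssb <= 1e-30:
        return 0.0, 1.0
    if ssw <= 0:
        # deviations differ between groups but have no within-group spread
        return float("inf"), 0.0
    w_stat = (ssb / df_b) / (ssw / df_w)
    return float(w_stat), float(f_dist.sf(w_stat, df_b, df_w))


def summarize(
    records: pd.DataFrame, by: list[str], value: str = "itpr"
) -> pd.DataFrame:
    """Mean ± sample SD ± n per cell of a record table.

    SD uses the n−1 denominator; single-observation cells report SD 0
    with ``degenerate = True``.
    """
    if len(records) == 0:
        raise SpineCongruenceError("no records to summarize")
    agg = (
        records.groupby(by, sort=False)[value]
        .agg(["mean", "std", "count"])
        .rename(columns={"std": "sd", "count": "n"})
    )
    agg["degenerate"] = agg["n"] < 2
    agg["sd"] = agg["sd"].fillna(0.0)
    return agg
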