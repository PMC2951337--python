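"""Expression-stratified survival analysis and group-association tests.

Covers the median (rank) split of a gene's expression, Kaplan–Meier
product-limit curves, the two-group log-rank (chi-square, 1 df) test,
ANOVA/t-tests of expression across subtype groups, the 2x2 chi-square
for pathological complete response, and doubling-time estimation by
linear regression of log2 cell counts on time.

The log-rank statistic is computed directly (observed minus expected
events at each distinct event time, hypergeometric variance) so that
large null calibrations stay cheap; it agrees with
``lifelines.statistics.logrank_test``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "KmCurve",
    "rank_split",
    "km_estimate",
    "logrank_test",
    "death_count_chisq",
    "expression_group_tests",
    "pcr_chisq",
    "doubling_time",
]


@dataclass
class KmCurve:
    group: str
    times: np.ndarray           # event times where the curve steps
    survival: np.ndarray        # S(t) just after each step
    at_risk: np.ndarray         # subjects at risk just before each step


def rank_split(values) -> pd.Series:
    """Rank values high-to-low and split into halves.

    The top ``ceil(n/2)`` values are labeled ``"high"``, the rest
    ``"low"``; ties (and the odd middle element) break by stable input
    order, so the result is deterministic.
    """
    values = pd.Series(values)
    v = values.to_numpy(dtype=float)
    if np.isnan(v).all():
        raise ValueError("all values missing")
    if len(v) < 2:
        raise ValueError("need at least 2 samples to split")
    order = np.argsort(-v, kind="stable")  # NaN sorts last
    n_high = int(np.ceil(len(v) / 2))
    labels = np.empty(len(v), dtype=object)
    labels[order[:n_high]] = "high"
    labels[order[n_high:]] = "low"
    return pd.Series(labels, index=values.index, name="split")


def km_estimate(times, events, groups=None) -> dict[str, KmCurve]:
    """Kaplan–Meier product-limit curves, one per group.

    Censored subjects reduce the at-risk count without producing steps.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValueError("negative survival times")
    if groups is None:
        groups = np.array(["all"] * len(times))
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() < 1:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], event_observed=events[sel])
        ev = kmf.event_table
        steps = ev[ev["observed"] > 0]
        surv = kmf.survival_function_at_times(steps.index.to_numpy()).to_numpy()
        out[str(g)] = KmCurve(
            group=str(g),
            times=steps.index.to_numpy(dtype=float),
            survival=surv,
            at_risk=steps["at_risk"].to_numpy(dtype=float),
        )
    return out


def _logrank_two_group(times, events, in_g1) -> float:
    """Log-rank chi-square statistic for two groups (vectorized)."""
    order = np.argsort(times, kind="stable")
    t, e, g1 = times[order], events[order], in_g1[order]

    ut, inv = np.unique(t, return_inverse=True)
    d = np.bincount(inv, weights=e.astype(float), minlength=len(ut))
    d1 = np.bincount(inv, weights=(e & g1).astype(float), minlength=len(ut))
    removed = np.bincount(inv, minlength=len(ut)).astype(float)
    removed1 = np.bincount(inv, weights=g1.astype(float), minlength=len(ut))
    n_at = len(t) - np.concatenate([[0.0], np.cumsum(removed)[:-1]])
    n1_at = g1.sum() - np.concatenate([[0.0], np.cumsum(removed1)[:-1]])

    has = (d > 0) & (n_at > 1)
    d, d1, n_at, n1_at = d[has], d1[has], n_at[has], n1_at[has]
    exp1 = d * n1_at / n_at
    var1 = d * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d) / (n_at - 1)
    v = var1.sum()
    if v == 0:
        return 0.0
    return float((d1.sum() - exp1.sum()) ** 2 / v)


def logrank_test(times, events, groups) -> dict:
    """Two-group log-rank test.

    Returns ``{"chi2": statistic, "df": 1, "p": p-value}``. The statistic
    is the squared standardized observed-minus-expected event count,
    asymptotically chi-square with 1 df.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    if events.sum() < 1:
        raise ValueError("no events observed")
    chi2 = _logrank_two_group(times, events, groups == labels[0])
    return {"chi2": chi2, "df": 1, "p": float(stats.chi2.sf(chi2, df=1))}


def death_count_chisq(events, groups) -> dict:
    """Naive 2x2 chi-square on death counts per group (sensitivity check)."""
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("need exactly 2 groups")
    table = [
        [int((events & (groups == g)).sum()), int((~events & (groups == g)).sum())]
        for g in labels
    ]
    return pcr_chisq(np.array(table))


def expression_group_tests(expr, labels, welch: bool = False) -> dict:
    """Two-sided t-test (2 groups) or one-way ANOVA (>2 groups) on expression."""
    expr = pd.Series(expr).astype(float)
    labels = pd.Series(labels)
    by = expr.groupby(labels.to_numpy())
    arrays = [g.dropna().to_numpy() for _, g in by]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    if len(arrays) == 2:
        t_stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=not welch)
        return {"test": "t", "statistic": float(t_stat), "p": float(p)}
    f_stat, p = stats.f_oneway(*arrays)
    return {"test": "anova", "statistic": float(f_stat), "p": float(p)}


def pcr_chisq(counts, correction: bool = False) -> dict:
    """Pearson chi-square on a 2x2 contingency table, 1 df.

    No continuity correction by default.
    """
    counts = np.asarray(counts)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
        if (counts != np.round(counts)).any() or (counts < 0).any():
            raise ValueError("counts must be non-negative integers")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(counts, correction=correction)
    return {"chi2": float(chi2), "df": int(dof), "p": float(p)}


def doubling_time(counts, times_h) -> float:
    """Doubling time (hours) from linear regression of log2(count) on time.

    DT = 1 / slope. Raises on non-positive counts and flags a
    non-growing culture (slope <= 0) as an error.
    """
    counts = np.asarray(counts, dtype=float)
    times_h = np.asarray(times_h, dtype=float)
    if len(counts) < 3:
        raise ValueError("need at least 3 counts")
    if (counts <= 0).any():
        raise ValueError("counts must be positive")
    res = stats.linregress(times_h, np.log2(counts))
    if res.slope <= 0:
        raise ValueError("non-growing culture: regression slope is not positive")
    return float(1.0 / res.slope)
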