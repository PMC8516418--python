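"""Group statistics: log transform, t-tests, one-way ANOVA with
Student-Newman-Keuls post hoc, and mean +/- SEM summaries.

Fission-pore durations are approximately log-normal, so they are
log10-transformed before t-tests to meet the normality assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "log_transform",
    "ttest_unpaired",
    "ttest_paired",
    "anova_oneway_posthoc",
    "AnovaResult",
    "PairwiseComparison",
    "summarize",
]


def log_transform(values) -> np.ndarray:
    """Elementwise base-10 logarithm; requires strictly positive input."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("log transform requires strictly positive values")
    return np.log10(v)


def ttest_unpaired(a, b):
    """Two-tailed unpaired Student's t-test: returns (t, p, df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue), len(a) + len(b) - 2


def ttest_paired(a, b):
    """Two-tailed paired Student's t-test: returns (t, p, df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must be aligned")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), len(a) - 1


@dataclass
class PairwiseComparison:
    """One SNK pairwise decision (group indices into the input order)."""

    i: int
    j: int
    q: float
    p: float  # NaN when the comparison was gated off by the stepwise rule
    reject: bool


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    posthoc: list


@lru_cache(maxsize=256)
def _q_crit(alpha: float, r: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, r, df))


def anova_oneway_posthoc(
    groups: Sequence,
    alpha: float = 0.05,
    compute_pvalues: bool = True,
) -> AnovaResult:
    """One-way ANOVA with Student-Newman-Keuls pairwise post hoc.

    SNK orders the group means and tests ranges stepwise: the comparison of
    means ``r`` steps apart uses the studentized-range critical value for
    ``r`` means, and an inner comparison is only tested when every range
    enclosing it was significant.  Under a complete null this caps the
    familywise error at alpha.

    ``compute_pvalues=False`` skips the (expensive) studentized-range
    p-value evaluation and reports decisions only, which is what large
    null-calibration simulations need.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("fewer than 3 groups: use a t-test instead")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")

    f_stat, f_p = sps.f_oneway(*groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    df_within = int(ns.sum() - k)
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    mse = sse / df_within

    order = np.argsort(means)  # ascending
    comparisons: list[PairwiseComparison] = []

    def q_of(ai: int, bi: int) -> float:
        # harmonic-mean sample size handles mild imbalance (Tukey-Kramer form)
        nh = 2.0 / (1.0 / ns[ai] + 1.0 / ns[bi])
        se = np.sqrt(mse / nh)
        return abs(means[ai] - means[bi]) / se if se > 0 else np.inf

    def test_range(lo: int, hi: int):
        """Stepwise recursion over the ordered means."""
        r = hi - lo + 1
        if r < 2:
            return
        ai, bi = sorted((int(order[lo]), int(order[hi])))
        q = q_of(ai, bi)
        reject = q > _q_crit(alpha, r, df_within)
        p = float(sps.studentized_range.sf(q, r, df_within)) if compute_pvalues else np.nan
        comparisons.append(PairwiseComparison(i=ai, j=bi, q=q, p=p, reject=reject))
        if reject:
            test_range(lo, hi - 1)
            test_range(lo + 1, hi)

    test_range(0, k - 1)
    # comparisons never reached by the recursion: not significant by gating
    seen = {(min(c.i, c.j), max(c.i, c.j)) for c in comparisons}
    for lo in range(k):
        for hi in range(lo + 1, k):
            ai, bi = sorted((int(order[lo]), int(order[hi])))
            if (ai, bi) not in seen:
                comparisons.append(PairwiseComparison(
                    i=ai, j=bi, q=q_of(ai, bi), p=np.nan, reject=False,
                ))
    # deduplicate (recursion can visit a pair twice via both branches)
    uniq = {}
    for c in comparisons:
        key = (min(c.i, c.j), max(c.i, c.j))
        if key not in uniq or (c.reject and not uniq[key].reject):
            uniq[key] = c
    posthoc = sorted(uniq.values(), key=lambda c: (c.i, c.j))
    return AnovaResult(F=float(f_stat), p=float(f_p),
                       df_between=k - 1, df_within=df_within, posthoc=posthoc)


def summarize(grouped: dict) -> pd.DataFrame:
    """Mean +/- SEM table: one row per group label.

    SEM = SD / sqrt(n) with the sample SD (ddof=1); a single-value group has
    an undefined SEM (NaN).
    """
    rows = []
    for label, values in grouped.items():
        v = np.asarray(values, dtype=float)
        n = len(v)
        sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"group": label, "mean": float(v.mean()) if n else np.nan,
                     "sem": sem, "n": n})
    return pd.DataFrame(rows).set_index("group")
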