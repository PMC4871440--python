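"""Behavioral measures and exact small-sample nonparametric statistics.

The retrieval index (RI) counts correctly anticipated targets in a
sequence-learning run; gene carriers are split by proximity to predicted
onset (YTO threshold) and by a median split of baseline RI.  Because the
group sizes in this design are tiny (<= 10 per group), the Spearman,
Wilcoxon signed-rank, and Mann-Whitney tests compute exact p-values by
full enumeration wherever feasible, falling back to the usual
tie-corrected normal/t approximations at larger n.
"""

from __future__ import annotations

import itertools
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import norm, rankdata, t as t_dist

SPEARMAN_EXACT_MAX_N = 10
WILCOXON_EXACT_MAX_N = 15
MANNWHITNEY_EXACT_MAX_N = 20  # pooled m + n


# ---------------------------------------------------------------------------
# behavioral measures and group splits

def retrieval_index(run_outcomes) -> int:
    """Number of correctly anticipated targets in one LEARN run."""
    outcomes = np.asarray(run_outcomes)
    if outcomes.size == 0:
        raise ValueError("empty trial log")
    if not np.isin(outcomes, (0, 1)).all():
        raise ValueError("trial outcomes must be binary (0/1)")
    return int(outcomes.sum())


def retrieval_index_timepoint(runs) -> float:
    """Run-averaged RI for one timepoint (the default aggregation rule)."""
    return float(np.mean([retrieval_index(r) for r in runs]))


def classify_onset(subject_table: pd.DataFrame,
                   yto_cut: float = 11.0) -> pd.Series:
    """nearPC if YTO <= cut (boundary inclusive), else farPC; carriers only."""
    phd = subject_table[subject_table["group"] == "pHD"]
    yto = pd.to_numeric(phd["yto"], errors="coerce")
    if yto.isna().any():
        raise ValueError("YTO missing for some gene carriers")
    labels = np.where(yto <= yto_cut, "nearPC", "farPC")
    return pd.Series(labels, index=phd["subject"].to_numpy(), name="onset_group")


def classify_learners(subject_table: pd.DataFrame,
                      median_override: float | None = None) -> pd.Series:
    """Median split of baseline RI: above the median -> good learners (GL),
    at or below -> bad learners (BL).  The printed split value of a report
    can be supplied via ``median_override``."""
    phd = subject_table[subject_table["group"] == "pHD"]
    ri = pd.to_numeric(phd["ri_tp1"], errors="coerce")
    if ri.isna().any():
        raise ValueError("baseline RI missing for some gene carriers")
    cut = float(np.median(ri)) if median_override is None else float(median_override)
    labels = np.where(ri > cut, "GL", "BL")
    return pd.Series(labels, index=phd["subject"].to_numpy(), name="learner_group")


# ---------------------------------------------------------------------------
# exact nonparametric tests

def _two_sided_from_tails(lo_tail: float, hi_tail: float) -> float:
    return float(min(1.0, 2.0 * min(lo_tail, hi_tail)))


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float(rx @ ry / denom)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Two-sided p is exact (full enumeration of the n! rank permutations)
    for n <= 10 and uses the t approximation above that.  Constant input
    gives (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), float("nan")
    rx, ry = rankdata(x), rankdata(y)
    rho = _rank_corr(rx, ry)

    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.fromiter(
            itertools.chain.from_iterable(itertools.permutations(range(n))),
            dtype=np.int8, count=n * factorial(n)).reshape(-1, n)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
        null = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        tstat = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * t_dist.sf(abs(tstat), n - 2))
    return rho, min(p, 1.0)


def wilcoxon_signed_rank(deltas) -> tuple[float, float]:
    """Wilcoxon signed-rank test (W = sum of positive ranks).

    Zeros are dropped; ties mid-ranked.  Two-sided p is exact (all 2^n
    sign assignments) for n <= 15 after zero removal, else the normal
    approximation with tie correction.  All-zero input gives (nan, nan).
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return float("nan"), float("nan")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if n <= WILCOXON_EXACT_MAX_N:
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)
        null = signs @ ranks
        p = _two_sided_from_tails(np.mean(null <= w_pos + 1e-12),
                                  np.mean(null >= w_pos - 1e-12))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        var = (n * (n + 1) * (2 * n + 1) / 24.0
               - np.sum(counts ** 3 - counts) / 48.0)
        z = (w_pos - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return w_pos, p


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U test; U counts pairs with x > y (ties count 1/2).

    Exact two-sided p by enumeration of all C(m+n, m) group assignments of
    the pooled ranks when m + n <= 20, else the tie-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = float(ranks[:m].sum())
    u = r_x - m * (m + 1) / 2.0

    if m + n <= MANNWHITNEY_EXACT_MAX_N:
        combos = np.array(list(itertools.combinations(range(m + n), m)))
        null = ranks[combos].sum(axis=1) - m * (m + 1) / 2.0
        p = _two_sided_from_tails(np.mean(null <= u + 1e-12),
                                  np.mean(null >= u - 1e-12))
        assert combos.shape[0] == comb(m + n, m)
    else:
        mean = m * n / 2.0
        N = m + n
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / (N * (N - 1))
        var = m * n / 12.0 * (N + 1 - tie_term)
        z = (u - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return u, p


def interaction_f(group_labels, deltas) -> tuple[float, int, int, float]:
    """Group x time interaction for a two-timepoint two-group design.

    With one TP2-TP1 delta per subject, the repeated-measures interaction
    reduces to the pooled-variance two-sample t test on the deltas:
    F = t^2 with df (1, n - 2).  Zero pooled variance gives F = inf when
    the group means differ (degenerate flag) and F = 0 when they agree.
    """
    labels = np.asarray(group_labels)
    d = np.asarray(deltas, dtype=float)
    groups = pd.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two groups are required")
    a, b = d[labels == groups[0]], d[labels == groups[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two subjects")
    n = a.size + b.size
    df2 = n - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df2
    diff = a.mean() - b.mean()
    if pooled == 0:
        F = np.inf if diff != 0 else 0.0
        return float(F), 1, df2, 0.0 if diff != 0 else 1.0
    tstat = diff / np.sqrt(pooled * (1 / a.size + 1 / b.size))
    F = tstat ** 2
    return float(F), 1, df2, float(f_dist.sf(F, 1, df2))


def group_summary(values: pd.DataFrame, by: str) -> pd.DataFrame:
    """mean +- SD table per group, for report output."""
    num = values.select_dtypes("number")
    agg = values.groupby(by)[num.columns].agg(["mean", "std", "count"])
    return agg
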