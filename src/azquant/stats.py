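"""Group statistics: the nonparametric/parametric test battery applied to
per-sample summaries, with Benjamini–Hochberg FDR for post-hoc families.

All tests are two-sided. The Mann–Whitney U test is exact (full permutation
distribution of the rank sum) for small tie-free samples and falls back to
a tie-corrected normal approximation otherwise; which p-value was computed
is always recorded in the result. BH adjustment is the original step-up
procedure at q = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "rm_anova_oneway",
    "oneway_anova_log",
    "bh_fdr",
    "pearson_r",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    ns: tuple[int, ...]
    method: str = ""
    effect_direction: str = ""
    adjusted_p: float | None = None
    family: str | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"p-value out of range: {self.pvalue}")


def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks and tie group sizes."""
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    return ranks, counts


def _exact_u_pmf(n: int, m: int) -> np.ndarray:
    """Null PMF of the Mann–Whitney U statistic for tie-free samples of
    sizes n and m, via the counting recurrence
    c(i, j, u) = c(i−1, j, u−j) + c(i, j−1, u)
    (condition on whether the largest pooled value is an x or a y);
    equivalent to full enumeration of all C(n+m, n) labelings."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def counts(i: int, j: int) -> tuple[float, ...]:
        if i == 0 or j == 0:
            return (1.0,)
        out = [0.0] * (i * j + 1)
        for u, v in enumerate(counts(i - 1, j)):
            out[u + j] += v
        for u, v in enumerate(counts(i, j - 1)):
            out[u] += v
        return tuple(out)

    f = np.array(counts(n, m))
    return f / f.sum()


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
) -> TestResult:
    """Two-sided Mann–Whitney U test.

    ``mode='exact'`` uses the full permutation null (valid only without
    ties); ``'normal_tie_corrected'`` uses the normal approximation with
    mid-ranks, tie-corrected variance and continuity correction; ``'auto'``
    picks exact when n_x + n_y ≤ 12 and the data are tie-free. With zero
    null variance (all values identical) p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n + m
    if mode == "auto":
        mode = "exact" if (n + m <= 12 and not has_ties) else "normal_tie_corrected"
    ranks, tie_counts = _rank_with_ties(pooled)
    rx = ranks[:n].sum()
    u_x = rx - n * (n + 1) / 2.0  # number of (x > y) pairs, ties as 1/2
    direction = "x>y" if u_x > n * m / 2 else ("x<y" if u_x < n * m / 2 else "none")

    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        pmf = _exact_u_pmf(n, m)
        u = int(round(u_x))
        lower = pmf[: u + 1].sum()
        upper = pmf[u:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        method = "exact (full permutation null)"
    elif mode == "normal_tie_corrected":
        mean_u = n * m / 2.0
        N = n + m
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
        var_u = n * m / 12.0 * ((N + 1) - tie_term)
        if var_u <= 0:
            p = 1.0
            z = 0.0
        else:
            z = (u_x - mean_u - math.copysign(0.5, u_x - mean_u)) / math.sqrt(var_u)
            if u_x == mean_u:
                z = 0.0
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal approximation, tie-corrected, continuity-corrected"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(
        test="mann-whitney-u",
        statistic=float(u_x),
        pvalue=float(p),
        ns=(n, m),
        method=method,
        effect_direction=direction,
        notes={"ties": bool(has_ties)},
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected, chi-square p with k−1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    h, p = sps.kruskal(*arrays)
    return TestResult(
        test="kruskal-wallis",
        statistic=float(h),
        pvalue=float(p),
        ns=tuple(len(a) for a in arrays),
        method=f"chi-square approximation, df={len(arrays) - 1}, tie-corrected",
    )


def rm_anova_oneway(table: np.ndarray) -> TestResult:
    """Repeated-measures one-way ANOVA on a complete subjects × conditions
    table.

    F = MS_condition / MS_(condition × subject) with df (k−1, (k−1)(n−1)).
    No sphericity correction is applied (a note flags k > 2, where
    sphericity can matter).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a complete table with >=2 subjects and >=2 conditions")
    if not np.isfinite(t).all():
        raise ValueError("table must be complete (no missing values)")
    n, k = t.shape
    grand = t.mean()
    ss_cond = n * ((t.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((t.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((t - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f_stat = 0.0 if ms_cond == 0 else np.inf
        p = 1.0 if ms_cond == 0 else 0.0
    else:
        f_stat = ms_cond / ms_err
        p = float(sps.f.sf(f_stat, df_cond, df_err))
    notes = {"sphericity_correction": "none"}
    if k > 2:
        notes["sphericity_flag"] = "k > 2: sphericity assumed, not tested"
    return TestResult(
        test="rm-anova-oneway",
        statistic=float(f_stat),
        pvalue=float(p),
        ns=(n, k),
        method=f"F({df_cond}, {df_err})",
        notes=notes,
    )


def oneway_anova_log(groups: Sequence[Sequence[float]], log_base: float = 2.0) -> TestResult:
    """Classic (pooled-variance) one-way ANOVA on log-transformed data.

    Errors on nonpositive values; the test is invariant to a common
    multiplicative rescaling of all data (a log-shift).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for a in arrays:
        if (a <= 0).any():
            raise ValueError("log-transformed ANOVA requires strictly positive data")
    logs = [np.log(a) / np.log(log_base) for a in arrays]
    if np.concatenate(logs).std() == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*logs)
        if np.isnan(f_stat):
            f_stat, p = 0.0, 1.0
    return TestResult(
        test="oneway-anova-log",
        statistic=float(f_stat),
        pvalue=float(p),
        ns=tuple(len(a) for a in arrays),
        method=f"pooled-variance ANOVA on log{log_base:g} data",
    )


def bh_fdr(
    pvalues: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment at rate ``q``.

    Returns ``(adjusted_p, reject)``. Adjusted p_i = min over j ≥ i of
    m·p_(j)/j with monotonicity enforced; the rejection set is every
    hypothesis up to the largest i with p_(i) ≤ i·q/m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson's correlation coefficient R."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of equal length >= 3")
    return float(sps.pearsonr(x, y).statistic)
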