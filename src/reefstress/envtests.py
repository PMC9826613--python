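"""Paired and two-sample comparisons of environmental series between years.

The year-to-year design is repeated-measures with calendar month-day as
the block: the Friedman test (degenerate but faithful with k = 2
treatments) for daily mean/max/min and DTR, the Wilcoxon signed-rank
test for day-paired cumulative series (running mDHW, max-3-day
temperature), the Mann-Whitney U test for unpaired daily series
(sunshine hours), and McNemar's test for the paired daily exceedance
indicator behind the acute index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, EmptyInputError

__all__ = [
    "TestResult",
    "friedman_test",
    "friedman_paired",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "mcnemar_test",
    "heating_rate2_window",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``n`` is the number of usable observations after the method's own
    exclusion rules (blocks dropped, zero differences removed, ...).
    """

    statistic: float
    p_value: float
    method: str
    n: int
    df: int | None = None
    z: float | None = None

    def to_dict(self):
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "n": self.n,
            "df": self.df,
            "z": self.z,
        }


def friedman_test(blocks: np.ndarray) -> TestResult:
    """Friedman rank test on an (n_blocks × k_treatments) array.

    Within-block average ranks with the standard tie correction; the
    statistic is referred to χ² with k−1 df.  Blocks containing missing
    values are dropped with a warning.  With every block fully tied the
    statistic is defined as 0.
    """
    x = np.asarray(blocks, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D array with >=2 treatments")
    keep = ~np.isnan(x).any(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} blocks with missing values", stacklevel=2)
        x = x[keep]
    n, k = x.shape
    if n < 2:
        raise DegenerateDataError("need >=2 complete blocks")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    num = 12.0 * np.sum((col_sums - n * (k + 1) / 2.0) ** 2) / (n * k * (k + 1))
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    corr = 1.0 - tie_sum / (n * k * (k**2 - 1))
    stat = 0.0 if corr == 0.0 else num / corr
    p = float(stats.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return TestResult(float(stat), p, "Friedman rank test", n, df=k - 1)


def friedman_paired(paired: pd.DataFrame, variable: str) -> TestResult:
    """Friedman test on a paired daily table for one variable.

    ``variable`` is a prefix such as ``'mean_temp'`` or ``'dtr'``; the two
    year columns ``<variable>_a`` / ``<variable>_b`` form the treatments,
    month-day rows the blocks.
    """
    cols = [c for c in paired.columns if c.startswith(variable + "_")]
    if len(cols) < 2:
        raise ValueError(f"no paired columns for {variable!r}")
    return friedman_test(paired[cols].to_numpy(dtype=float))


def _wplus_exact_sf_cdf(ranks: np.ndarray, w: float):
    """Exact P(W+ <= w) and P(W+ >= w) by dynamic programming.

    Works with average ranks (multiples of 0.5) by counting on a
    2×-scaled integer grid over all 2^n sign assignments.
    """
    scaled = np.rint(2.0 * ranks).astype(int)
    total = int(scaled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in scaled:
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    ws = int(round(2.0 * w))
    cdf = float(counts[: ws + 1].sum())
    sf = float(counts[ws:].sum())
    return cdf, sf


def wilcoxon_signed_rank(a, b=None, exact_max_n: int = 25) -> TestResult:
    """Wilcoxon signed-rank test on pairs (a, b) or differences ``a``.

    Zero differences are dropped; tied absolute differences get average
    ranks.  The two-sided p-value is exact (full enumeration of sign
    patterns via dynamic programming, valid under ties) for n ≤
    ``exact_max_n``, otherwise a normal approximation with continuity
    and tie corrections.  All differences zero raises
    :class:`~reefstress.errors.DegenerateDataError`.
    """
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= exact_max_n:
        cdf, sf = _wplus_exact_sf_cdf(ranks, w_plus)
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "Wilcoxon signed-rank (exact)"
        z = None
    else:
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        # continuity correction toward the mean
        num = w_plus - mu
        num -= 0.5 * np.sign(num)
        z = float(num / np.sqrt(var))
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "Wilcoxon signed-rank (normal approx.)"
    return TestResult(w_plus, p, method, n, z=z)


def _u_exact_sf_cdf(n1: int, n2: int, u: int):
    """Exact cdf/sf of the Mann-Whitney U statistic (no ties).

    Counts arrangements by the recurrence P(i, j) = q^j P(i-1, j)
    + P(i, j-1): the largest remaining value is either from sample a
    (beating all j remaining b's) or from sample b.
    """
    maxu = n1 * n2
    # table[j] = counting polynomial for (current i, j) as coefficient array
    table = [np.zeros(maxu + 1) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        table[j][0] = 1.0  # i = 0
    for _i in range(1, n1 + 1):
        new = [np.zeros(maxu + 1) for _ in range(n2 + 1)]
        new[0][0] = 1.0  # j = 0
        for j in range(1, n2 + 1):
            shifted = np.zeros(maxu + 1)
            shifted[j:] = table[j][: maxu + 1 - j]
            new[j] = shifted + new[j - 1]
        table = new
    f = table[n2]
    f /= f.sum()
    cdf = float(f[: u + 1].sum())
    sf = float(f[u:].sum())
    return cdf, sf


def mann_whitney_u(a, b, continuity: bool = True, exact_max_n: int = 12) -> TestResult:
    """Mann-Whitney U test of two independent samples.

    Reports U for sample ``a`` and the tie-corrected normal-approximation
    Z.  The two-sided p-value is exact when both samples have ≤
    ``exact_max_n`` observations and there are no cross-sample ties,
    otherwise from the normal approximation (continuity-corrected by
    default).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise EmptyInputError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    nt = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((nt) * (nt - 1))
    var = n1 * n2 / 12.0 * (nt + 1 - tie_term)
    if var > 0:
        num = u1 - mu
        if continuity:
            num -= 0.5 * np.sign(num)
        z = float(num / np.sqrt(var))
    else:
        z = 0.0
    has_ties = len(tie_counts) < nt
    if n1 <= exact_max_n and n2 <= exact_max_n and not has_ties:
        cdf, sf = _u_exact_sf_cdf(n1, n2, int(round(u1)))
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "Mann-Whitney U (exact)"
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "Mann-Whitney U (normal approx.)"
    return TestResult(u1, p, method, nt, z=z)


def mcnemar_test(table, correction: bool = True) -> TestResult:
    """McNemar's test on a 2×2 paired-classification count table.

    Uses the discordant cells b = table[0][1], c = table[1][0]:
    χ² = (|b−c|−1)²/(b+c) with the continuity correction (default) or
    (b−c)²/(b+c) without, df = 1.  b + c = 0 raises
    :class:`~reefstress.errors.DegenerateDataError`.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    b, c = t[0, 1], t[1, 0]
    if b + c == 0:
        raise DegenerateDataError("no discordant pairs (b + c = 0)")
    if correction:
        stat = (abs(b - c) - 1.0) ** 2 / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    stat = max(0.0, float(stat))
    p = float(stats.chi2.sf(stat, 1))
    label = "McNemar (continuity-corrected)" if correction else "McNemar"
    return TestResult(stat, p, label, int(t.sum()), df=1)


def heating_rate2_window(daily: pd.DataFrame):
    """Span over which the pre-peak heating-rate slope is estimated.

    Finds the ISO (Monday-start) calendar week with the maximum mean of
    daily mean temperature (ties broken to the earliest week) and
    returns the 3-calendar-month span ending the day before that week
    starts.  If the span would begin before the record does, it is
    truncated to the first observed day with a warning.
    """
    d = daily[daily["valid"]]
    if len(d) < 7:
        raise EmptyInputError("need at least one complete week")
    idx = pd.DatetimeIndex(pd.to_datetime(list(d.index)))
    week_start = idx - pd.to_timedelta(idx.weekday, unit="D")
    weekly = d["mean_temp"].groupby(week_start.date).mean()
    best = weekly.idxmax()  # idxmax takes the first maximum -> earliest week
    best = pd.Timestamp(best)
    start = (best - pd.DateOffset(months=3)).date()
    end = (best - pd.Timedelta(days=1)).date()
    first = min(d.index)
    if start < first:
        warnings.warn("heating-rate window truncated at start of record", stacklevel=2)
        start = first
    return start, end
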