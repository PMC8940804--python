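"""Exact and rank-based nonparametric tests for small behavioural samples.

The study's group sizes (6-12 cows per punisher) sit squarely in the range
where large-sample approximations of rank tests are unreliable, so each
routine here computes the exact conditional null distribution by complete
enumeration (implemented as integer dynamic programming over the observed
mid-ranks, which handles ties exactly) up to a size threshold, and falls
back to the tie-corrected normal approximation above it.

Degenerate inputs that leave a statistic undefined (all paired differences
zero, a zero-variance vector in a rank correlation) are returned as an
undefined :class:`TestResult` carrying an explanatory note, never as a
silent NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

#: Sample-size ceilings below which the exact null distribution is used.
EXACT_MAX_SIGNED_RANK = 15
EXACT_MAX_RANK_SUM = 16
EXACT_MAX_SPEARMAN = 8


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``statistic`` and ``p_value`` are ``None`` when the statistic is
    undefined for the input (see ``note``); ``method`` records whether the
    p-value came from exact enumeration or an approximation.
    """

    statistic_name: str
    statistic: Optional[float]
    p_value: Optional[float]
    n_effective: int
    method: str
    note: str = ""

    @property
    def defined(self) -> bool:
        return self.statistic is not None and self.p_value is not None

    def as_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_effective": self.n_effective,
            "method": self.method,
            "note": self.note,
        }


def _twosided_from_counts(counts: np.ndarray, observed: int) -> float:
    """Two-sided p from an enumerated integer-valued null distribution.

    ``counts[s]`` is the number of enumeration outcomes with statistic value
    ``s``; the conventional doubled one-tail p, capped at 1.
    """
    total = counts.sum()
    lo = counts[: observed + 1].sum() / total
    hi = counts[observed:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def _scaled_int_ranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks doubled to integers (mid-ranks are multiples of 1/2)."""
    r = 2.0 * stats.rankdata(values)
    ri = np.rint(r).astype(np.int64)
    if not np.allclose(r, ri):
        raise AssertionError("doubled mid-ranks must be integral")
    return ri


def wilcoxon_signed_rank(differences: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Exact zeros are dropped before ranking.  For n <= 15 the p-value comes
    from the exact distribution of V (sum of positive ranks) over all 2^n
    sign assignments of the observed mid-ranks; above that, the
    tie-corrected normal approximation is used.  All-zero differences give
    an undefined result.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        raise ValueError("differences must be one-dimensional")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult("V", None, None, 0, "exact", note="all differences zero")
    ranks2 = _scaled_int_ranks(np.abs(d))  # doubled mid-ranks, integers
    v2 = int(ranks2[d > 0].sum())  # doubled V statistic
    v = v2 / 2.0
    if n <= EXACT_MAX_SIGNED_RANK:
        total = int(ranks2.sum())
        counts = np.zeros(total + 1, dtype=np.int64)
        counts[0] = 1
        for r in ranks2:  # DP over sign inclusion of each rank
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        p = _twosided_from_counts(counts, v2)
        return TestResult("V", v, p, n, "exact")
    mean = n * (n + 1) / 4.0
    # variance with tie correction: sum of squared ranks / 4
    var = float(np.sum((ranks2 / 2.0) ** 2)) / 4.0
    z = (v - mean) / math.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult("V", v, p, n, "approximate")


def wilcoxon_rank_sum(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The reported statistic is W = (rank sum of group a) - n_a(n_a+1)/2,
    i.e. the Mann-Whitney U of the first group.  Exact enumeration over all
    C(n_a+n_b, n_a) rank splits when the combined size is <= 16, handling
    ties through mid-ranks; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    ranks2 = _scaled_int_ranks(np.concatenate([a, b]))
    rs2 = int(ranks2[:na].sum())  # doubled rank sum of group a
    w = rs2 / 2.0 - na * (na + 1) / 2.0
    if n <= EXACT_MAX_RANK_SUM:
        total = int(ranks2.sum())
        # ways[k, s]: subsets of size k with doubled-rank sum s
        ways = np.zeros((na + 1, total + 1), dtype=np.int64)
        ways[0, 0] = 1
        for r in ranks2:
            for k in range(min(na, 1_000), 0, -1):
                ways[k, r:] += ways[k - 1, : total + 1 - r]
        p = _twosided_from_counts(ways[na], rs2)
        return TestResult("W", w, p, n, "exact")
    mean_rs = na * (n + 1) / 2.0
    ranks = ranks2 / 2.0
    var = na * nb * np.var(ranks, ddof=0) * n / (n - 1)
    z = (rs2 / 2.0 - mean_rs) / math.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult("W", w, p, n, "approximate")


def fisher_freeman_halton(table) -> TestResult:
    """Freeman-Halton (Fisher) exact test on an r x c contingency table.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more probable than the
    observed table.
    """
    t = np.asarray(table)
    if not np.issubdtype(t.dtype, np.integer):
        tf = np.asarray(table, dtype=float)
        if not np.allclose(tf, np.rint(tf)):
            raise ValueError("counts must be integers")
        t = np.rint(tf).astype(np.int64)
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if t.sum() == 0:
        raise ValueError("table must contain at least one count")
    # empty rows/columns carry no information; a degenerate table is
    # compatible with exactly one margin-preserving configuration
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return TestResult("p_FH", 1.0, 1.0, int(t.sum()), "exact", note="degenerate table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    lg_margins = (
        sum(math.lgamma(r + 1) for r in rows)
        + sum(math.lgamma(c + 1) for c in cols)
        - math.lgamma(n + 1)
    )
    # cell-only part of the observed log-probability (margin constant omitted,
    # consistently with the enumeration accumulator below)
    log_obs = -sum(math.lgamma(x + 1) for x in t.ravel())

    r, c = t.shape
    p_extreme = 0.0

    def recurse(row: int, remaining_cols: np.ndarray, log_acc: float) -> None:
        nonlocal p_extreme
        if row == r - 1:
            lp = log_acc - sum(math.lgamma(x + 1) for x in remaining_cols)
            if lp <= log_obs + 1e-10:
                p_extreme += math.exp(lp + lg_margins)
            return

        target = rows[row]

        def fill(col: int, left: int, cells: list[int]) -> None:
            if col == c - 1:
                if left > remaining_cols[col]:
                    return
                recurse(
                    row + 1,
                    remaining_cols - np.array(cells + [left]),
                    log_acc
                    - sum(math.lgamma(x + 1) for x in cells)
                    - math.lgamma(left + 1),
                )
                return
            for v in range(min(left, remaining_cols[col]) + 1):
                fill(col + 1, left - v, cells + [v])

        fill(0, int(target), [])

    recurse(0, cols.copy(), 0.0)
    return TestResult("p_FH", float(min(p_extreme, 1.0)), float(min(p_extreme, 1.0)), n, "exact")


def friedman_block(values, treatment, block) -> TestResult:
    """Friedman rank test across treatments with matched blocks.

    Each complete block (one value per treatment) contributes a within-block
    ranking; blocks missing a treatment or holding duplicates are dropped
    with a warning.  The chi-square statistic uses mid-ranks with the
    standard tie correction (delegated to scipy).
    """
    import pandas as pd

    df = pd.DataFrame({"value": values, "treatment": treatment, "block": block})
    levels = sorted(df["treatment"].unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 treatments")
    complete = []
    for b, sub in df.groupby("block"):
        counts = sub["treatment"].value_counts()
        if sorted(counts.index) == levels and (counts == 1).all():
            complete.append(sub.set_index("treatment")["value"].reindex(levels).to_numpy())
        else:
            warnings.warn(f"dropping incomplete block {b!r}", stacklevel=2)
    if len(complete) < 2:
        raise ValueError("need at least 2 complete blocks")
    mat = np.asarray(complete, dtype=float)  # blocks x treatments
    within_var = np.ptp(mat, axis=1)
    if np.all(within_var == 0):  # every block fully tied: no evidence at all
        return TestResult("chi2", 0.0, 1.0, mat.shape[0], "approximate", note="all blocks tied")
    chi2, p = stats.friedmanchisquare(*mat.T)
    return TestResult("chi2", float(chi2), float(p), mat.shape[0], "approximate")


def spearman_safe(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with explicit null-variance handling.

    Returns an undefined result flagged ``"null variance"`` when either
    vector is constant (the correlation does not exist there).  The p-value
    is exact by permutation enumeration for n <= 8, otherwise from the t
    approximation.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    n = xv.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return TestResult("rho", None, None, n, "exact", note="null variance")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.mean(rx * ry))
    if n <= EXACT_MAX_SPEARMAN:
        perms = np.array(list(permutations(range(n))))
        rhos = (rx[perms] * ry).mean(axis=1)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return TestResult("rho", rho, p, n, "exact")
    if abs(rho) >= 1.0:
        return TestResult("rho", rho, 0.0, n, "approximate")
    tstat = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = float(min(1.0, 2.0 * stats.t.sf(abs(tstat), df=n - 2)))
    return TestResult("rho", rho, p, n, "approximate")


def bonferroni_adjust(p_values, m: Optional[int] = None):
    """Multiply p-values by the number of comparisons, capping at 1."""
    p = np.asarray(p_values, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    out = np.minimum(1.0, p * m)
    return float(out[0]) if scalar else out
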