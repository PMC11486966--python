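"""Exact small-sample hypothesis tests and multiple-testing helpers.

Two-tailed Fisher's exact test with the point-probability definition of the
two-sided p value (sum over all tables with the observed margins whose
hypergeometric probability does not exceed that of the observed table), and
a two-sided Mann–Whitney U test with an exact permutation null for small
samples (handling ties through midranks) and a tie-corrected normal
approximation with continuity correction for larger ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

POINT_PROB_TOL = 1e-12


@dataclass
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("contingency table must have a positive margin")

    @classmethod
    def from_rows(cls, rows) -> "ContingencyTable":
        (a, b), (c, d) = rows
        return cls(int(a), int(b), int(c), int(d))


def fisher_exact_two_tailed(table) -> float:
    """Two-sided Fisher exact p value (point-probability method).

    ``table`` is a :class:`ContingencyTable` or a 2x2 nested sequence. With a
    zero row or column margin the test is degenerate and returns 1.0.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable.from_rows(table)
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, a + b + c + d
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = sps.hypergeom.pmf(a, n, col1, row1)
    return float(min(pmf[pmf <= p_obs + POINT_PROB_TOL].sum(), 1.0))


class MWResult(NamedTuple):
    u: float        # U statistic of the first sample
    p_value: float
    method: str     # 'exact' | 'asymptotic'


def mann_whitney_two_sided(x: Sequence[float], y: Sequence[float],
                           exact_below: int = 20) -> MWResult:
    """Two-sided Mann–Whitney U test.

    For a combined sample size up to ``exact_below`` the null distribution of
    U is enumerated over all assignments of pooled midranks (exact even with
    ties); the two-sided p value is ``2 * min(P(U <= u), P(U >= u))`` capped
    at 1. Larger samples use the tie-corrected normal approximation with
    continuity correction. Identical samples give p = 1.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise ValidationError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.array(x + y)
    ranks = sps.rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    if np.ptp(pooled) == 0:
        return MWResult(u, 1.0, "exact")

    if nx + ny <= exact_below:
        n = nx + ny
        total = 0
        le = 0
        ge = 0
        for combo in itertools.combinations(range(n), nx):
            u_perm = ranks[list(combo)].sum() - nx * (nx + 1) / 2.0
            total += 1
            if u_perm <= u + 1e-9:
                le += 1
            if u_perm >= u - 1e-9:
                ge += 1
        p = min(2.0 * min(le, ge) / total, 1.0)
        return MWResult(u, p, "exact")

    mu = nx * ny / 2.0
    tie_counts = np.array([np.sum(pooled == v) for v in np.unique(pooled)])
    n = nx + ny
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return MWResult(u, 1.0, "asymptotic")
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    p = min(2.0 * sps.norm.sf(max(z, 0.0)), 1.0)
    return MWResult(u, float(p), "asymptotic")


def adjust_pvalues(pvalues: Sequence[float], method: str = "bonferroni") -> list[float]:
    """Multiple-testing correction: 'bonferroni' or 'benjamini-hochberg'."""
    mapping = {"bonferroni": "bonferroni", "benjamini-hochberg": "fdr_bh"}
    if method not in mapping:
        raise ValidationError(f"unknown correction method {method!r}")
    return list(multipletests(list(pvalues), method=mapping[method])[1])
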