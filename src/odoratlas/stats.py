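"""Shared statistical helpers.

Centralizes the paired sign-rank convention used by every comparison in
the package: Wilcoxon signed-rank, two-sided, zero differences dropped
(the classic Wilcoxon treatment), exact null distribution for n <= 25
when the |differences| are tie-free, normal approximation with
continuity correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

EXACT_MAX_N = 25


@dataclass(frozen=True)
class SignRankResult:
    n: int                 # non-zero differences actually tested
    statistic: float       # smaller of the two signed-rank sums
    p_value: float | None  # None when no non-zero differences remain
    method: str


def sign_rank_test(differences) -> SignRankResult:
    """Two-sided Wilcoxon signed-rank test of paired differences vs 0."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return SignRankResult(n=0, statistic=0.0, p_value=None, method="degenerate")
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= EXACT_MAX_N and not has_ties:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
        method = "normal_approx"
    return SignRankResult(
        n=n, statistic=float(res.statistic), p_value=float(res.pvalue), method=method
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided p-value."""
    res = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)
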