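"""Statistical tests used throughout the pipeline.

Group comparisons in this field are almost always two-sided Wilcoxon
rank-sum tests on per-animal summary values (each worm is one n), and
survival comparisons are Fisher's exact test on a 2x2 alive/dead table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["RankSumResult", "wilcoxon_rank_sum", "fisher_exact_2x2"]


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Wilcoxon rank-sum test result.

    statistic is the rank sum W of the first sample (ranks over the pooled
    data); method records whether the exact null distribution or the
    tie-corrected normal approximation was used.
    """

    statistic: float
    p_value: float
    method: str


def wilcoxon_rank_sum(x, y, *, exact_max_n: int = 20) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The exact null distribution is used when both samples have fewer than
    ``exact_max_n`` observations and the pooled sample is tie-free;
    otherwise the normal approximation with tie correction is used.

    Parameters
    ----------
    x, y : array-like
        Per-animal summary values for the two groups.

    Returns
    -------
    RankSumResult
        Rank sum of ``x``, two-sided p-value and the method used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    use_exact = tie_free and x.size < exact_max_n and y.size < exact_max_n
    method = "exact" if use_exact else "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    # U1 -> rank sum of the first sample
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return RankSumResult(statistic=w, p_value=float(res.pvalue), method=method)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Returns (odds_ratio, p_value).
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("table counts must be non-negative")
    odds, p = _sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)
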