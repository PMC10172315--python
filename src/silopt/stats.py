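"""Statistical procedures shared by every analysis stage.

Three procedures cover all hypothesis testing in the pipeline: the
two-sided Wilcoxon rank-sum (Mann-Whitney) test for two-group comparisons,
Benjamini-Hochberg step-up adjustment for multiple testing, and Spearman
rank correlation.  Each wraps the corresponding scipy/statsmodels routine
and records which method (exact enumeration vs. normal approximation) was
used, so downstream TSVs carry the provenance of every p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "wilcoxon_rank_sum", "bh_adjust", "spearman"]

#: combined sample size at or below which the exact null distribution is
#: enumerated (when the data are untied)
EXACT_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    n_x: int
    n_y: int


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = EXACT_LIMIT,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    The exact permutation null is enumerated when the combined sample is
    small (``n_x + n_y <= exact_limit``) and tie-free; otherwise the normal
    approximation with midranks, tie correction and continuity correction
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size + y.size <= exact_limit:
        method = "exact"
        res = _sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
    else:
        method = "normal_approx"
        res = _sps.mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic", use_continuity=True
        )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n_x=int(x.size),
        n_y=int(y.size),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of midranks).

    Returns NaN when either vector is constant (the correlation is
    undefined there, reported as missing rather than raised).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan")
    rho = _sps.spearmanr(x, y).statistic
    return float(rho)
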