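"""Rank-based group comparisons with FDR control.

Kruskal-Wallis across the four clinical groups, Wilcoxon rank-sum
(Mann-Whitney U) for pairwise and F1-vs-F2 comparisons — exact by
enumeration for small tie-free samples, normal approximation with tie
and continuity correction otherwise — and Benjamini-Hochberg step-up
q-values.  Two-sided throughout, alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA = 0.05
EXACT_WILCOXON_MAX_N = 12  # exact enumeration up to this combined sample size


@dataclass(frozen=True, slots=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    n_per_group: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def kruskal_wallis(groups: list, labels: list[str] | None = None) -> TestResult:
    """Kruskal-Wallis H test on k independent samples.

    Mid-rank H with tie correction, p from chi-square with k-1 df.  The
    degenerate all-identical case (tie correction divides by zero) is
    reported as H = 0, p = 1 by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        logger.info("kruskal_wallis: all observations identical; H=0, p=1 by convention")
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    return TestResult(
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        groups=tuple(labels) if labels else tuple(f"g{i}" for i in range(len(arrays))),
        n_per_group=tuple(a.size for a in arrays),
    )


def wilcoxon_rank_sum(
    a, b, exact: bool | None = None, labels: tuple[str, str] = ("a", "b")
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact two-sided p by enumeration when n_a + n_b <= 12 with no ties
    (or when `exact=True` is forced and there are no ties); otherwise
    the normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if exact is None:
        exact = (a.size + b.size) <= EXACT_WILCOXON_MAX_N and not has_ties
    if exact and has_ties:
        logger.warning("ties present; falling back to normal approximation")
        exact = False
    if exact:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(res.pvalue)
    if np.isnan(p):  # zero tie-corrected variance: no evidence either way
        p = 1.0
    return TestResult(
        test_name="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        p_value=min(p, 1.0),
        groups=labels,
        n_per_group=(a.size, b.size),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
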