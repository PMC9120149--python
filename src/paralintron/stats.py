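"""Statistical tests used across the analyses.

All tests are two-sided.  Contingency tables of categorical variables
are tested with a Pearson χ² test without continuity correction
(classical degrees of freedom), or Fisher's exact test for 2×2 tables
(two-sided by the probability-mass rule).  Distributional differences
(relative intron positions, branch lengths) use the two-sample
Kolmogorov–Smirnov test.  P values from families of comparisons are
adjusted with the Benjamini–Hochberg false-discovery-rate procedure,
and binomial fractions are reported with Wilson score intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    df: Optional[int] = None
    p_adj: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p value out of range: {self.p}")
        if self.p_adj is not None and self.p_adj < self.p - 1e-12:
            raise ValueError("adjusted p below raw p")


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero margin")
    return arr


def chi2_contingency(table) -> TestResult:
    """Pearson χ² contingency test, no continuity correction."""
    arr = _as_table(table)
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult(statistic=float(stat), p=float(p), df=int(df), method="chi2")


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test for a 2×2 table.

    The two-sided p value sums the probabilities of all tables with the
    same margins whose hypergeometric probability does not exceed that
    of the observed table.  The statistic reported is the sample odds
    ratio.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(statistic=float(odds), p=float(p), method="fisher")


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test.

    Exact p value when ``len(x) * len(y) <= 10_000``, asymptotic
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if x.size * y.size <= 10_000 else "asymp"
    res = sps.ks_2samp(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), method="ks")


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p values, input order kept."""
    pvals = list(pvals)
    if not pvals:
        return []
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(p) for p in adjusted]


def wilson_interval(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial fraction."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    lo, hi = proportion_confint(x, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)


def phase_distribution(
    phases_by_category: dict[str, Iterable[int]],
) -> tuple[dict[str, tuple[int, int, int]], list[tuple[str, str, TestResult]]]:
    """Phase counts per intron category plus all pairwise comparisons.

    Each category's phases are binned into counts ``(n0, n1, n2)``;
    every pair of categories is compared with a χ² test on the 2×3
    table, and the p values of the comparison family are BH-adjusted.
    Empty categories are dropped with a warning.
    """
    counts: dict[str, tuple[int, int, int]] = {}
    for category, phases in phases_by_category.items():
        phases = list(phases)
        if not phases:
            warnings.warn(f"phase category {category!r} is empty; dropped")
            continue
        if any(ph not in (0, 1, 2) for ph in phases):
            raise ValueError(f"invalid phase in category {category!r}")
        counts[category] = (
            sum(1 for ph in phases if ph == 0),
            sum(1 for ph in phases if ph == 1),
            sum(1 for ph in phases if ph == 2),
        )
    comparisons = []
    pairs = list(combinations(sorted(counts), 2))
    raw = []
    for a, b in pairs:
        result = chi2_contingency([counts[a], counts[b]])
        raw.append(result)
    adjusted = bh_fdr([r.p for r in raw])
    for (a, b), result, p_adj in zip(pairs, raw, adjusted):
        result.p_adj = p_adj
        comparisons.append((a, b, result))
    return counts, comparisons
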