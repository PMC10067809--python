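"""Two-sample tests for sperm-trait comparisons between ecotypes.

Sperm counts are right-skewed, so concentration and total-sperm comparisons
use the Mann-Whitney (Wilcoxon rank-sum) test; velocity parameters (VCL, VAP)
are compared with t-tests. There is no automatic test picker: the caller
chooses, matching how the original analysis was done.

The reported Mann-Whitney statistic W is the number of (x, y) pairs with
x > y plus half the ties, with the LF group passed first — the convention
under which the study's printed W values are reproduced. The p-value is exact
(full enumeration of rank arrangements) for small untied samples and a
normal approximation with tie and continuity corrections otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["TwoSampleResult", "mann_whitney", "t_test"]

EXACT_MAX_N = 10


@dataclass(frozen=True)
class TwoSampleResult:
    test: str
    statistic: float
    p_two_sided: float
    n1: int
    n2: int
    df: Optional[float] = None
    labels: tuple = ("group1", "group2")

    def __post_init__(self) -> None:
        if not 0 <= self.p_two_sided <= 1:
            raise ValueError("p-value outside [0, 1]")


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney(
    x: Sequence[float], y: Sequence[float], labels: tuple = ("LF", "LP")
) -> TwoSampleResult:
    """Mann-Whitney rank-sum test, W computed for the first group.

    Exact enumeration p-value when both groups have <= 10 untied values,
    otherwise the tie- and continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    exact = x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not _has_ties(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TwoSampleResult(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        n1=int(x.size),
        n2=int(y.size),
        labels=labels,
    )


def t_test(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "student",
    labels: tuple = ("LF", "LP"),
) -> TwoSampleResult:
    """Two-sample t-test: pooled-variance Student (default) or Welch."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    equal_var = variant == "student"
    if equal_var:
        pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
            x.size + y.size - 2
        )
        if pooled == 0:
            raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return TwoSampleResult(
        test=f"t_{variant}",
        statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        n1=int(x.size),
        n2=int(y.size),
        df=float(res.df),
        labels=labels,
    )
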