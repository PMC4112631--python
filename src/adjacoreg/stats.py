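"""Small self-contained genetics statistics.

Mendelian segregation goodness-of-fit (chi-square against an expected
phenotype ratio, e.g. 1 mutant : 3 wild type for non-complementation in an
F1 of two heterozygotes), group mean +/- SEM summaries, display fold
effects, and two-group t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SegregationObservation",
    "GroupSummary",
    "segregation_chi2",
    "group_summary",
    "fold_effect",
    "two_sample_t",
]


@dataclass(frozen=True)
class SegregationObservation:
    """Observed counts per phenotype class plus the expected ratio."""

    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.observed) != len(self.expected_ratio):
            raise ValueError("observed and expected_ratio lengths differ")
        if len(self.observed) < 2:
            raise ValueError("need at least two phenotype classes")
        if any(o < 0 for o in self.observed):
            raise ValueError("observed counts must be non-negative")
        if sum(self.observed) == 0:
            raise ValueError("total observed must be positive")
        if any(r <= 0 for r in self.expected_ratio):
            raise ValueError("every expected ratio component must be > 0")

    @property
    def expected_counts(self) -> tuple[float, ...]:
        total = sum(self.observed)
        ratio_sum = sum(self.expected_ratio)
        return tuple(total * r / ratio_sum for r in self.expected_ratio)


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


def segregation_chi2(
    obs: SegregationObservation | Sequence[int],
    expected_ratio: Sequence[float] | None = None,
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of observed counts to an expected ratio.

    ``expected_i = total * ratio_i / sum(ratio)``; no continuity
    correction; df = number of classes - 1; upper-tail p. Invariant under
    rescaling the ratio (1:3 is the same null as 25:75).

    Accepts either a :class:`SegregationObservation` or
    ``(counts, ratio)``.
    """
    if not isinstance(obs, SegregationObservation):
        if expected_ratio is None:
            raise ValueError("expected_ratio required when passing raw counts")
        obs = SegregationObservation(tuple(int(c) for c in obs), tuple(expected_ratio))
    chi2, p = sps.chisquare(obs.observed, f_exp=obs.expected_counts)
    df = len(obs.observed) - 1
    return float(chi2), df, float(p)


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Mean and standard error (sample SD with n-1 denominator over sqrt n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("SEM undefined for fewer than 2 values")
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sem=float(sps.sem(arr, ddof=1)),
    )


def fold_effect(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Display fold effect ``numerator / denominator``.

    Rounded half away from zero to ``decimals`` places, the convention of
    printed fold-change tables.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    ratio = numerator / denominator
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(ratio)).quantize(q, rounding=ROUND_HALF_UP))


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    equal_variance: bool = True,
    paired: bool = False,
) -> tuple[float, float, float]:
    """Two-sided two-group t-test: ``(t, df, p)``.

    Pooled-variance (Student) test by default; Welch when
    ``equal_variance=False``; paired test when ``paired=True`` (samples
    must then have equal length).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal sample sizes")
        res = sps.ttest_rel(x, y)
    else:
        res = sps.ttest_ind(x, y, equal_var=equal_variance)
    return float(res.statistic), float(res.df), float(res.pvalue)
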