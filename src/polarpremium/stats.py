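"""Inferential statistics over concept scores.

Words are the units of inference throughout: a concept's word means form
the sample, and two concepts on the same axis are compared with a
two-sided Welch (unequal-variance) t-test.  Confidence intervals are
Student-t intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np
from scipy import stats as sps

if TYPE_CHECKING:  # pragma: no cover
    from .polar import ConceptScore

__all__ = ["TestResult", "PremiumRecord", "welch_t", "mean_ci", "compute_premium", "holm_adjust"]

DEFAULT_ALPHA = 0.05

LABEL_POS = "positive_significant"
LABEL_NEG = "negative_significant"
LABEL_NS = "not_significant"


@dataclass
class TestResult:
    """Two-sample Welch t-test outcome, with a CI for the mean difference."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    n_a: int
    n_b: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")


@dataclass
class PremiumRecord:
    """One language x axis comparison of two concepts (Beauty vs Ugliness).

    ``difference`` is ``beauty.mean - ugliness.mean``; the label encodes
    the sign of the difference together with significance at level alpha.
    """

    language: str
    axis: str
    beauty: "ConceptScore"
    ugliness: "ConceptScore"
    difference: float
    test: TestResult
    label: str
    alpha: float = DEFAULT_ALPHA


def welch_t(a: Sequence[float], b: Sequence[float], ci_level: float = 0.95) -> TestResult:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom.

    Degenerate case: when both samples have zero variance and equal means
    the statistic is defined as t = 0, p = 1 (not an error).  Sample sizes
    below 2 are errors.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"welch_t needs at least 2 observations per sample, got {a.size} and {b.size}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("welch_t requires finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    if va == 0 and vb == 0:
        df = float(a.size + b.size - 2)
        if diff == 0:
            return TestResult(0.0, df, 1.0, a.size, b.size, diff, diff)
        t = float(np.inf if diff > 0 else -np.inf)
        return TestResult(t, df, 0.0, a.size, b.size, diff, diff)
    res = sps.ttest_ind(a, b, equal_var=False)
    df = float(res.df)
    se = float(np.sqrt(va / a.size + vb / b.size))
    half = float(sps.t.ppf((1 + ci_level) / 2, df)) * se
    return TestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=df,
        p_value=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
        ci_low=diff - half,
        ci_high=diff + half,
    )


def mean_ci(x: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval for the mean of a sample.

    Returns ``mean +/- t_{(1+level)/2, n-1} * s / sqrt(n)``.  A sample of
    fewer than 2 values yields the undefined-interval signal (NaN, NaN).
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return (float("nan"), float("nan"))
    m = float(x.mean())
    s = float(x.std(ddof=1))
    half = float(sps.t.ppf((1 + level) / 2, x.size - 1)) * s / np.sqrt(x.size)
    return (m - half, m + half)


def compute_premium(
    beauty: "ConceptScore",
    ugliness: "ConceptScore",
    alpha: float = DEFAULT_ALPHA,
    language: str = "und",
) -> PremiumRecord:
    """Assemble the premium record for two concepts on a shared axis.

    The difference of concept means is tested with a Welch t-test on the
    two word-mean samples; the label is ``positive_significant`` iff the
    difference is positive and p <= alpha, mirrored for negative, else
    ``not_significant``.
    """
    if beauty.axis != ugliness.axis:
        raise ValueError(f"axis mismatch: {beauty.axis!r} vs {ugliness.axis!r}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    test = welch_t(beauty.word_means, ugliness.word_means)
    difference = beauty.mean - ugliness.mean
    if test.p_value <= alpha and difference > 0:
        label = LABEL_POS
    elif test.p_value <= alpha and difference < 0:
        label = LABEL_NEG
    else:
        label = LABEL_NS
    return PremiumRecord(
        language=language,
        axis=beauty.axis,
        beauty=beauty,
        ugliness=ugliness,
        difference=difference,
        test=test,
        label=label,
        alpha=alpha,
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control).

    Offered as a clearly labelled extension column for cross-language
    tables; the headline per-language labels are unadjusted.
    """
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted
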