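"""Hypothesis tests for comparing strata: Pearson chi-square on 2x2
proportions and the Wilcoxon signed-rank test on paired entropies.

The chi-square test is the uncorrected Pearson form (no Yates
continuity correction), computed from the closed form

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))

with df = 1 and the upper chi-square tail as the two-sided p-value.
The Wilcoxon test drops zero differences, assigns mid-ranks to tied
absolute differences, and uses the normal approximation with
tie-corrected variance; it reports a signed Z statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import ValidationError

__all__ = ["TestResult", "chi_square_2x2", "compare_proportions",
           "wilcoxon_signed_rank"]


class UndefinedTestError(ValueError):
    """The test statistic is undefined for this input."""


@dataclass(frozen=True)
class TestResult:
    method: str  # "chi_square_2x2" | "wilcoxon_signed_rank"
    statistic: float
    p: float
    df: int | None = None
    detail: dict | None = None

    def as_dict(self) -> dict:
        out = {"method": self.method, "statistic": self.statistic, "p": self.p}
        if self.df is not None:
            out["df"] = self.df
        if self.detail is not None:
            out.update(self.detail)
        return out


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Uncorrected Pearson chi-square for the 2x2 table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValidationError(f"cell counts must be non-negative integers, got {v!r}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise UndefinedTestError(
            f"chi-square undefined: zero marginal in [[{a},{b}],[{c},{d}]]"
        )
    chi2 = n * (a * d - b * c) ** 2 / np.prod(margins, dtype=float)
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(method="chi_square_2x2", statistic=float(chi2), p=p, df=1,
                      detail={"table": [[a, b], [c, d]]})


def compare_proportions(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Chi-square comparison of two proportions x1/n1 vs x2/n2.

    Builds the 2x2 table [[x1, n1-x1], [x2, n2-x2]] and delegates to
    :func:`chi_square_2x2`.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if not 0 <= x <= n:
            raise ValidationError(f"need 0 <= successes <= total, got {x}/{n}")
    return chi_square_2x2(x1, n1 - x1, x2, n2 - x2)


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> TestResult:
    """Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (Wilcoxon's method); tied absolute
    differences receive mid-ranks; Z is the signed normal approximation
    with tie-corrected variance and p is two-sided.  Raises
    :class:`UndefinedTestError` when every difference is zero.
    """
    if not len(pairs):
        raise ValidationError("need at least one pair")
    diffs = np.array([float(x) - float(y) for x, y in pairs])
    diffs = diffs[diffs != 0.0]
    n = len(diffs)
    if n == 0:
        raise UndefinedTestError("all paired differences are zero; no test")
    ranks = stats.rankdata(np.abs(diffs))  # mid-ranks for ties
    w_plus = float(ranks[diffs > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var <= 0:
        raise UndefinedTestError("zero variance (all differences tied at one rank)")
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return TestResult(method="wilcoxon_signed_rank", statistic=float(z),
                      p=min(p, 1.0), detail={"n_nonzero": n, "w_plus": w_plus})
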