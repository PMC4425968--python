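"""Group-comparison and study-design statistics.

* Wilcoxon rank-sum (Mann–Whitney) test with an exact null for small
  tie-free samples and a tie-corrected normal approximation otherwise,
* Pearson correlation with its t-based test,
* two-sample power and sample-size calculations for a difference in means
  in the normal-approximation style of Stata's ``sampsi`` (two-sided,
  unequal SDs, unequal group sizes), with a t-based variant behind a flag.

Summary statistics elsewhere in the package are mean ± SD with the n − 1
denominator. No multiple-testing correction is applied anywhere: cohort
tables report per-row Wilcoxon p-values as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError, InfeasibleDesignError

#: Largest combined sample size at which the exact rank-sum null is used.
EXACT_THRESHOLD = 12


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank-sum W of the first sample (midranks under ties)
    pvalue: float
    method: str       # "exact" | "normal"


def wilcoxon_rank_sum(
    sample1: Sequence[float],
    sample2: Sequence[float],
    *,
    continuity: bool = True,
    exact_threshold: int = EXACT_THRESHOLD,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the rank sum W of ``sample1`` (midranks for ties).
    The null is evaluated exactly when n1 + n2 ≤ ``exact_threshold`` and
    there are no ties, else by the normal approximation with tie-corrected
    variance and (by default) a continuity correction.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    use_exact = (x.size + y.size) <= exact_threshold and not has_ties
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=continuity,
    )
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U1 -> rank sum
    return RankSumResult(
        statistic=w,
        pvalue=float(min(res.pvalue, 1.0)),
        method="exact" if use_exact else "normal",
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    pvalue: float
    n: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-test at n − 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have the same length")
    if x.size < 3:
        raise DomainError(f"need n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


# --------------------------------------------------------------------------
# power / sample size for a two-sample comparison of means


@dataclass(frozen=True)
class TwoSampleDesign:
    """Inputs of a two-sample mean comparison: group means, SDs, sizes, the
    significance level α and (for sample-size calculations) target power."""

    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int = 2
    n2: int = 2
    alpha: float = 0.05
    power: float = 0.9

    def __post_init__(self) -> None:
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise DomainError("SDs must be > 0")
        if not (0 < self.alpha < 1):
            raise DomainError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0 < self.power < 1):
            raise DomainError(f"power must be in (0,1), got {self.power}")


def two_sample_power(design: TwoSampleDesign, *, use_t: bool = False) -> float:
    """Power of the two-sided two-sample comparison of means.

    Default is the normal-approximation (``sampsi``-style) formula with
    unequal SDs and group sizes: with δ = |μ1 − μ2|,
    se = √(σ1²/n1 + σ2²/n2) and z = z_{1−α/2},

        power = Φ(δ/se − z) + Φ(−δ/se − z),

    which equals α exactly under the null. ``use_t=True`` instead evaluates
    the noncentral-t power of the Welch test (Satterthwaite df).
    """
    if design.n1 < 2 or design.n2 < 2:
        raise DomainError("need n1, n2 >= 2")
    se = math.sqrt(design.sd1**2 / design.n1 + design.sd2**2 / design.n2)
    d = abs(design.mean1 - design.mean2) / se
    if use_t:
        v1 = design.sd1**2 / design.n1
        v2 = design.sd2**2 / design.n2
        df = (v1 + v2) ** 2 / (
            v1**2 / (design.n1 - 1) + v2**2 / (design.n2 - 1)
        )
        tcrit = sps.t.ppf(1 - design.alpha / 2, df)
        return float(sps.nct.sf(tcrit, df, d) + sps.nct.cdf(-tcrit, df, d))
    z = sps.norm.ppf(1 - design.alpha / 2)
    return float(sps.norm.cdf(d - z) + sps.norm.cdf(-d - z))


def two_sample_sample_size(
    design: TwoSampleDesign, *, ratio: float = 1.0, use_t: bool = False
) -> tuple[int, int]:
    """Smallest per-group sizes achieving the design's target power.

    ``ratio`` = n2/n1. Returns (n1, n2) with n1 the smallest integer ≥ 2
    such that the power at (n1, ⌈ratio·n1⌉) reaches ``design.power``;
    consistency with :func:`two_sample_power` is by construction (integer
    search seeded at the closed-form normal approximation).
    """
    delta = abs(design.mean1 - design.mean2)
    if delta == 0:
        raise InfeasibleDesignError("zero effect size: no finite n achieves power")
    if ratio <= 0:
        raise DomainError("ratio must be > 0")
    za = sps.norm.ppf(1 - design.alpha / 2)
    zb = sps.norm.ppf(design.power)
    n0 = (za + zb) ** 2 * (design.sd1**2 + design.sd2**2 / ratio) / delta**2
    n1 = max(2, math.floor(n0) - 2)

    def achieved(n1_try: int) -> float:
        n2_try = max(2, math.ceil(ratio * n1_try))
        return two_sample_power(
            replace(design, n1=n1_try, n2=n2_try), use_t=use_t
        )

    while achieved(n1) < design.power:
        n1 += 1
    while n1 > 2 and achieved(n1 - 1) >= design.power:
        n1 -= 1
    return n1, max(2, math.ceil(ratio * n1))
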