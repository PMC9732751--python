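"""Trial statistics: Mann-Whitney U, Fisher exact tests, and the a priori
two-sample t-test sample size.

Conventions:

* Mann-Whitney uses the exact null distribution when the product of sample
  sizes is at most 400 and the pooled data are tie-free, otherwise the
  normal approximation with midrank tie correction and continuity
  correction; the statistic reported is the U of the smaller sample.
* The two-sided Fisher p sums the hypergeometric probabilities of all tables
  with the observed margins whose point probability does not exceed the
  observed one (minimum-likelihood rule), with a small relative tolerance
  for floating-point ties.
* The sample-size routine inverts the noncentral-t power function of the
  two-sided two-sample t test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PowerSpec",
    "mann_whitney",
    "fisher_exact",
    "fisher_exact_2xk",
    "sample_size_two_sample_t",
    "two_sample_t_power",
    "format_p",
]

_EXACT_MAX_PRODUCT = 400
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact by enumeration of the rank distribution when n1·n2 ≤ 400 and the
    pooled sample has no ties; otherwise the normal approximation with
    midrank tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size * y.size <= _EXACT_MAX_PRODUCT) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    u_x = float(res.statistic)
    u_y = x.size * y.size - u_x
    # report the U of the smaller sample (either one when sizes are equal)
    u = u_x if x.size < y.size else u_y if y.size < x.size else min(u_x, u_y)
    return TestResult(
        test_name="mann_whitney_u",
        statistic=u,
        p_value=min(1.0, float(res.pvalue)),
        method="exact" if exact else "asymptotic",
        n_per_group=(int(x.size), int(y.size)),
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2×2 count table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table cells must be non-negative integers")
    if arr.sum() == 0:
        raise ValueError("table has no observations")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        test_name="fisher_exact",
        statistic=float(odds),
        p_value=min(1.0, float(p)),
        method="exact",
        n_per_group=(int(arr[0].sum()), int(arr[1].sum())),
    )


def fisher_exact_2xk(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided exact test on a 2×k count table (k ≥ 2), minimum-likelihood rule.

    Enumerates every table with the observed margins and sums the
    multivariate-hypergeometric probabilities of those no more likely than
    the observed table.  Intended for small demographic tables; cost grows
    with the product of column margins.
    """
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValueError("expected a 2xk table with k >= 2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table cells must be non-negative integers")
    col_margins = arr.sum(axis=0)
    row1 = int(arr[0].sum())
    total = int(arr.sum())
    if total == 0:
        raise ValueError("table has no observations")

    def log_prob(top_row: Sequence[int]) -> float:
        # multivariate hypergeometric: prod C(m_j, a_j) / C(N, row1)
        out = -math.lgamma(total + 1) + math.lgamma(row1 + 1) + math.lgamma(total - row1 + 1)
        for a, m in zip(top_row, col_margins):
            out += (
                math.lgamma(m + 1)
                - math.lgamma(a + 1)
                - math.lgamma(m - a + 1)
            )
        return out

    observed = log_prob(arr[0])
    threshold = observed + math.log1p(_TIE_RTOL)
    p = 0.0
    ranges = [range(int(m) + 1) for m in col_margins[:-1]]
    for partial in itertools.product(*ranges):
        last = row1 - sum(partial)
        if not 0 <= last <= col_margins[-1]:
            continue
        lp = log_prob((*partial, last))
        if lp <= threshold:
            p += math.exp(lp)
    return TestResult(
        test_name="fisher_exact",
        statistic=math.nan,
        p_value=min(1.0, p),
        method="exact",
        n_per_group=(row1, total - row1),
    )


class PowerSpec(BaseModel):
    """Design of an a priori two-sided two-sample t-test power analysis."""

    model_config = ConfigDict(frozen=True)

    effect_size: float = Field(gt=0, description="standardized difference (Cohen's d)")
    power: float = Field(default=0.90, gt=0, lt=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)


def two_sample_t_power(n_per_arm: int, spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t test at n per arm.

    Noncentrality d·sqrt(n/2) with 2n−2 degrees of freedom.
    """
    if n_per_arm < 2:
        return 0.0
    df = 2 * n_per_arm - 2
    ncp = spec.effect_size * math.sqrt(n_per_arm / 2.0)
    crit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp))


def sample_size_two_sample_t(spec: PowerSpec, *, n_max: int = 100_000) -> int:
    """Smallest integer n per arm attaining the requested power."""
    for n in range(2, n_max + 1):
        if two_sample_t_power(n, spec) >= spec.power:
            return n
    raise ValueError(f"no n <= {n_max} reaches power {spec.power}")


def format_p(p: float) -> str:
    """P-value display convention of clinical reports: '.34', '<.001', '.99'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    if p < 0.001:
        return "<.001"
    if p > 0.99:
        return ".99"
    return f"{p:.2f}".lstrip("0")
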