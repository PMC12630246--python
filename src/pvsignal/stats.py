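"""Statistical core: Haldane correction, ROR with Woolf CI, signal criteria,
and the cohort descriptive tests (Pearson chi-square, pooled-variance t,
rounded proportions).

All comparisons (signal logic) run on full precision; rounding is half-up
and happens only at presentation (2 decimals for ROR/CI, 4 for chi-square,
1 for percentages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Tuple

import numpy as np
from scipy import stats as sps

from pvsignal.contingency import ContingencyTable

__all__ = [
    "RorResult",
    "SignalCriteria",
    "analyze_table",
    "compute_ror",
    "evaluate_signal",
    "haldane_adjust",
    "pearson_chi2",
    "proportion",
    "round_half_up",
    "two_sample_t_equal_var",
]

Z_95 = 1.96


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (5 rounds up)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SignalCriteria:
    """A-priori signal thresholds: ROR >= min_ror, CI lower bound strictly
    above min_ci_low, and at least min_cases case mentions (pre-correction)."""

    min_ror: float = 2.0
    min_ci_low: float = 1.0
    min_cases: int = 5

    def __post_init__(self) -> None:
        if self.min_ror < 0 or self.min_ci_low < 0 or self.min_cases < 1:
            raise ValueError("signal criteria thresholds must be positive")


@dataclass(frozen=True)
class RorResult:
    """Reporting odds ratio with Woolf (log-method) confidence interval."""

    entity: str
    level: int
    comparator: str
    a: float
    b: float
    c: float
    d: float
    ror: float
    ci_low: float
    ci_high: float
    z: float
    corrected: bool
    n_case_mentions: int
    signal: bool = False


def haldane_adjust(table: ContingencyTable) -> ContingencyTable:
    """Add 0.5 to ALL FOUR cells when any cell is zero; no-op otherwise.

    The all-cells variant (rather than correcting only the zero cells) is
    the conservative form this pipeline standardizes on.
    """
    cells = table.cells()
    if min(cells) < 0:
        raise ValueError("cells must be non-negative")
    if max(cells) == 0:
        raise ValueError("all four cells are zero")
    if min(cells) > 0:
        return replace(table, corrected=False)
    a, b, c, d = (x + 0.5 for x in cells)
    return replace(table, a=a, b=b, c=c, d=d, corrected=True)


def compute_ror(table: ContingencyTable, z: float = Z_95) -> RorResult:
    """ROR = (a*d)/(b*c) with CI = exp(ln ROR +/- z*sqrt(1/a+1/b+1/c+1/d)).

    Requires a Haldane-adjusted table (all cells > 0).  ``n_case_mentions``
    records the pre-correction case-mention count used by signal criteria.
    """
    a, b, c, d = table.cells()
    if min(a, b, c, d) <= 0:
        raise ValueError(
            "all cells must be > 0; apply haldane_adjust before compute_ror"
        )
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    n_case = int(round(a - 0.5)) if table.corrected else int(round(a))
    return RorResult(
        entity=table.entity,
        level=table.level,
        comparator=table.comparator,
        a=a,
        b=b,
        c=c,
        d=d,
        ror=ror,
        ci_low=ror * math.exp(-z * se),
        ci_high=ror * math.exp(z * se),
        z=z,
        corrected=table.corrected,
        n_case_mentions=n_case,
    )


def evaluate_signal(result: RorResult, criteria: SignalCriteria) -> bool:
    """Apply the three-part criterion on unrounded values."""
    return (
        result.ror >= criteria.min_ror
        and result.ci_low > criteria.min_ci_low
        and result.n_case_mentions >= criteria.min_cases
    )


def analyze_table(
    table: ContingencyTable, criteria: Optional[SignalCriteria] = None, z: float = Z_95
) -> RorResult:
    """Haldane-adjust, estimate, and flag in one step."""
    result = compute_ror(haldane_adjust(table), z=z)
    if criteria is not None:
        result = replace(result, signal=evaluate_signal(result, criteria))
    return result


def pearson_chi2(table) -> Tuple[float, int, float]:
    """Pearson chi-square WITHOUT continuity correction on an r x k table.

    Returns (statistic, df, p).  A zero row or column margin is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin; statistic undefined")
    res = sps.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def two_sample_t_equal_var(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> Tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, df, p) with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def proportion(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to 1 decimal."""
    if denominator <= 0:
        raise ZeroDivisionError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    return round_half_up(100.0 * numerator / denominator, 1)
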