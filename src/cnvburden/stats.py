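"""Carrier-based 2x2 burden statistics.

A burden comparison counts *carriers* — individuals with at least one
qualifying deletion under some predicate — in cases versus controls, and
tests the 2x2 table with an uncorrected Pearson chi-square (df = 1) or, when
any expected cell count falls below 5 (Cochran's rule), Fisher's exact test.
Effect sizes are cross-product odds ratios with Woolf log-interval 95% CIs,
falling back to the conditional-MLE exact interval when a zero cell makes
the cross-product degenerate. Attributable risk is reported as the
difference of carrier percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .core import CnvCall, SampleRecord, cohort_sizes

CHI2 = "chi2"
FISHER = "fisher"


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier 2x2 table: a/b case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def n_case(self) -> int:
        return self.a + self.b

    @property
    def n_control(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n_case + self.n_control

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def swapped_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)

    @property
    def carrier_pct_case(self) -> float:
        return 100.0 * self.a / self.n_case if self.n_case else float("nan")

    @property
    def carrier_pct_control(self) -> float:
        return 100.0 * self.c / self.n_control if self.n_control else float("nan")


def carrier_table(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    predicate: Callable[[CnvCall], bool],
) -> ContingencyTable:
    """Count carriers of >= 1 call satisfying ``predicate`` per cohort.

    Each sample contributes at most one carrier regardless of how many
    qualifying deletions it has; denominators include samples with no calls.
    """
    n_case, n_control = cohort_sizes(samples)
    cohort = {s.sample_id: s.cohort for s in samples}
    carriers: set[str] = set()
    for c in calls:
        if c.sample_id in carriers:
            continue
        try:
            hit = bool(predicate(c))
        except Exception as exc:
            raise RuntimeError(
                f"predicate failed on call {c.sample_id} {c.interval}: {exc}"
            ) from exc
        if hit:
            if c.sample_id not in cohort:
                raise ValueError(f"call sample {c.sample_id!r} not in sample table")
            carriers.add(c.sample_id)
    a = sum(1 for s in carriers if cohort[s] == "case")
    c_ = len(carriers) - a
    return ContingencyTable(a, n_case - a, c_, n_control - c_)


def expected_counts(table: ContingencyTable) -> np.ndarray:
    t = table.as_array().astype(float)
    n = t.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / n


def select_test(table: ContingencyTable) -> str:
    """Cochran's rule: Fisher's exact test iff any expected cell count < 5."""
    return FISHER if (expected_counts(table) < 5).any() else CHI2


def pearson_chi2(table: ContingencyTable) -> tuple[float, float]:
    """Uncorrected Pearson chi-square statistic and two-sided p (df = 1)."""
    t = table.as_array()
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal; use fisher_exact instead")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table: ContingencyTable, method: str = "sum") -> tuple[float, float]:
    """Fisher's exact test: two-sided p and the conditional-MLE odds ratio.

    ``method="sum"`` (default) sums hypergeometric probabilities <= that of
    the observed table; ``method="doubling"`` doubles the smaller one-sided
    tail (capped at 1). The returned odds ratio is the conditional maximum
    likelihood estimate (infinite with an appropriate zero cell).
    """
    t = table.as_array()
    if method == "sum":
        p = float(sps.fisher_exact(t, alternative="two-sided").pvalue)
    elif method == "doubling":
        p_less = float(sps.fisher_exact(t, alternative="less").pvalue)
        p_greater = float(sps.fisher_exact(t, alternative="greater").pvalue)
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValueError(f"unknown two-sided method {method!r}")
    or_mle = float(_scipy_odds_ratio(t, kind="conditional").statistic)
    return p, or_mle


def odds_ratio_woolf(
    table: ContingencyTable, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Cross-product odds ratio with a Woolf log-interval CI.

    With any zero cell, the cross-product OR is 0 or infinite and the Woolf
    interval is undefined; the CI then falls back to the exact conditional
    interval, giving the customary one-sided bound (e.g. ``Inf; 9.7-Inf``).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        res = _scipy_odds_ratio(table.as_array(), kind="conditional")
        ci = res.confidence_interval(confidence_level=1 - alpha)
        if a * d == 0 and b * c == 0:
            point = float("nan")
        else:
            point = float("inf") if b * c == 0 else 0.0
        return point, float(ci.low), float(ci.high)
    or_point = (a * d) / (b * c)
    z = sps.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_point, or_point * math.exp(-z * se), or_point * math.exp(z * se)


def attributable_risk(table: ContingencyTable) -> tuple[float, float]:
    """Carrier-percentage difference, in percentage points.

    Returns ``(rounded, raw)`` where ``rounded`` is the difference of the
    carrier percentages each first rounded to one decimal (the convention
    used when quoting attributable risk from printed carrier frequencies),
    and ``raw`` is the unrounded difference.
    """
    raw = table.carrier_pct_case - table.carrier_pct_control
    rounded = round(table.carrier_pct_case, 1) - round(table.carrier_pct_control, 1)
    return round(rounded, 10), raw


@dataclass
class BurdenResult:
    """A complete carrier-burden comparison for one predicate."""

    table: ContingencyTable
    test: str
    statistic: Optional[float]
    p_two_sided: float
    or_point: float
    ci_low: float
    ci_high: float
    or_conditional: Optional[float] = None
    label: str = ""

    @property
    def carrier_pct_case(self) -> float:
        return self.table.carrier_pct_case

    @property
    def carrier_pct_control(self) -> float:
        return self.table.carrier_pct_control

    @property
    def attributable_risk_pct(self) -> float:
        return attributable_risk(self.table)[0]


def burden_test(table: ContingencyTable, label: str = "",
                test: Optional[str] = None) -> BurdenResult:
    """Run the appropriate 2x2 test and effect-size estimation on a table."""
    chosen = test or select_test(table)
    p_fisher, or_mle = fisher_exact(table)
    if chosen == CHI2:
        stat, p = pearson_chi2(table)
    else:
        stat, p = None, p_fisher
    or_point, lo, hi = odds_ratio_woolf(table)
    return BurdenResult(
        table=table, test=chosen, statistic=stat, p_two_sided=p,
        or_point=or_point, ci_low=lo, ci_high=hi, or_conditional=or_mle,
        label=label,
    )


@dataclass
class MannWhitneyResult:
    u: float
    p_two_sided: float
    median_case: float
    iqr_case: tuple[float, float]
    median_control: float
    iqr_control: tuple[float, float]
    method: str


def mann_whitney(
    sizes_case: Sequence[float], sizes_control: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Wilcoxon-Mann-Whitney comparison of deletion sizes (kb).

    Uses exact enumeration when both groups have n <= 20 (and no ties),
    otherwise the tie-corrected normal approximation. Medians and
    interquartile ranges of each group are reported alongside.
    """
    x, y = np.asarray(sizes_case, float), np.asarray(sizes_control, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both size lists must be non-empty")
    method = "exact" if (len(x) <= 20 and len(y) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(
        u=float(res.statistic),
        p_two_sided=float(res.pvalue),
        median_case=float(np.median(x)),
        iqr_case=(float(np.percentile(x, 25)), float(np.percentile(x, 75))),
        median_control=float(np.median(y)),
        iqr_control=(float(np.percentile(y, 25)), float(np.percentile(y, 75))),
        method=method,
    )
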