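"""Carrier tables and 2x2 statistics, checked against independent oracles."""

import itertools
import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvburden.core import CnvCall, GenomicInterval
from cnvburden.stats import (
    ContingencyTable,
    attributable_risk,
    burden_test,
    carrier_table,
    fisher_exact,
    mann_whitney,
    odds_ratio_woolf,
    pearson_chi2,
    select_test,
)

from conftest import make_samples


def fisher_two_sided_oracle(t: ContingencyTable) -> float:
    """Exact-integer enumeration of fixed-margin tables.

    Sums the hypergeometric probabilities of every table whose probability
    does not exceed the observed one (probability-summation two-sided rule).
    All arithmetic is exact (integer weights), independent of the tested
    implementation.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    weights = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    w_obs = weights[a]
    # integer weights make probability ties exact; no floating-point slack
    kept = sum(w for w in weights.values() if w <= w_obs)
    return kept / total


class TestCarrierTable:
    def test_no_matching_calls(self):
        samples = make_samples(5, 7)
        t = carrier_table([], samples, lambda c: True)
        assert (t.a, t.b, t.c, t.d) == (0, 5, 0, 7)

    def test_double_carrier_counted_once(self):
        samples = make_samples(3, 3)
        calls = [
            CnvCall("case_0", GenomicInterval("1", 0, 500_000), 300),
            CnvCall("case_0", GenomicInterval("5", 0, 700_000), 300),
        ]
        t = carrier_table(calls, samples, lambda c: True)
        assert t.a == 1 and t.b == 2

    def test_planted_carriers(self):
        samples = make_samples(5, 5)
        calls = [
            CnvCall(s, GenomicInterval("1", 0, 500_000), 300)
            for s in ("case_1", "case_2", "ctrl_1")
        ]
        t = carrier_table(calls, samples, lambda c: True)
        assert (t.a, t.b, t.c, t.d) == (2, 3, 1, 4)

    def test_failing_predicate_names_call(self):
        samples = make_samples(1, 1)
        calls = [CnvCall("case_0", GenomicInterval("1", 0, 500_000), 300)]

        def bad(call):
            raise KeyError("boom")

        with pytest.raises(RuntimeError, match="case_0"):
            carrier_table(calls, samples, bad)


class TestPearsonChi2:
    def test_large_cohort_burden(self):
        stat, p = pearson_chi2(ContingencyTable(100, 1266, 208, 5026))
        assert p == pytest.approx(1.77e-7, rel=5e-3)

    def test_single_hotspot_comparison(self):
        _, p = pearson_chi2(ContingencyTable(13, 1353, 14, 5220))
        assert p == pytest.approx(4.18e-4, rel=5e-3)

    def test_equal_proportions(self):
        stat, p = pearson_chi2(ContingencyTable(10, 90, 10, 90))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_zero_marginal_directs_to_fisher(self):
        with pytest.raises(ValueError, match="fisher"):
            pearson_chi2(ContingencyTable(0, 10, 0, 20))


tables = st.builds(
    ContingencyTable,
    st.integers(0, 60), st.integers(1, 60), st.integers(0, 60), st.integers(1, 60),
)


class TestFisherExact:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((11, 1355, 0, 5234), 2.89e-8),
            ((3, 1363, 0, 5234), 8.85e-3),
        ],
    )
    def test_zero_cell_comparisons(self, cells, expected):
        p, or_mle = fisher_exact(ContingencyTable(*cells))
        assert p == pytest.approx(expected, rel=5e-3)
        assert math.isinf(or_mle)

    def test_no_carriers_anywhere(self):
        p, _ = fisher_exact(ContingencyTable(0, 50, 0, 70))
        assert p == 1.0

    @given(t=tables)
    @settings(max_examples=250, derandomize=True, deadline=None)
    def test_matches_fixed_margin_enumeration(self, t):
        p, _ = fisher_exact(t)
        assert p == pytest.approx(fisher_two_sided_oracle(t), rel=1e-6, abs=1e-12)

    def test_doubling_rule_at_least_sum_rule(self):
        t = ContingencyTable(3, 1363, 0, 5234)
        p_sum, _ = fisher_exact(t)
        p_double, _ = fisher_exact(t, method="doubling")
        assert p_double >= p_sum


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((100, 1266, 208, 5026), 1.91),
            ((38, 1328, 20, 5214), 7.46),
            ((13, 1353, 14, 5220), 3.58),
        ],
    )
    def test_cross_product_point(self, cells, expected):
        or_point, lo, hi = odds_ratio_woolf(ContingencyTable(*cells))
        assert round(or_point, 2) == expected
        assert lo < or_point < hi

    def test_symmetric_table_is_unity(self):
        or_point, lo, hi = odds_ratio_woolf(ContingencyTable(7, 30, 7, 30))
        assert or_point == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_zero_cell_exact_bound(self):
        # conditional exact interval takes over: Inf point, finite lower bound
        or_point, lo, hi = odds_ratio_woolf(ContingencyTable(11, 1355, 0, 5234))
        assert math.isinf(or_point) and math.isinf(hi)
        assert lo == pytest.approx(9.7, abs=0.05)

    @given(t=tables.filter(lambda t: min(t.a, t.b, t.c, t.d) > 0))
    @settings(max_examples=150, derandomize=True)
    def test_antisymmetry(self, t):
        or1, *_ = odds_ratio_woolf(t)
        or2, *_ = odds_ratio_woolf(t.swapped_rows())
        assert or1 * or2 == pytest.approx(1.0)


class TestSelectTest:
    def test_small_expected_uses_fisher(self):
        assert select_test(ContingencyTable(11, 1355, 0, 5234)) == "fisher"

    def test_large_expected_uses_chi2(self):
        assert select_test(ContingencyTable(100, 1266, 208, 5026)) == "chi2"

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            select_test(ContingencyTable(0, 0, 0, 0))

    def test_chi2_close_to_fisher_when_expected_large(self):
        # with all expected counts >= 20 and non-extreme p, the uncorrected
        # chi-square approximates the exact test well (deep tails excluded:
        # relative agreement of an asymptotic tail is not meaningful there)
        from cnvburden.stats import expected_counts

        rng = np.random.default_rng(5)
        rel = []
        while len(rel) < 40:
            a, b, c, d = rng.integers(30, 400, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            if (expected_counts(t) >= 20).all():
                _, p_chi = pearson_chi2(t)
                p_f, _ = fisher_exact(t)
                if p_chi > 0.01:
                    rel.append(abs(p_chi - p_f) / p_f)
        assert float(np.median(rel)) < 0.10
        assert max(rel) < 0.35


class TestMannWhitney:
    def test_identical_multisets(self):
        r = mann_whitney([5, 6, 7], [5, 6, 7])
        assert r.u == pytest.approx(4.5)
        assert r.p_two_sided == pytest.approx(1.0)

    def test_complete_separation(self):
        r = mann_whitney([5, 6, 7], [1, 2, 3])
        assert r.u == 9.0  # every case exceeds every control
        assert r.p_two_sided == pytest.approx(0.1)

    def test_exact_and_asymptotic_agree(self):
        rng = np.random.default_rng(12)
        x = rng.lognormal(6.5, 0.5, 15)
        y = rng.lognormal(6.4, 0.5, 15)
        exact = mann_whitney(list(x), list(y))
        assert exact.method == "exact"
        # tie-corrected normal approximation on the same data
        from scipy.stats import mannwhitneyu

        approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert abs(exact.p_two_sided - approx.pvalue) < 0.01

    def test_medians_and_iqr_reported(self):
        r = mann_whitney([100, 700, 1500], [400, 600, 800])
        assert r.median_case == 700 and r.median_control == 600

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestAttributableRisk:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((100, 1266, 208, 5026), 3.3),  # 7.3% - 4.0%
            ((38, 1328, 20, 5214), 2.4),  # 2.8% - 0.4%
            ((10, 90, 10, 90), 0.0),
        ],
    )
    def test_rounded_difference(self, cells, expected):
        rounded, raw = attributable_risk(ContingencyTable(*cells))
        assert rounded == pytest.approx(expected)
        assert abs(raw - rounded) < 0.1


def test_burden_test_bundles_everything():
    r = burden_test(ContingencyTable(100, 1266, 208, 5026))
    assert r.test == "chi2"
    assert round(r.or_point, 2) == 1.91
    assert r.ci_low < r.or_point < r.ci_high
    assert 0 <= r.p_two_sided <= 1
    assert r.attributable_risk_pct == pytest.approx(3.3)
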