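"""Group comparison statistics, volcano classification and set arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from lactopept import (
    DegenerateVarianceError,
    PeptideRecord,
    PeptideTable,
    classify,
    detect_filter,
    differential_analysis,
    impute_missing,
    percent_difference,
    student_t_two_sided,
    venn_from_counts,
    venn_summary,
)


def _table(records):
    samples = ["A1", "A2", "A3", "B1", "B2", "B3"]
    return PeptideTable(records, samples, {s: s[0] for s in samples})


# ---------------------------------------------------------------------------
# t-test against independent oracles
# ---------------------------------------------------------------------------

def _t_density(x: float, df: int) -> float:
    """Student's t density written from the closed form (independent oracle)."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def _two_sided_p_by_integration(t: float, df: int) -> float:
    tail, _ = integrate.quad(_t_density, abs(t), np.inf, args=(df,))
    return 2.0 * tail


class TestStudentT:
    def test_identical_groups(self):
        t, p = student_t_two_sided([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == 1.0

    def test_known_value_against_integrated_density(self):
        t, p = student_t_two_sided([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-3)
        assert p == pytest.approx(_two_sided_p_by_integration(t, 4), abs=1e-9)

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateVarianceError):
            student_t_two_sided([5, 5], [5, 5])

    def test_matches_scipy_equal_variance(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = rng.normal(0, 1, rng.integers(2, 6))
            b = rng.normal(0.5, 1, rng.integers(2, 6))
            t, p = student_t_two_sided(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    @pytest.mark.parametrize("df", [2, 4, 6, 10])
    def test_p_agrees_with_integrated_density_small_df(self, df):
        n_a = 2
        n_b = df + 2 - n_a
        rng = np.random.default_rng(df)
        a = rng.normal(0, 1, n_a)
        b = rng.normal(1, 1, n_b)
        t, p = student_t_two_sided(a, b)
        assert p == pytest.approx(_two_sided_p_by_integration(t, df), abs=1e-6)


# ---------------------------------------------------------------------------
# Filtering, imputation, classification
# ---------------------------------------------------------------------------

class TestDetectFilter:
    def test_one_sided_peptide_retained_not_tested(self):
        rec = PeptideRecord("PEPA", {"A1": 1.0, "A2": 1.0, "A3": 1.0})
        table = detect_filter(_table([rec]), min_detected=2)
        assert len(table.records) == 1
        assert table.records[0].annotations["tested"] is False

    def test_sparse_peptide_dropped(self):
        rec = PeptideRecord("PEPA", {"A1": 1.0, "B2": 1.0})
        assert detect_filter(_table([rec]), min_detected=2).records == []

    def test_min_zero_keeps_everything(self):
        recs = [PeptideRecord("PEPA", {}), PeptideRecord("PEPC", {"A1": 1.0})]
        table = detect_filter(_table(recs), min_detected=0)
        assert len(table.records) == 2

    def test_min_exceeding_group_size_errors(self):
        with pytest.raises(ValueError):
            detect_filter(_table([]), min_detected=4)


class TestImpute:
    def test_half_group_min(self):
        rec = PeptideRecord(
            "PEPA", {"A1": 2.0, "A2": 4.0, "B1": 6.0, "B2": 6.0, "B3": 6.0}
        )
        out = impute_missing(_table([rec]), "half_group_min").records[0]
        assert out.abundances["A3"] == 1.0

    def test_all_missing_group_uses_global_half_min(self):
        rec = PeptideRecord("PEPA", {"A1": 8.0, "A2": 9.0, "A3": 10.0})
        out = impute_missing(_table([rec]), "half_group_min").records[0]
        assert out.abundances["B1"] == 4.0

    def test_zero_strategy(self):
        rec = PeptideRecord("PEPA", {"A1": 8.0})
        out = impute_missing(_table([rec]), "zero").records[0]
        assert out.abundances["B3"] == 0.0


class TestClassify:
    @pytest.mark.parametrize(
        "log2fc,p,expected",
        [
            (2.0, 0.01, "up"),
            (2.0, 0.2, "ns"),
            (-1.0, 0.001, "down"),  # |fc| == threshold is significant
            (1.0, 0.001, "up"),
            (0.5, 0.001, "ns"),
            (2.0, 0.05, "ns"),  # p == alpha is not significant
            (2.0, None, "not_tested"),
        ],
    )
    def test_boundaries(self, log2fc, p, expected):
        assert classify(log2fc, p, alpha=0.05, fc_threshold=1.0) == expected


class TestDifferentialAnalysis:
    def test_swapping_groups_negates_fc_and_swaps_statuses(self, two_group_table):
        prepared = impute_missing(detect_filter(two_group_table, 2))
        fwd = differential_analysis(prepared, "A", "B")
        rev = differential_analysis(prepared, "B", "A")
        swap = {"up": "down", "down": "up", "ns": "ns", "not_tested": "not_tested"}
        for f, r in zip(fwd, rev):
            if math.isfinite(f.log2fc):
                assert r.log2fc == pytest.approx(-f.log2fc)
            if not math.isnan(f.p_value):
                assert r.p_value == pytest.approx(f.p_value)
            assert r.status == swap[f.status]

    def test_statuses_partition_tested_peptides(self, two_group_table):
        prepared = impute_missing(detect_filter(two_group_table, 2))
        results = differential_analysis(prepared)
        counts = {s: sum(r.status == s for r in results) for s in
                  ("up", "down", "ns", "not_tested")}
        tested = sum(1 for r in prepared.records if r.annotations["tested"])
        assert counts["up"] + counts["down"] + counts["ns"] == tested
        assert counts["not_tested"] == len(results) - tested

    def test_bh_adjustment_populates_monotone_qvalues(self, two_group_table):
        prepared = impute_missing(detect_filter(two_group_table, 2))
        results = differential_analysis(prepared, adjust=True)
        qs = [r.p_adjusted for r in results if r.p_adjusted is not None]
        ps = [r.p_value for r in results if r.p_adjusted is not None]
        assert qs and all(q >= p for p, q in zip(ps, qs))


# ---------------------------------------------------------------------------
# Venn arithmetic and percent differences
# ---------------------------------------------------------------------------

class TestVenn:
    def test_basic_overlap(self):
        v = venn_summary({"P1", "P2"}, {"P2", "P3"})
        assert (v.n_shared, v.n_unique_a, v.n_unique_b, v.n_union) == (1, 1, 1, 3)

    def test_identical_and_disjoint(self):
        same = venn_summary({"A", "B"}, {"A", "B"})
        assert same.n_shared == same.n_a and same.n_unique_a == 0
        disjoint = venn_summary({"A"}, {"B", "C"})
        assert disjoint.n_shared == 0 and disjoint.n_union == 3

    def test_from_counts_consistency_error(self):
        with pytest.raises(ValueError):
            venn_from_counts(3, 4, 4)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    def test_union_identity_property(self, sa, sb):
        v = venn_summary({str(x) for x in sa}, {str(x) for x in sb})
        assert v.n_union == v.n_a + v.n_b - v.n_shared
        assert v.n_union == len(sa | sb)
        assert min(v.n_unique_a, v.n_unique_b, v.n_shared) >= 0


class TestPercentDifference:
    def test_lower_than_ref(self):
        assert percent_difference(78.9, 39.4, "lower_than_ref") == pytest.approx(
            50.06, abs=0.01
        )

    def test_more_than_ref(self):
        assert percent_difference(339, 567, "more_than_ref") == pytest.approx(
            67.26, abs=0.01
        )

    def test_equal_values_zero(self):
        assert percent_difference(5.0, 5.0, "lower_than_ref") == 0.0
        assert percent_difference(5.0, 5.0, "more_than_ref") == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0, "more_than_ref")
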