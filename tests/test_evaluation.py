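"""Metric family: plain, incl/excl, validity, fractions, Tanimoto, families."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conformal_qsar.conformal import (
    BOTH,
    EMPTY,
    SINGLE_ACTIVE,
    SINGLE_INACTIVE,
)
from conformal_qsar.evaluation import (
    confusion_table,
    family_aggregate,
    mcp_metrics,
    qsar_metrics,
    set_fractions,
    tanimoto_median,
    validity,
)

A, I = "active", "inactive"


class TestQsarMetrics:
    def test_counts_example(self):
        labels = [A] * 10 + [I] * 10
        pred = [A] * 8 + [I] * 2 + [A] * 4 + [I] * 6
        m = qsar_metrics(labels, pred)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.6)
        assert m["ccr"] == pytest.approx(0.7)

    def test_perfect_and_degenerate_predictors(self):
        labels = [A, A, I, I]
        assert qsar_metrics(labels, labels)["ccr"] == 1.0
        m = qsar_metrics(labels, [A] * 4)
        assert (m["sensitivity"], m["specificity"], m["ccr"]) == (1.0, 0.0, 0.5)

    def test_absent_class_reported_missing(self):
        m = qsar_metrics([A, A], [A, I])
        assert np.isnan(m["specificity"]) and np.isnan(m["ccr"])


class TestMcpMetrics:
    def test_incl_vs_excl_worked_example(self):
        # 10 actives: 7 single-active, 1 single-inactive, 1 both, 1 empty
        cats = [SINGLE_ACTIVE] * 7 + [SINGLE_INACTIVE, BOTH, EMPTY]
        labels = [A] * 10
        assert mcp_metrics(cats, labels, "incl")["sensitivity"] == pytest.approx(0.8)
        assert mcp_metrics(cats, labels, "excl")["sensitivity"] == pytest.approx(7 / 9)

    def test_all_both_incl_one_excl_missing(self):
        cats = [BOTH] * 6
        labels = [A] * 3 + [I] * 3
        incl = mcp_metrics(cats, labels, "incl")
        assert (incl["sensitivity"], incl["specificity"], incl["ccr"]) == (1.0, 1.0, 1.0)
        excl = mcp_metrics(cats, labels, "excl")
        assert np.isnan(excl["sensitivity"]) and np.isnan(excl["ccr"])

    def test_no_both_or_empty_collapses_to_plain_rates(self):
        cats = [SINGLE_ACTIVE, SINGLE_INACTIVE, SINGLE_INACTIVE, SINGLE_ACTIVE]
        labels = [A, A, I, I]
        incl = mcp_metrics(cats, labels, "incl")
        excl = mcp_metrics(cats, labels, "excl")
        plain = qsar_metrics(labels, [A, I, I, A])
        assert incl == excl == plain

    def test_empty_counts_as_error_in_both_modes(self):
        cats = [SINGLE_ACTIVE, EMPTY]
        labels = [A, A]
        assert mcp_metrics(cats, labels, "incl")["sensitivity"] == 0.5
        assert mcp_metrics(cats, labels, "excl")["sensitivity"] == 0.5

    @given(
        outcomes=st.lists(
            st.tuples(
                st.sampled_from([A, I]),
                st.sampled_from([SINGLE_ACTIVE, SINGLE_INACTIVE, BOTH, EMPTY]),
            ),
            min_size=4,
            max_size=80,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_incl_at_least_excl_and_ccr_identity(self, outcomes):
        labels = [o[0] for o in outcomes]
        cats = [o[1] for o in outcomes]
        for mode in ("incl", "excl"):
            m = mcp_metrics(cats, labels, mode)
            if not np.isnan(m["ccr"]):
                assert m["ccr"] == pytest.approx((m["sensitivity"] + m["specificity"]) / 2)
        incl, excl = mcp_metrics(cats, labels, "incl"), mcp_metrics(cats, labels, "excl")
        for k in ("sensitivity", "specificity"):
            if not (np.isnan(incl[k]) or np.isnan(excl[k])):
                assert incl[k] >= excl[k] - 1e-12


class TestValidity:
    def test_error_rate_against_epsilon(self):
        cats = [SINGLE_ACTIVE] * 85 + [SINGLE_INACTIVE] * 15
        labels = [A] * 100
        v = validity(cats, labels, 0.20)
        assert v == {"error_rate": pytest.approx(0.15), "valid": True}
        cats = [SINGLE_ACTIVE] * 75 + [SINGLE_INACTIVE] * 25
        assert not validity(cats, labels, 0.20)["valid"]

    def test_all_both_is_valid_at_any_epsilon(self):
        cats = [BOTH] * 20
        labels = [A] * 12 + [I] * 8
        for eps in (0.01, 0.1, 0.3):
            v = validity(cats, labels, eps)
            assert v["valid"] and v["error_rate"] == 0.0

    def test_per_class_scope(self):
        cats = [SINGLE_ACTIVE, EMPTY, SINGLE_INACTIVE, SINGLE_INACTIVE]
        labels = [A, A, I, I]
        assert validity(cats, labels, 0.3, scope=A)["error_rate"] == pytest.approx(0.5)
        assert validity(cats, labels, 0.3, scope=I)["error_rate"] == 0.0


class TestSetFractions:
    def test_counts(self):
        cats = [BOTH] * 8 + [EMPTY] * 4 + [SINGLE_ACTIVE] * 88
        fr = set_fractions(cats)
        assert fr["fraction_both"] == pytest.approx(0.08)
        assert fr["fraction_empty"] == pytest.approx(0.04)
        assert fr["fraction_single"] == pytest.approx(0.88)

    def test_boundary_cases(self):
        assert set_fractions([SINGLE_ACTIVE] * 5)["fraction_both"] == 0.0
        assert set_fractions([EMPTY] * 5)["fraction_empty"] == 1.0


class TestTanimoto:
    def _fp(self, on_bits, n=16):
        v = np.zeros(n, dtype=np.uint8)
        v[list(on_bits)] = 1
        return v

    def test_worked_example_half(self):
        a, b = self._fp({1, 2, 3}), self._fp({2, 3, 4})
        assert tanimoto_median([a], [b]) == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        a = self._fp({0, 5})
        assert tanimoto_median([a], [a]) == 1.0
        assert tanimoto_median([a], [self._fp({1, 6})]) == 0.0

    def test_all_zero_pair_defined_as_zero(self):
        z = self._fp(set())
        assert tanimoto_median([z], [z]) == 0.0

    def test_median_over_cross_pairs(self):
        fa = [self._fp({1, 2, 3}), self._fp({1, 2, 3})]
        fb = [self._fp({1, 2, 3}), self._fp({2, 3, 4})]
        # pair similarities: 1, 0.5, 1, 0.5 -> median 0.75
        assert tanimoto_median(fa, fb) == pytest.approx(0.75)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            tanimoto_median(np.empty((0, 8)), [self._fp({1})])


class TestAggregation:
    def test_family_aggregate_unweighted_mean(self):
        df = pd.DataFrame(
            {
                "target_id": ["a", "b", "c"],
                "family": ["kinase", "kinase", "gpcr"],
                "ccr": [0.8, 0.6, 0.9],
            }
        )
        agg = family_aggregate(df, ["ccr"]).set_index("family")["ccr"]
        assert agg["kinase"] == pytest.approx(0.7)
        assert agg["gpcr"] == pytest.approx(0.9)

    def test_confusion_table_layout(self):
        cats = [SINGLE_ACTIVE, SINGLE_INACTIVE, BOTH, EMPTY]
        labels = [A, A, A, A]
        tab = confusion_table(cats, labels).set_index("label")
        assert tab.loc[A].tolist() == [1, 1, 2]  # correct, incorrect, uncertain
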