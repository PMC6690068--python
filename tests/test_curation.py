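"""Record filters, duplicate aggregation, activity labelling, retention."""

import numpy as np
import pandas as pd
import pytest

from conformal_qsar import curation
from conformal_qsar.curation import (
    ACTIVE,
    INACTIVE,
    CurationConfig,
    SchemaError,
    aggregate_duplicates,
    assign_activity_class,
    curate,
    filter_records,
    retain_target,
)

from conftest import make_record, records_frame


class TestFilterRecords:
    @pytest.mark.parametrize(
        "overrides, kept",
        [
            ({}, True),  # clean '=' record with pChEMBL
            ({"relation": "<", "pchembl": 4.0}, True),  # censored inactive
            ({"activity_comment": "inconclusive"}, False),
            ({"activity_comment": "undetermined"}, False),
            ({"activity_comment": "active"}, True),  # only those two strings excluded
            ({"relation": ">", "pchembl": 5.0}, False),
            ({"relation": "~"}, False),
            ({"pchembl": ""}, False),  # no pChEMBL value
            ({"duplicate_flag": True}, False),
            ({"data_validity_comment": "outside typical range"}, False),
            ({"src_id": 7}, False),  # not literature or DrugMatrix
            ({"src_id": 15}, True),
        ],
    )
    def test_single_record_filters(self, overrides, kept):
        df = records_frame([make_record(**overrides)])
        assert len(filter_records(df)) == (1 if kept else 0)

    def test_missing_column_raises_schema_error_naming_it(self):
        df = records_frame([make_record()]).drop(columns=["doc_id"])
        with pytest.raises(SchemaError, match="doc_id"):
            filter_records(df)

    def test_filtering_is_idempotent(self, rng):
        rows = [
            make_record(
                compound_id=f"C{i}",
                relation=rng.choice(["=", "<", ">"]),
                duplicate_flag=bool(rng.random() < 0.3),
                activity_comment=rng.choice(["", "inconclusive", "ok"]),
                src_id=int(rng.choice([1, 15, 3])),
            )
            for i in range(60)
        ]
        once = filter_records(records_frame(rows))
        twice = filter_records(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_configurable_source_allowlist(self):
        df = records_frame([make_record(src_id=15)])
        assert len(filter_records(df, CurationConfig(src_allowlist=(1,)))) == 0


class TestAggregateDuplicates:
    def test_median_odd_and_even(self):
        rows = [make_record(pchembl=v) for v in (6.0, 7.0, 9.0)]
        agg = aggregate_duplicates(records_frame(rows))
        assert agg["median_pchembl"].tolist() == [7.0]
        rows = [make_record(pchembl=v) for v in (6.0, 8.0)]
        agg = aggregate_duplicates(records_frame(rows))
        assert agg["median_pchembl"].tolist() == [7.0]

    def test_only_censored_records_become_censored_inactive(self):
        rows = [make_record(relation="<", pchembl=v) for v in (4.0, 4.5)]
        agg = aggregate_duplicates(records_frame(rows))
        assert agg["censored"].tolist() == [True]
        assert np.isnan(agg["median_pchembl"].iloc[0])

    def test_measured_takes_precedence_over_censored(self):
        rows = [make_record(pchembl=8.0), make_record(relation="<", pchembl=4.0)]
        agg = aggregate_duplicates(records_frame(rows))
        assert len(agg) == 1
        assert not agg["censored"].iloc[0]
        assert agg["median_pchembl"].iloc[0] == 8.0

    def test_permutation_invariance(self, rng):
        rows = [
            make_record(compound_id=f"C{i % 7}", smiles=f"S{i % 7}", pchembl=float(4 + i % 9))
            for i in range(40)
        ]
        a = aggregate_duplicates(records_frame(rows))
        shuffled = records_frame(rows).sample(frac=1.0, random_state=3)
        b = aggregate_duplicates(shuffled)
        a = a.sort_values("smiles").reset_index(drop=True)
        b = b.sort_values("smiles").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_unparsable_structure_dropped_not_crash(self, caplog):
        def canon(s):
            if s == "BAD":
                raise ValueError("no parse")
            return s

        rows = [make_record(), make_record(compound_id="C2", smiles="BAD")]
        with caplog.at_level("WARNING"):
            agg = aggregate_duplicates(records_frame(rows), canonicalize=canon)
        assert agg["compound_id"].tolist() == ["C0001"]

    def test_activity_type_priority_selects_ic50(self):
        df = records_frame(
            [make_record(pchembl=9.0), make_record(pchembl=5.0)]
        )
        df["standard_type"] = ["Ki", "IC50"]
        agg = aggregate_duplicates(df)
        assert agg["median_pchembl"].tolist() == [5.0]


class TestAssignActivityClass:
    @pytest.mark.parametrize(
        "value, family, expected",
        [
            (7.6, "kinase", ACTIVE),
            (7.5, "kinase", ACTIVE),  # threshold boundary counts as active
            (7.4, "kinase", INACTIVE),
            (5.0, "ion_channel", ACTIVE),
            (6.8, "gpcr", INACTIVE),
            (7.0, "nuclear_receptor", ACTIVE),
            (6.5, "protease", ACTIVE),  # unknown family -> 6.5 default
            (6.4, "protease", INACTIVE),
        ],
    )
    def test_family_thresholds(self, value, family, expected):
        assert assign_activity_class(value, family) == expected

    def test_censored_always_inactive(self):
        assert assign_activity_class(np.nan, "kinase", censored=True) == INACTIVE

    def test_override_supersedes_family(self):
        assert assign_activity_class(6.8, "kinase", threshold_override=6.5) == ACTIVE


def _aggregated(n_active, n_inactive, family, lo, hi, n_between=0):
    """Aggregated table: actives >= hi, inactives < lo, n_between in [lo, hi)."""
    rows = []
    for i in range(n_active):
        rows.append((f"C{i}", f"S{i}", hi + 0.5))
    for i in range(n_between):
        rows.append((f"B{i}", f"SB{i}", (lo + hi) / 2))
    for i in range(n_inactive):
        rows.append((f"I{i}", f"SI{i}", lo - 1.0))
    df = pd.DataFrame(rows, columns=["compound_id", "smiles", "median_pchembl"])
    df.insert(0, "target_id", "T")
    df.insert(1, "family", family)
    df["censored"] = False
    return df[["target_id", "family", "compound_id", "smiles", "median_pchembl", "censored"]]


class TestRetainTarget:
    def test_retained_at_family_threshold(self):
        ds = retain_target(_aggregated(45, 35, "gpcr", 6.5, 7.0), n_docs=3)
        assert ds is not None and ds.threshold_used == 7.0
        assert (ds.n_active, ds.n_inactive) == (45, 35)

    def test_rescued_by_default_threshold(self):
        # 39 active at kinase 7.5; 21 compounds between 6.5 and 7.5 lift the
        # active count to 60 when relabelled at the 6.5 default
        ds = retain_target(_aggregated(39, 279, "kinase", 6.5, 7.5, n_between=21), n_docs=5)
        assert ds is not None and ds.threshold_used == 6.5
        assert (ds.n_active, ds.n_inactive) == (60, 279)

    def test_single_publication_discarded(self):
        assert retain_target(_aggregated(100, 100, "gpcr", 6.5, 7.0), n_docs=1) is None

    def test_insufficient_counts_discarded(self):
        assert retain_target(_aggregated(39, 300, "gpcr", 6.8, 7.0), n_docs=3) is None

    def test_relabelling_changes_labels_not_compounds(self):
        table = _aggregated(39, 279, "kinase", 6.5, 7.5, n_between=21)
        ds = retain_target(table, n_docs=5)
        assert sorted(ds.compounds["compound_id"]) == sorted(table["compound_id"])

    def test_ratio(self):
        ds = retain_target(_aggregated(90, 30, "gpcr", 6.5, 7.0), n_docs=2)
        assert ds.ratio == pytest.approx(3.0)
        ds = retain_target(_aggregated(40, 80, "gpcr", 6.5, 7.0), n_docs=2)
        assert ds.ratio == pytest.approx(0.5)


class TestCurateInvariants:
    def test_retained_datasets_satisfy_type_invariants(self):
        from conformal_qsar.synthetic import SyntheticConfig, generate_activity_table

        data = generate_activity_table(SyntheticConfig(n_targets=4, n_compounds=150, seed=9))
        datasets, summary = curate(data.records)
        assert len(datasets) >= 1
        for ds in datasets.values():
            assert ds.n_active >= 40 and ds.n_inactive >= 30
            assert ds.n_docs >= 2
            assert ds.compounds["compound_id"].is_unique
            assert ds.threshold_used in (
                curation.family_threshold(ds.family),
                curation.DEFAULT_THRESHOLD,
            )

    def test_summary_covers_all_targets(self):
        from conformal_qsar.synthetic import SyntheticConfig, generate_activity_table

        data = generate_activity_table(SyntheticConfig(n_targets=3, n_compounds=100, seed=2))
        _, summary = curate(data.records)
        assert set(summary["target_id"]) == set(data.records["target_id"])
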