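"""ChEMBL-style bioactivity curation: record filters, duplicate aggregation,
activity labelling and target retention.

The pipeline turns a raw activity table (one row per measurement) into one
modelling-ready dataset per protein target:

1. record filters — keep literature/DrugMatrix sources, relations '=' (exact
   pChEMBL) and '<' (censored, high-quality inactive), drop flagged
   duplicates, validity comments and inconclusive/undetermined activities;
2. per-(target, structure) aggregation — median of the exact pChEMBL values;
   structures with only censored records are carried as censored-inactive;
3. class assignment — active iff median pChEMBL >= the protein-family potency
   threshold (kinases 7.5, GPCRs 7, nuclear receptors 7, ion channels 5,
   everything else 6.5); censored compounds are inactive;
4. retention — a target needs data from at least two publications and at
   least 40 active / 30 inactive compounds under its family threshold,
   falling back to relabelling everything at the 6.5 default before giving up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ._util import as_bool_series

log = logging.getLogger(__name__)

ACTIVE = "active"
INACTIVE = "inactive"

#: Illuminating-the-Druggable-Genome per-family pChEMBL activity thresholds
IDG_THRESHOLDS = {
    "kinase": 7.5,
    "gpcr": 7.0,
    "nuclear_receptor": 7.0,
    "ion_channel": 5.0,
}
DEFAULT_THRESHOLD = 6.5

MANDATORY_COLUMNS = (
    "target_id",
    "family",
    "compound_id",
    "smiles",
    "relation",
    "pchembl",
    "doc_id",
    "src_id",
    "duplicate_flag",
    "data_validity_comment",
    "activity_comment",
)

_EXCLUDED_COMMENTS = {"inconclusive", "undetermined"}


class SchemaError(ValueError):
    """Input table is missing a mandatory column."""


@dataclass(frozen=True)
class CurationConfig:
    src_allowlist: tuple[int, ...] = (1, 15)
    #: activity-type priority applied per (target, structure, source) when a
    #: `standard_type` column is present (DrugMatrix carries both Ki and IC50
    #: for each pair; IC50 is preferred)
    type_priority: tuple[str, ...] = ("IC50", "Ki")
    min_active: int = 40
    min_inactive: int = 30
    min_docs: int = 2
    default_threshold: float = DEFAULT_THRESHOLD


@dataclass
class TargetDataset:
    """Curated, labelled compound set for one target."""

    target_id: str
    family: str
    threshold_used: float
    compounds: pd.DataFrame  # compound_id, smiles, median_pchembl, label
    n_docs: int

    def __post_init__(self):
        counts = self.compounds["label"].value_counts()
        self.n_active = int(counts.get(ACTIVE, 0))
        self.n_inactive = int(counts.get(INACTIVE, 0))

    @property
    def ratio(self) -> float:
        """Active:inactive ratio (the imbalance statistic reported per target)."""
        return self.n_active / self.n_inactive

    @property
    def labels(self) -> np.ndarray:
        return self.compounds["label"].to_numpy()


def family_threshold(family: str, override: float | None = None) -> float:
    """Activity threshold for a family, or the 6.5 default for unknown ones."""
    if override is not None:
        return float(override)
    try:
        return IDG_THRESHOLDS[str(family)]
    except KeyError:
        log.info("unknown protein family %r: using default threshold %.1f", family, DEFAULT_THRESHOLD)
        return DEFAULT_THRESHOLD


def _check_schema(df: pd.DataFrame) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")


def filter_records(df: pd.DataFrame, config: CurationConfig = CurationConfig()) -> pd.DataFrame:
    """Apply the record-level quality filters.

    Keeps rows whose relation is '=' or '<' with a pChEMBL value present, not
    flagged as potential duplicates, with no data-validity comment, whose
    activity comment is neither 'inconclusive' nor 'undetermined', and whose
    source is in the allow-list.
    """
    _check_schema(df)
    relation = df["relation"].astype(str).str.strip()
    pchembl = pd.to_numeric(df["pchembl"], errors="coerce")
    comment = df["activity_comment"].fillna("").astype(str).str.strip().str.lower()
    validity = df["data_validity_comment"].fillna("").astype(str).str.strip()
    src = pd.to_numeric(df["src_id"], errors="coerce")

    keep = (
        relation.isin(["=", "<"])
        & pchembl.notna()
        & ~as_bool_series(df["duplicate_flag"])
        & (validity == "")
        & ~comment.isin(_EXCLUDED_COMMENTS)
        & src.isin(list(config.src_allowlist))
    )
    out = df.loc[keep].copy()
    out["relation"] = relation[keep]
    out["pchembl"] = pchembl[keep]
    return out


def _select_activity_type(df: pd.DataFrame, config: CurationConfig) -> pd.DataFrame:
    """Per (target, structure, source): keep only the highest-priority
    activity type present.  No-op when the table has no `standard_type`."""
    if "standard_type" not in df.columns:
        return df
    rank = {t: i for i, t in enumerate(config.type_priority)}
    r = df["standard_type"].map(lambda t: rank.get(t, len(rank))).to_numpy()
    df = df.assign(_type_rank=r)
    best = df.groupby(["target_id", "smiles", "src_id"])["_type_rank"].transform("min")
    return df.loc[df["_type_rank"] == best].drop(columns="_type_rank")


def aggregate_duplicates(
    df: pd.DataFrame,
    config: CurationConfig = CurationConfig(),
    canonicalize: Callable[[str], str] | None = None,
) -> pd.DataFrame:
    """Collapse to one row per (target, canonical structure).

    Exact ('=') pChEMBL values are median-aggregated; a structure with only
    censored ('<') records is kept as censored-inactive (``censored=True``,
    ``median_pchembl=NaN``).  Unparsable structures are dropped with a logged
    warning.  Returns columns: target_id, family, compound_id, smiles,
    median_pchembl, censored.
    """
    df = df.copy()
    if canonicalize is not None:
        canon, bad = {}, []
        for smi in pd.unique(df["smiles"]):
            try:
                canon[smi] = canonicalize(smi)
            except Exception:
                bad.append(smi)
        if bad:
            log.warning("dropping %d record(s) with unparsable structures", int(df["smiles"].isin(bad).sum()))
            df = df.loc[~df["smiles"].isin(bad)]
        df["smiles"] = df["smiles"].map(canon)

    df = _select_activity_type(df, config)

    rows = []
    for (target, smi), grp in df.groupby(["target_id", "smiles"], sort=False):
        measured = grp.loc[grp["relation"] == "=", "pchembl"]
        rows.append(
            {
                "target_id": target,
                "family": grp["family"].iloc[0],
                "compound_id": grp["compound_id"].iloc[0],
                "smiles": smi,
                # '=' takes precedence over '<' for the same structure
                "median_pchembl": float(measured.median()) if len(measured) else np.nan,
                "censored": len(measured) == 0,
            }
        )
    return pd.DataFrame(
        rows, columns=["target_id", "family", "compound_id", "smiles", "median_pchembl", "censored"]
    )


def assign_activity_class(
    median_pchembl: float,
    family: str,
    threshold_override: float | None = None,
    censored: bool = False,
) -> str:
    """Label one aggregated compound.

    Censored-inactive compounds are always inactive; measured compounds are
    active iff the median pChEMBL is >= the threshold (family value, or the
    override — in practice the 6.5 fallback).
    """
    if censored or pd.isna(median_pchembl):
        return INACTIVE
    thr = family_threshold(family, threshold_override)
    return ACTIVE if median_pchembl >= thr else INACTIVE


def retain_target(
    aggregated: pd.DataFrame,
    n_docs: int,
    config: CurationConfig = CurationConfig(),
) -> TargetDataset | None:
    """Retention decision for one target's aggregated compounds.

    Requires >= 2 publications first; then tries the family threshold, then
    the 6.5 fallback, against the 40-active / 30-inactive floor.  Relabelling
    at 6.5 changes labels only, never the compound set.
    """
    if n_docs < config.min_docs:
        return None
    target_id = aggregated["target_id"].iloc[0]
    family = aggregated["family"].iloc[0]
    for threshold in _candidate_thresholds(family, config):
        labels = [
            assign_activity_class(v, family, threshold, censored=c)
            for v, c in zip(aggregated["median_pchembl"], aggregated["censored"])
        ]
        table = aggregated[["compound_id", "smiles", "median_pchembl"]].copy()
        table["label"] = labels
        ds = TargetDataset(str(target_id), str(family), threshold, table.reset_index(drop=True), int(n_docs))
        if ds.n_active >= config.min_active and ds.n_inactive >= config.min_inactive:
            return ds
    return None


def _candidate_thresholds(family, config: CurationConfig) -> list[float]:
    fam = family_threshold(family)
    return [fam] if fam == config.default_threshold else [fam, config.default_threshold]


def active_inactive_ratio(dataset: TargetDataset) -> float:
    return dataset.ratio


def curate(
    df: pd.DataFrame,
    config: CurationConfig = CurationConfig(),
    canonicalize: Callable[[str], str] | None = None,
) -> tuple[dict[str, TargetDataset], pd.DataFrame]:
    """Full curation: filter, aggregate, label, retain — per target.

    Returns retained datasets keyed by target id plus a run summary with one
    row per input target (retained or not).
    """
    filtered = filter_records(df, config)
    summary_rows = []
    datasets: dict[str, TargetDataset] = {}
    docs_per_target = filtered.groupby("target_id")["doc_id"].nunique()
    aggregated = aggregate_duplicates(filtered, config, canonicalize)
    for target, grp in aggregated.groupby("target_id", sort=False):
        n_docs = int(docs_per_target.get(target, 0))
        ds = retain_target(grp, n_docs, config)
        if ds is not None:
            datasets[str(target)] = ds
        summary_rows.append(
            {
                "target_id": target,
                "retained": ds is not None,
                "threshold_used": ds.threshold_used if ds else np.nan,
                "n_active": ds.n_active if ds else np.nan,
                "n_inactive": ds.n_inactive if ds else np.nan,
                "ratio": ds.ratio if ds else np.nan,
                "n_docs": n_docs,
            }
        )
    return datasets, pd.DataFrame(summary_rows)


def label_with_threshold(
    aggregated: pd.DataFrame, family: str, threshold: float
) -> pd.DataFrame:
    """Label an aggregated table at a fixed threshold (temporal validation
    reuses the training release's ``threshold_used``)."""
    table = aggregated[["compound_id", "smiles", "median_pchembl"]].copy()
    table["label"] = [
        assign_activity_class(v, family, threshold, censored=c)
        for v, c in zip(aggregated["median_pchembl"], aggregated["censored"])
    ]
    return table.reset_index(drop=True)
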