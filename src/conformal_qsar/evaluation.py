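"""The metric family for both arms, and the temporal-validation workflow.

Sensitivity = TP/(TP+FN) over active compounds, specificity = TN/(TN+FP)
over inactives, CCR = their mean.  For conformal prediction sets the
``incl`` variants count 'both' assignments as correct while the ``excl``
variants drop those compounds from numerator and denominator; 'empty'
assignments are errors in every variant.  A Mondrian predictor is *valid*
at significance eps if its error rate (true class outside the prediction
set) does not exceed eps — overall or restricted to one class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import conformal, curation
from .conformal import ACTIVE, BOTH, EMPTY, INACTIVE, SINGLE_ACTIVE, SINGLE_INACTIVE

_SINGLE = {ACTIVE: SINGLE_ACTIVE, INACTIVE: SINGLE_INACTIVE}


def qsar_metrics(labels, predicted) -> dict:
    """Plain sensitivity/specificity/CCR from hard class predictions."""
    labels = np.asarray(labels, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    out = {}
    for cls, name in ((ACTIVE, "sensitivity"), (INACTIVE, "specificity")):
        mask = labels == cls
        out[name] = float(np.mean(predicted[mask] == cls)) if mask.any() else np.nan
    out["ccr"] = _ccr(out["sensitivity"], out["specificity"])
    return out


def mcp_metrics(categories, labels, mode: str) -> dict:
    """Sensitivity/specificity/CCR from prediction-set categories.

    ``mode="incl"``: 'both' counts as correct, denominator is the whole
    class.  ``mode="excl"``: 'both' compounds are dropped entirely; 'empty'
    remains an error.  An empty excl denominator yields NaN for that rate.
    """
    if mode not in ("incl", "excl"):
        raise ValueError("mode must be 'incl' or 'excl'")
    categories = np.asarray(categories, dtype=object)
    labels = np.asarray(labels, dtype=object)
    out = {}
    for cls, name in ((ACTIVE, "sensitivity"), (INACTIVE, "specificity")):
        cats = categories[labels == cls]
        if mode == "excl":
            cats = cats[cats != BOTH]
            correct = cats == _SINGLE[cls]
        else:
            correct = (cats == _SINGLE[cls]) | (cats == BOTH)
        out[name] = float(np.mean(correct)) if len(cats) else np.nan
    out["ccr"] = _ccr(out["sensitivity"], out["specificity"])
    return out


def _ccr(sens: float, spec: float) -> float:
    return np.nan if (np.isnan(sens) or np.isnan(spec)) else (sens + spec) / 2.0


def validity(categories, labels, epsilon: float, scope: str = "overall") -> dict:
    """Conformal validity at significance ``epsilon``.

    An error is a compound whose true class is outside its prediction set
    (wrong single class or empty); 'both' always contains the truth.
    ``scope`` is ``"overall"``, ``"active"`` or ``"inactive"``.
    """
    categories = np.asarray(categories, dtype=object)
    labels = np.asarray(labels, dtype=object)
    if scope != "overall":
        mask = labels == scope
        categories, labels = categories[mask], labels[mask]
    in_set = np.array(
        [conformal.ACTIVE in conformal.set_members(c) if l == ACTIVE
         else conformal.INACTIVE in conformal.set_members(c)
         for c, l in zip(categories, labels)]
    ) if len(categories) else np.array([], dtype=bool)
    error_rate = float(np.mean(~in_set)) if len(in_set) else np.nan
    return {"error_rate": error_rate, "valid": bool(error_rate <= epsilon) if len(in_set) else None}


def set_fractions(categories) -> dict:
    """Fractions of compounds in the 'both' / 'empty' prediction classes."""
    categories = np.asarray(categories, dtype=object)
    n = len(categories)
    both = float(np.mean(categories == BOTH)) if n else np.nan
    empty = float(np.mean(categories == EMPTY)) if n else np.nan
    return {
        "fraction_both": both,
        "fraction_empty": empty,
        "fraction_single": 1.0 - both - empty if n else np.nan,
    }


def tanimoto_median(fps_a: np.ndarray, fps_b: np.ndarray) -> float:
    """Median Tanimoto coefficient over all cross-set fingerprint pairs.

    Tanimoto(a, b) = |a AND b| / |a OR b| on the on-bits; a pair of all-zero
    fingerprints has similarity 0 by convention.
    """
    a = np.atleast_2d(np.asarray(fps_a, dtype=np.int64))
    b = np.atleast_2d(np.asarray(fps_b, dtype=np.int64))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both fingerprint sets must be non-empty")
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return float(np.median(sim))


def family_aggregate(per_target: pd.DataFrame, metric_cols=None) -> pd.DataFrame:
    """Unweighted mean of per-target metrics within each protein family."""
    if metric_cols is None:
        metric_cols = [c for c in per_target.columns if per_target[c].dtype.kind == "f"]
    return per_target.groupby("family")[list(metric_cols)].mean().reset_index()


def confusion_table(categories, labels) -> pd.DataFrame:
    """Correct / incorrect / uncertain counts per true class, where
    uncertain = 'both' + 'empty' (the layout used for temporal comparisons)."""
    categories = np.asarray(categories, dtype=object)
    labels = np.asarray(labels, dtype=object)
    rows = []
    for cls in (ACTIVE, INACTIVE):
        cats = categories[labels == cls]
        rows.append(
            {
                "label": cls,
                "correct": int(np.sum(cats == _SINGLE[cls])),
                "incorrect": int(np.sum(cats == _SINGLE[ACTIVE if cls == INACTIVE else INACTIVE])),
                "uncertain": int(np.sum((cats == BOTH) | (cats == EMPTY))),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# temporal validation


@dataclass
class TemporalReport:
    """Pooled new-compound performance of models from an earlier release."""

    n_targets: int
    n_new_compounds: int
    qsar: dict  # pooled sensitivity/specificity/ccr on the temporal set
    mcp: dict  # {eps: {"incl": metrics, "excl": metrics, "fractions": ..., "validity": ...}}
    internal_qsar: dict  # pooled internal (within-release) metrics, for reference
    internal_mcp: dict
    per_target: pd.DataFrame


def temporal_validation(
    release_a: pd.DataFrame,
    release_b: pd.DataFrame,
    featurizer,
    split_plan=None,
    rf_config=None,
    epsilons=(0.30, 0.20, 0.10),
    p_value_mode: str = "adjusted",
    curation_config=None,
    canonicalize=None,
    min_compounds: int = 10,
) -> TemporalReport:
    """Train per-target models on release A; evaluate on release B's new compounds.

    New compounds are release-B structures (canonical non-stereo SMILES)
    absent from release A for the same target, labelled with the threshold
    the release-A model used.  Predictions are pooled over targets; targets
    with fewer than ``min_compounds`` new compounds get NaN in the
    per-target frame (they still contribute to the pool).
    """
    from .protocol import BenchmarkProtocol, SplitPlan, set_column

    split_plan = split_plan or SplitPlan()
    rf_config = rf_config or _default_rf()
    curation_config = curation_config or curation.CurationConfig()

    datasets, _ = curation.curate(release_a, curation_config, canonicalize)
    if not datasets:
        import warnings

        warnings.warn("no targets retained from the model release; empty temporal report")
        return TemporalReport(0, 0, {}, {}, {}, {}, pd.DataFrame())

    filtered_b = curation.filter_records(release_b, curation_config)
    aggregated_b = curation.aggregate_duplicates(filtered_b, curation_config, canonicalize)

    pooled_rows = []
    internal_rows = []
    per_target_rows = []
    n_targets_used = 0
    for target_id, ds in datasets.items():
        grp = aggregated_b.loc[aggregated_b["target_id"].astype(str) == target_id]
        new = grp.loc[~grp["smiles"].isin(set(ds.compounds["smiles"]))]
        if len(new) == 0:
            continue
        labelled = curation.label_with_threshold(new, ds.family, ds.threshold_used)
        if labelled["label"].nunique() == 0:
            continue
        bits_a, phys_a = featurizer(ds.compounds)
        bits_n, phys_n = featurizer(labelled)
        proto = BenchmarkProtocol(
            bits_a,
            ds.labels,
            split_plan,
            rf_config,
            epsilons,
            p_value_mode,
            physchem=phys_a,
            X_external=bits_n,
            physchem_external=phys_n,
        )
        res = proto.run()
        n_targets_used += 1
        ext = res.external.copy()
        ext["label"] = labelled["label"].to_numpy()
        ext["target_id"] = target_id
        pooled_rows.append(ext)
        internal = res.outcomes.copy()
        internal["target_id"] = target_id
        internal_rows.append(internal)
        per_target_rows.append(
            {
                "target_id": target_id,
                "family": ds.family,
                "n_new": len(ext),
                "temporal_ccr": qsar_metrics(ext["label"], ext["qsar_class"])["ccr"]
                if len(ext) >= min_compounds
                else np.nan,
            }
        )

    if not pooled_rows:
        import warnings

        warnings.warn("no overlapping targets with new compounds; empty temporal report")
        return TemporalReport(0, 0, {}, {}, {}, {}, pd.DataFrame())

    pooled = pd.concat(pooled_rows, ignore_index=True)
    # internal outcomes may contain compounds never sampled into a test set
    internal = (
        pd.concat(internal_rows, ignore_index=True)
        .dropna(subset=["qsar_median_prob", "p_active_median"])
    )

    def _mcp_block(frame):
        block = {}
        for eps in epsilons:
            cats = frame[set_column(eps)]
            block[eps] = {
                "incl": mcp_metrics(cats, frame["label"], "incl"),
                "excl": mcp_metrics(cats, frame["label"], "excl"),
                "fractions": set_fractions(cats),
                "validity": validity(cats, frame["label"], eps),
            }
        return block

    return TemporalReport(
        n_targets=n_targets_used,
        n_new_compounds=len(pooled),
        qsar=qsar_metrics(pooled["label"], pooled["qsar_class"]),
        mcp=_mcp_block(pooled),
        internal_qsar=qsar_metrics(internal["label"], internal["qsar_class"]),
        internal_mcp=_mcp_block(internal),
        per_target=pd.DataFrame(per_target_rows),
    )


def _default_rf():
    from .models import RFConfig

    return RFConfig()
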