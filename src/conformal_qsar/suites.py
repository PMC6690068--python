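"""Synthetic benchmark suites: validity, class-assignment trends, parameter
recovery, class-weighting effect and temporal robustness.

Each suite generates synthetic targets under stated study conditions, runs
the modelling arms through the shared repeated-split protocol, and returns
the aggregate quantities of interest.  Problem sizes default to
desk-scale settings (tens of targets, a few hundred compounds, ~100-tree
forests, single-digit repeat counts) chosen so a full run of every suite
completes in minutes on one core; the library-level defaults for real
analyses remain 100 repeats and 300 trees.
"""

from __future__ import annotations

import numpy as np

from ._util import derive_seeds
from .curation import curate
from .evaluation import qsar_metrics, temporal_validation
from .models import RFConfig
from .protocol import DEFAULT_EPSILONS, BenchmarkProtocol, SplitPlan
from .synthetic import (
    SyntheticConfig,
    generate_features,
    generate_activity_table,
    generate_temporal_pair,
)


def validity_suite(
    seed: int,
    n_targets: int = 50,
    n_compounds: int = 250,
    separability: float = 0.5,
    active_fraction: float = 4.0 / 9.0,
    n_repeats: int = 9,
    n_trees: int = 100,
    epsilons=DEFAULT_EPSILONS,
) -> dict:
    """Per-class conformal error rates and model validity on exchangeable data.

    Runs the MCP arm (adjusted p-values) on ``n_targets`` independent
    synthetic targets and pools per-class errors; a model is valid at a
    significance level if its overall error rate does not exceed it.
    Returns per-epsilon pooled error rates, their 3-sigma binomial bounds,
    and the fraction of valid models.
    """
    t_seeds = derive_seeds(seed, n_targets, key="validity")
    errors = {e: {"active": [0, 0], "inactive": [0, 0]} for e in epsilons}
    valid = {e: 0 for e in epsilons}
    for t in range(n_targets):
        s = int(t_seeds[t])
        bits, phys, y = generate_features(
            n_compounds, active_fraction, separability, 8, seed=s
        )
        res = BenchmarkProtocol(
            bits, y,
            SplitPlan(n_repeats=n_repeats, master_seed=s),
            RFConfig(n_trees=n_trees, seed=s),
            epsilons, "adjusted", physchem=phys, run_qsar=False,
        ).run()
        for eps in epsilons:
            v = res.validity(eps)
            valid[eps] += int(v["valid"])
            for cls in ("active", "inactive"):
                pc = res.validity(eps, scope=cls)
                done = res.outcomes.dropna(subset=["p_active_median"])
                n_cls = int((done["label"] == cls).sum())
                errors[eps][cls][0] += round(pc["error_rate"] * n_cls)
                errors[eps][cls][1] += n_cls
    out = {"n_targets": n_targets, "epsilons": list(epsilons), "per_class": {}, "valid_fraction": {}}
    for eps in epsilons:
        out["valid_fraction"][eps] = valid[eps] / n_targets
        out["per_class"][eps] = {}
        for cls in ("active", "inactive"):
            k, n = errors[eps][cls]
            se = np.sqrt(eps * (1 - eps) / n)
            out["per_class"][eps][cls] = {
                "error_rate": k / n,
                "n": n,
                "bound": eps + 3 * se,
            }
    return out


def trend_suite(
    seed: int,
    n_targets: int = 8,
    n_compounds: int = 400,
    separability: float = 0.5,
    n_repeats: int = 9,
    n_trees: int = 100,
    epsilons=DEFAULT_EPSILONS,
) -> dict:
    """Pooled 'both'/'empty' fractions across confidence levels 70/80/90%."""
    t_seeds = derive_seeds(seed, n_targets, key="trend")
    counts = {e: {"both": 0, "empty": 0, "n": 0} for e in epsilons}
    for t in range(n_targets):
        s = int(t_seeds[t])
        bits, phys, y = generate_features(n_compounds, 4.0 / 9.0, separability, 8, seed=s)
        res = BenchmarkProtocol(
            bits, y,
            SplitPlan(n_repeats=n_repeats, master_seed=s),
            RFConfig(n_trees=n_trees, seed=s),
            epsilons, "adjusted", physchem=phys, run_qsar=False,
        ).run()
        done = res.outcomes.dropna(subset=["p_active_median"])
        from .protocol import set_column

        for eps in epsilons:
            cats = done[set_column(eps)]
            counts[eps]["both"] += int((cats == "both").sum())
            counts[eps]["empty"] += int((cats == "empty").sum())
            counts[eps]["n"] += len(cats)
    return {
        eps: {
            "fraction_both": c["both"] / c["n"],
            "fraction_empty": c["empty"] / c["n"],
            "n": c["n"],
        }
        for eps, c in counts.items()
    }


def recovery_suite(
    seed: int,
    separability: float,
    n_targets: int = 20,
    n_compounds: int = 400,
    n_repeats: int = 6,
    n_trees: int = 100,
) -> dict:
    """Full-pipeline parameter recovery: generate -> curate -> QSAR CCR.

    With high separability and no label noise the hidden labels should be
    recovered almost perfectly; with zero separability CCR should sit at
    chance level.
    """
    cfg = SyntheticConfig(
        n_targets=n_targets, n_compounds=n_compounds,
        separability=separability, label_noise=0.0, seed=seed,
    )
    data = generate_activity_table(cfg)
    datasets, _ = curate(data.records)
    featurize = data.featurizer()
    ccrs = []
    t_seeds = derive_seeds(seed, len(datasets), key="recovery")
    for i, ds in enumerate(datasets.values()):
        bits, phys = featurize(ds.compounds)
        res = BenchmarkProtocol(
            bits, ds.labels,
            SplitPlan(n_repeats=n_repeats, master_seed=int(t_seeds[i])),
            RFConfig(n_trees=n_trees, seed=int(t_seeds[i])),
            physchem=phys, run_mcp=False,
        ).run()
        ccrs.append(res.qsar_metrics()["ccr"])
    return {"n_targets": len(ccrs), "mean_ccr": float(np.mean(ccrs)), "ccrs": ccrs}


def weighting_suite(
    seed: int,
    ratio: float = 0.15,
    separability: float = 0.7,
    n_targets: int = 8,
    n_compounds: int = 400,
    n_repeats: int = 6,
    n_trees: int = 100,
) -> dict:
    """Paired effect of inverse-frequency class weights on imbalanced targets.

    For each synthetic target (active:inactive ratio ``ratio``) the QSAR arm
    is run twice under identical seeds, with and without class weighting;
    reports the mean |sensitivity - specificity| gap for both settings.
    """
    active_fraction = ratio / (1.0 + ratio)
    t_seeds = derive_seeds(seed, n_targets, key="weighting")
    gaps = {True: [], False: []}
    for t in range(n_targets):
        s = int(t_seeds[t])
        bits, phys, y = generate_features(
            n_compounds, active_fraction, separability, 8, seed=s
        )
        for weighted in (True, False):
            res = BenchmarkProtocol(
                bits, y,
                SplitPlan(n_repeats=n_repeats, master_seed=s),
                RFConfig(n_trees=n_trees, class_weighting=weighted, seed=s),
                physchem=phys, run_mcp=False,
            ).run()
            m = res.qsar_metrics()
            gaps[weighted].append(abs(m["sensitivity"] - m["specificity"]))
    return {
        "gap_weighted": float(np.mean(gaps[True])),
        "gap_unweighted": float(np.mean(gaps[False])),
        "per_target_weighted": gaps[True],
        "per_target_unweighted": gaps[False],
    }


def temporal_suite(
    seed: int,
    temporal_shift: float,
    n_targets: int = 6,
    n_compounds: int = 300,
    temporal_new_fraction: float = 0.25,
    n_repeats: int = 9,
    n_trees: int = 100,
) -> dict:
    """Temporal workflow on a synthetic release pair.

    With ``temporal_shift=0`` the new compounds are exchangeable with the
    training release and pooled temporal CCR should match internal CCR;
    a positive shift lowers the new compounds' separability and should
    lower temporal CCR.
    """
    cfg = SyntheticConfig(
        n_targets=n_targets, n_compounds=n_compounds,
        temporal_new_fraction=temporal_new_fraction,
        temporal_shift=temporal_shift, seed=seed,
    )
    release_a, release_b = generate_temporal_pair(cfg)
    rep = temporal_validation(
        release_a.records, release_b.records, release_b.featurizer(),
        split_plan=SplitPlan(n_repeats=n_repeats, master_seed=seed),
        rf_config=RFConfig(n_trees=n_trees, seed=seed),
    )
    return {
        "n_targets": rep.n_targets,
        "n_new_compounds": rep.n_new_compounds,
        "temporal_ccr": rep.qsar["ccr"],
        "internal_ccr": rep.internal_qsar["ccr"],
        "mcp": rep.mcp,
    }
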