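"""Repeated-split benchmark protocol shared by both modelling arms.

For each repeat the dataset is split 80/20 (stratified on the activity
class) with a per-repeat seed; both arms use *exactly the same* split so
their test sets coincide.  The QSAR arm trains a forest on the full training
portion; the MCP arm further splits the training portion 70/30 into proper
training and calibration sets.  A compound's final outcome is the median of
its per-repeat predictions over the repeats in which it landed in the test
set: median P(active) (hard class at 0.5) for QSAR, median p-value pair
(prediction sets at each significance level) for MCP.

External compounds (temporal validation) are predicted by every repeat's
models and median-aggregated over all repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import conformal
from ._util import derive_seeds
from .conformal import ACTIVE, INACTIVE
from .features import PhyschemScaler, assemble_features
from .models import (
    RFConfig,
    _build_forest,
    split_proper_calibration,
    stratified_split,
)

DEFAULT_EPSILONS = (0.30, 0.20, 0.10)


@dataclass(frozen=True)
class SplitPlan:
    """Shared splitting schedule for the two arms."""

    n_repeats: int = 100
    test_fraction: float = 0.20
    calibration_fraction: float = 0.30  # of the training portion
    master_seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not (0 < self.test_fraction < 1 and 0 < self.calibration_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")

    @property
    def seeds(self) -> np.ndarray:
        """One split seed per repeat, identical for both arms."""
        return derive_seeds(self.master_seed, self.n_repeats, key="split")

    @property
    def calibration_seeds(self) -> np.ndarray:
        return derive_seeds(self.master_seed, self.n_repeats, key="calibration-split")

    @property
    def model_seeds(self) -> np.ndarray:
        return derive_seeds(self.master_seed, self.n_repeats, key="model")


class BenchmarkProtocol:
    """Run both arms under shared repeated splits on one target's data.

    Parameters
    ----------
    X : assembled feature matrix, or fingerprint bits if ``physchem`` given.
    y : activity labels.
    physchem : optional raw six-descriptor block; when given, a min-max
        scaler is fitted on each repeat's training portion only (set
        ``scaler_scope="global"`` to fit once on the whole dataset instead)
        and X is treated as the fingerprint block.
    X_external, physchem_external : optional compounds outside the dataset
        (e.g. a temporal set) predicted by every repeat's models.
    """

    def __init__(
        self,
        X: np.ndarray,
        y,
        split_plan: SplitPlan = SplitPlan(),
        rf_config: RFConfig = RFConfig(),
        epsilons=DEFAULT_EPSILONS,
        p_value_mode: str = "adjusted",
        physchem: np.ndarray | None = None,
        scaler_scope: str = "per-split",
        X_external: np.ndarray | None = None,
        physchem_external: np.ndarray | None = None,
        run_qsar: bool = True,
        run_mcp: bool = True,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = conformal._normalize_labels(y)
        self.plan = split_plan
        self.rf_config = rf_config
        self.epsilons = tuple(float(e) for e in epsilons)
        if any(not 0 < e < 1 for e in self.epsilons):
            raise ValueError("epsilon values must lie in (0, 1)")
        if p_value_mode not in conformal.P_VALUE_MODES:
            raise ValueError(f"unknown p-value mode {p_value_mode!r}")
        self.p_value_mode = p_value_mode
        self.physchem = None if physchem is None else np.asarray(physchem, dtype=float)
        if scaler_scope not in ("per-split", "global"):
            raise ValueError("scaler_scope must be 'per-split' or 'global'")
        self.scaler_scope = scaler_scope
        self.X_external = None if X_external is None else np.asarray(X_external, dtype=float)
        self.physchem_external = (
            None if physchem_external is None else np.asarray(physchem_external, dtype=float)
        )
        self.run_qsar = run_qsar
        self.run_mcp = run_mcp

    def _features(self, train_idx):
        """Assembled features for (dataset, external), scaling physchem on
        the training portion when a raw block is supplied."""
        if self.physchem is None:
            return self.X, self.X_external
        scaler = PhyschemScaler()
        fit_on = self.physchem if self.scaler_scope == "global" else self.physchem[train_idx]
        scaler.fit(fit_on)
        X = assemble_features(self.X, scaler.transform(self.physchem))
        X_ext = None
        if self.X_external is not None:
            X_ext = assemble_features(self.X_external, scaler.transform(self.physchem_external))
        return X, X_ext

    def run(self) -> "BenchmarkResults":
        n = len(self.y)
        n_ext = 0 if self.X_external is None else len(self.X_external)
        qsar_probs = [[] for _ in range(n)]
        mcp_pa = [[] for _ in range(n)]
        mcp_pi = [[] for _ in range(n)]
        ext_probs = [[] for _ in range(n_ext)]
        ext_pa = [[] for _ in range(n_ext)]
        ext_pi = [[] for _ in range(n_ext)]

        plan = self.plan
        for r in range(plan.n_repeats):
            split_seed = int(plan.seeds[r])
            model_seed = int(plan.model_seeds[r])
            train, test = stratified_split(self.X, self.y, plan.test_fraction, split_seed)
            X, X_ext = self._features(train)

            if self.run_qsar:
                cfg = RFConfig(
                    self.rf_config.n_trees, self.rf_config.max_depth,
                    self.rf_config.class_weighting, model_seed,
                )
                forest = _build_forest(cfg).fit(X[train], self.y[train])
                col = list(forest.classes_).index(1)
                for i, p in zip(test, forest.predict_proba(X[test])[:, col]):
                    qsar_probs[i].append(p)
                if n_ext:
                    for i, p in enumerate(forest.predict_proba(X_ext)[:, col]):
                        ext_probs[i].append(p)

            if self.run_mcp:
                proper, cal = split_proper_calibration(
                    X[train], self.y[train], plan.calibration_fraction,
                    int(plan.calibration_seeds[r]),
                )
                cfg = RFConfig(
                    self.rf_config.n_trees, self.rf_config.max_depth,
                    self.rf_config.class_weighting, model_seed,
                )
                forest = _build_forest(cfg).fit(X[train][proper], self.y[train][proper])
                col = list(forest.classes_).index(1)
                calibration = conformal.calibrate(
                    forest.predict_proba(X[train][cal])[:, col], self.y[train][cal]
                )
                pv = conformal.p_values(
                    calibration, forest.predict_proba(X[test])[:, col], self.p_value_mode
                )
                for i, (pa, pi) in zip(test, pv):
                    mcp_pa[i].append(pa)
                    mcp_pi[i].append(pi)
                if n_ext:
                    pv_ext = conformal.p_values(
                        calibration, forest.predict_proba(X_ext)[:, col], self.p_value_mode
                    )
                    for i, (pa, pi) in enumerate(pv_ext):
                        ext_pa[i].append(pa)
                        ext_pi[i].append(pi)

        outcomes = self._aggregate(self.y, qsar_probs, mcp_pa, mcp_pi)
        external = None
        if n_ext:
            external = self._aggregate(None, ext_probs, ext_pa, ext_pi)
        return BenchmarkResults(self, outcomes, external)

    def _aggregate(self, y, qsar_probs, mcp_pa, mcp_pi) -> pd.DataFrame:
        n = len(qsar_probs)
        df = pd.DataFrame(index=pd.RangeIndex(n))
        if y is not None:
            df["label"] = np.where(y == 1, ACTIVE, INACTIVE)
        if self.run_qsar:
            df["n_test"] = [len(v) for v in qsar_probs]
            df["qsar_median_prob"] = [np.median(v) if v else np.nan for v in qsar_probs]
            df["qsar_class"] = [
                (ACTIVE if np.median(v) >= 0.5 else INACTIVE) if v else None
                for v in qsar_probs
            ]
        if self.run_mcp:
            if not self.run_qsar:
                df["n_test"] = [len(v) for v in mcp_pa]
            df["p_active_median"] = [np.median(v) if v else np.nan for v in mcp_pa]
            df["p_inactive_median"] = [np.median(v) if v else np.nan for v in mcp_pi]
            for eps in self.epsilons:
                df[set_column(eps)] = [
                    conformal.assign_prediction_set(pa, pi, eps)
                    if not (np.isnan(pa) or np.isnan(pi))
                    else None
                    for pa, pi in zip(df["p_active_median"], df["p_inactive_median"])
                ]
        return df


def set_column(epsilon: float) -> str:
    """Column name for the prediction set at a significance level,
    keyed by confidence percentage (eps 0.2 -> 'set_at_80')."""
    return f"set_at_{round((1 - epsilon) * 100):d}"


class BenchmarkResults:
    """Per-compound median outcomes of both arms, plus metric accessors."""

    def __init__(self, protocol: BenchmarkProtocol, outcomes: pd.DataFrame, external: pd.DataFrame | None = None):
        self.protocol = protocol
        self.outcomes = outcomes
        self.external = external

    @property
    def epsilons(self):
        return self.protocol.epsilons

    def qsar_metrics(self) -> dict:
        from .evaluation import qsar_metrics

        done = self.outcomes.dropna(subset=["qsar_median_prob"])
        return qsar_metrics(done["label"], done["qsar_class"])

    def mcp_metrics(self, epsilon: float, mode: str) -> dict:
        from .evaluation import mcp_metrics

        done = self.outcomes.dropna(subset=["p_active_median"])
        return mcp_metrics(done[set_column(epsilon)], done["label"], mode)

    def validity(self, epsilon: float, scope: str = "overall") -> dict:
        from .evaluation import validity

        done = self.outcomes.dropna(subset=["p_active_median"])
        return validity(done[set_column(epsilon)], done["label"], epsilon, scope)

    def set_fractions(self, epsilon: float) -> dict:
        from .evaluation import set_fractions

        done = self.outcomes.dropna(subset=["p_active_median"])
        return set_fractions(done[set_column(epsilon)])

    def summary(self) -> str:
        lines = [
            "Benchmark under repeated stratified splits",
            f"  repeats: {self.protocol.plan.n_repeats}; test fraction {self.protocol.plan.test_fraction}",
            f"  compounds: {len(self.outcomes)}",
        ]
        if self.protocol.run_qsar:
            m = self.qsar_metrics()
            lines.append(
                f"  QSAR  sens {m['sensitivity']:.3f}  spec {m['specificity']:.3f}  ccr {m['ccr']:.3f}"
            )
        if self.protocol.run_mcp:
            for eps in self.epsilons:
                mi = self.mcp_metrics(eps, "incl")
                fr = self.set_fractions(eps)
                lines.append(
                    f"  MCP @{round((1 - eps) * 100)}%  ccr_incl {mi['ccr']:.3f}  "
                    f"both {fr['fraction_both']:.3f}  empty {fr['fraction_empty']:.3f}"
                )
        return "\n".join(lines)
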