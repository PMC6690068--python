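"""Model/Results objects for the two modelling arms.

:class:`QsarForestModel` is the plain QSAR arm: a class-weighted random
forest returning P(active) per compound.  :class:`MondrianConformalModel`
wraps the same forest in a Mondrian conformal predictor: the training data
are split into a proper training set and a calibration set, the forest is
fitted on the former and its predicted class probabilities on the latter
become the per-class conformity score lists.

Both follow the model-built-from-data / ``fit()``-returns-results
convention; results objects carry the estimates and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from . import conformal
from .conformal import ACTIVE, INACTIVE, MondrianCalibration


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters (fixed study-wide, not tuned here)."""

    n_trees: int = 300
    max_depth: int = 20
    class_weighting: bool = True  # inverse class frequency, N/(2*n_class)
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be >= 1")


def balanced_class_weights(labels: np.ndarray) -> dict:
    """Per-class weights N/(k*n_class); a balanced set gets weight 1 each."""
    lab = conformal._normalize_labels(labels)
    n = lab.size
    classes, counts = np.unique(lab, return_counts=True)
    return {int(c): n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


def _build_forest(config: RFConfig) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        class_weight="balanced" if config.class_weighting else None,
        random_state=config.seed,
        n_jobs=1,
    )


def stratified_split(
    X: np.ndarray, y: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Label-stratified split; returns (train_idx, test_idx), deterministic."""
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=int(seed)
    )
    return train, test


class QsarForestModel:
    """QSAR arm: class-weighted random-forest binary activity classifier."""

    def __init__(self, X: np.ndarray, y, config: RFConfig = RFConfig()):
        self.X = np.asarray(X, dtype=float)
        self.y = conformal._normalize_labels(y)
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present to train")
        self.config = config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_cols: Sequence[str], label_col: str = "label", **kw):
        return cls(df[list(feature_cols)].to_numpy(), df[label_col].to_numpy(), **kw)

    def fit(self) -> "QsarForestResults":
        forest = _build_forest(self.config).fit(self.X, self.y)
        return QsarForestResults(self, forest)


class QsarForestResults:
    def __init__(self, model: QsarForestModel, forest: RandomForestClassifier):
        self.model = model
        self._forest = forest
        self.class_weights_ = balanced_class_weights(model.y) if model.config.class_weighting else {0: 1.0, 1: 1.0}

    def predict_proba(self, X) -> np.ndarray:
        """P(active) per compound."""
        proba = self._forest.predict_proba(np.asarray(X, dtype=float))
        active_col = list(self._forest.classes_).index(1)
        return proba[:, active_col]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Hard classes: active iff P(active) >= threshold."""
        return np.where(self.predict_proba(X) >= threshold, ACTIVE, INACTIVE)

    def summary(self) -> str:
        m = self.model
        lines = [
            "QSAR random-forest classifier",
            f"  compounds: {len(m.y)}  (active {int(m.y.sum())}, inactive {int((1 - m.y).sum())})",
            f"  trees: {m.config.n_trees}  max depth: {m.config.max_depth}",
            f"  class weights: { {k: round(v, 4) for k, v in self.class_weights_.items()} }",
        ]
        return "\n".join(lines)


def split_proper_calibration(
    X: np.ndarray, y: np.ndarray, fraction: float = 0.30, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Split a training set into proper-training and calibration indices.

    Stratified on the label so both per-class calibration lists are
    non-empty; deterministic given the seed.
    """
    y = conformal._normalize_labels(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training set")
    idx = np.arange(len(y))
    proper, cal = train_test_split(idx, test_size=fraction, stratify=y, random_state=int(seed))
    return proper, cal


class MondrianConformalModel:
    """Mondrian conformal predictor over a class-weighted random forest.

    The training data are split 70/30 into proper-training and calibration
    sets (stratified); the forest's predicted probability for a compound's
    true class on the calibration set forms the per-class conformity score
    lists used to compute p-values for new compounds.
    """

    def __init__(
        self,
        X: np.ndarray,
        y,
        config: RFConfig = RFConfig(),
        calibration_fraction: float = 0.30,
        p_value_mode: str = "adjusted",
        seed: int | None = None,
    ):
        if p_value_mode not in conformal.P_VALUE_MODES:
            raise ValueError(f"unknown p-value mode {p_value_mode!r}")
        self.X = np.asarray(X, dtype=float)
        self.y = conformal._normalize_labels(y)
        self.config = config
        self.calibration_fraction = calibration_fraction
        self.p_value_mode = p_value_mode
        self.seed = config.seed if seed is None else seed

    def fit(self) -> "MondrianConformalResults":
        proper, cal = split_proper_calibration(
            self.X, self.y, self.calibration_fraction, self.seed
        )
        forest = _build_forest(self.config).fit(self.X[proper], self.y[proper])
        active_col = list(forest.classes_).index(1)
        cal_prob = forest.predict_proba(self.X[cal])[:, active_col]
        calibration = conformal.calibrate(cal_prob, self.y[cal])
        return MondrianConformalResults(self, forest, calibration, proper, cal)


class MondrianConformalResults:
    def __init__(self, model, forest, calibration: MondrianCalibration, proper_idx, cal_idx):
        self.model = model
        self._forest = forest
        self.calibration_ = calibration
        self.proper_idx_ = proper_idx
        self.cal_idx_ = cal_idx

    def predict_proba(self, X) -> np.ndarray:
        proba = self._forest.predict_proba(np.asarray(X, dtype=float))
        active_col = list(self._forest.classes_).index(1)
        return proba[:, active_col]

    def p_values(self, X) -> pd.DataFrame:
        pv = conformal.p_values(self.calibration_, self.predict_proba(X), self.model.p_value_mode)
        return pd.DataFrame(pv, columns=["p_active", "p_inactive"])

    def predict_set(self, X, epsilon: float) -> np.ndarray:
        """Prediction-set category per compound at significance epsilon."""
        pv = self.p_values(X)
        return np.array(
            [
                conformal.assign_prediction_set(pa, pi, epsilon)
                for pa, pi in zip(pv["p_active"], pv["p_inactive"])
            ],
            dtype=object,
        )

    def summary(self) -> str:
        cal = self.calibration_
        lines = [
            "Mondrian conformal predictor (random-forest underlying model)",
            f"  proper training: {len(self.proper_idx_)} compounds; calibration: {len(self.cal_idx_)}",
            f"  calibration lists: active {cal.n_active}, inactive {cal.n_inactive}",
            f"  p-value mode: {self.model.p_value_mode}",
        ]
        return "\n".join(lines)
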