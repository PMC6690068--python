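"""Mondrian (class-conditional) conformal prediction for binary classifiers.

The conformity score of a compound for a candidate class is the classifier's
predicted probability for that class.  Calibration keeps one sorted score list
per true class (the Mondrian condition), and a new compound's p-value for a
class is the fraction of that class's calibration scores below its own score.
A class enters the prediction set at significance ``epsilon`` iff its p-value
exceeds ``epsilon``; sets may therefore contain one class, both, or neither.

Two p-value conventions are provided:

``literal``
    p = #{s : s < P_new} / n — a direct count with strict ties, the form the
    counting rule is usually stated in.
``adjusted``
    p = (#{s : s <= P_new} + 1) / (n + 1) — the finite-sample-corrected
    definition whose coverage guarantee (error rate <= epsilon per class,
    under exchangeability) is exact.  Default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

ACTIVE = "active"
INACTIVE = "inactive"
CLASSES = (ACTIVE, INACTIVE)

#: prediction-set categories
SINGLE_ACTIVE = "single-active"
SINGLE_INACTIVE = "single-inactive"
BOTH = "both"
EMPTY = "empty"

P_VALUE_MODES = ("adjusted", "literal")


class CalibrationError(ValueError):
    """Raised when a per-class calibration list would be empty."""


@dataclass(frozen=True)
class MondrianCalibration:
    """Per-class sorted conformity-score lists from a calibration set.

    ``scores[c]`` holds P(c) for every calibration compound whose true class
    is ``c``, sorted ascending.
    """

    scores: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for cls in CLASSES:
            arr = np.asarray(self.scores.get(cls, ()), dtype=float)
            if arr.size == 0:
                raise CalibrationError(f"empty calibration list for class {cls!r}")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("conformity scores must lie in [0, 1]")
            clean[cls] = np.sort(arr)
        object.__setattr__(self, "scores", clean)

    @property
    def n_active(self) -> int:
        return len(self.scores[ACTIVE])

    @property
    def n_inactive(self) -> int:
        return len(self.scores[INACTIVE])


def calibrate(prob_active: np.ndarray, labels: np.ndarray) -> MondrianCalibration:
    """Build per-class calibration lists from calibration-set predictions.

    Parameters
    ----------
    prob_active : P(active) from the underlying model for each calibration
        compound.
    labels : true class of each calibration compound, ``"active"`` /
        ``"inactive"`` (or 1/0).
    """
    prob_active = np.asarray(prob_active, dtype=float)
    lab = _normalize_labels(labels)
    return MondrianCalibration(
        {
            ACTIVE: prob_active[lab == 1],
            INACTIVE: 1.0 - prob_active[lab == 0],
        }
    )


def p_value(sorted_scores: np.ndarray, score: float, mode: str = "adjusted") -> float:
    """Conformal p-value of ``score`` against one class's calibration list."""
    scores = np.asarray(sorted_scores, dtype=float)
    if scores.size == 0:
        raise CalibrationError("empty calibration list")
    if mode == "literal":
        return float(np.searchsorted(scores, score, side="left")) / scores.size
    if mode == "adjusted":
        return (np.searchsorted(scores, score, side="right") + 1.0) / (scores.size + 1.0)
    raise ValueError(f"unknown p-value mode {mode!r}; expected one of {P_VALUE_MODES}")


def p_values(
    calibration: MondrianCalibration, prob_active: np.ndarray, mode: str = "adjusted"
) -> np.ndarray:
    """Vectorised (p_active, p_inactive) pairs for new compounds.

    Returns an ``(n, 2)`` array with column 0 = p_active, column 1 = p_inactive.
    """
    prob_active = np.atleast_1d(np.asarray(prob_active, dtype=float))
    out = np.empty((prob_active.size, 2))
    for j, (cls, score) in enumerate(
        ((ACTIVE, prob_active), (INACTIVE, 1.0 - prob_active))
    ):
        cal = calibration.scores[cls]
        if mode == "literal":
            out[:, j] = np.searchsorted(cal, score, side="left") / cal.size
        elif mode == "adjusted":
            out[:, j] = (np.searchsorted(cal, score, side="right") + 1.0) / (cal.size + 1.0)
        else:
            raise ValueError(f"unknown p-value mode {mode!r}")
    return out


def assign_prediction_set(p_active: float, p_inactive: float, epsilon: float) -> str:
    """Prediction-set category at significance ``epsilon`` (confidence 1-eps).

    A class is a member iff its p-value is strictly greater than ``epsilon``.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    a = p_active > epsilon
    i = p_inactive > epsilon
    if a and i:
        return BOTH
    if a:
        return SINGLE_ACTIVE
    if i:
        return SINGLE_INACTIVE
    return EMPTY


def set_members(category: str) -> frozenset:
    """The label set a category stands for."""
    return {
        SINGLE_ACTIVE: frozenset({ACTIVE}),
        SINGLE_INACTIVE: frozenset({INACTIVE}),
        BOTH: frozenset(CLASSES),
        EMPTY: frozenset(),
    }[category]


def assign_prediction_sets(
    pvals: np.ndarray, epsilons: Iterable[float]
) -> dict[float, np.ndarray]:
    """Categories per compound for every significance level in ``epsilons``."""
    pvals = np.asarray(pvals, dtype=float)
    out = {}
    for eps in epsilons:
        out[float(eps)] = np.array(
            [assign_prediction_set(pa, pi, eps) for pa, pi in pvals], dtype=object
        )
    return out


def _normalize_labels(labels) -> np.ndarray:
    """Map labels to 1 (active) / 0 (inactive)."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "biu":
        return arr.astype(int)
    out = np.empty(arr.shape, dtype=int)
    for i, v in enumerate(arr.ravel()):
        s = str(v).strip().lower()
        if s in (ACTIVE, "1", "true"):
            out.flat[i] = 1
        elif s in (INACTIVE, "0", "false"):
            out.flat[i] = 0
        else:
            raise ValueError(f"unrecognised class label {v!r}")
    return out
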