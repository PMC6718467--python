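"""Ventral-striatum reward measures from gain-anticipation contrasts.

Reward sensitivity is the slope of VS contrast values regressed on reward
rank (1 = 20 yen, 2 = 100 yen, 3 = 500 yen): V = b0 + b1 * rank.  A larger
slope b1 means stronger scaling of anticipatory VS activation with the size
of the potential gain.  Rank rather than yen amount is the regressor because
the rank relationship is closer to linear.  The two companion measures are
the maximal (500 vs. 0) and average (mean-gain vs. 0) contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task_glm import ContrastSet

__all__ = ["VsMeasures", "fit_rank_slope", "vs_measures", "MEASURE_NAMES"]

MEASURE_NAMES = ("sensitivity", "maximal", "average")

_RANKS = np.array([1.0, 2.0, 3.0])


@dataclass
class VsMeasures:
    """The three prediction targets (plus the slope-model intercept)."""

    sensitivity: np.ndarray | float
    maximal: np.ndarray | float
    average: np.ndarray | float
    intercept: np.ndarray | float

    def as_dict(self) -> dict[str, np.ndarray | float]:
        return {
            "sensitivity": self.sensitivity,
            "maximal": self.maximal,
            "average": self.average,
        }


def fit_rank_slope(values, use_yen: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """OLS line of contrast value on reward rank; returns ``(b0, b1)``.

    ``values`` holds the small/medium/maximal contrasts in rank order
    (ranks 1, 2, 3); vector-valued entries are fitted elementwise.  With
    ``use_yen`` the regressor is the yen amount (20, 100, 500) instead of the
    rank — offered for sensitivity analyses only.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != 3:
        raise ValueError("exactly the three ranks 1,2,3 must be present")
    x = np.array([20.0, 100.0, 500.0]) if use_yen else _RANKS
    xc = x - x.mean()
    b1 = np.tensordot(xc, values, axes=(0, 0)) / (xc @ xc)
    b0 = values.mean(axis=0) - b1 * x.mean()
    return b0, b1


def vs_measures(cs: ContrastSet) -> VsMeasures:
    """The three VS targets from a contrast set.

    sensitivity = rank-slope b1 over (small, medium, maximal); maximal and
    average are the corresponding contrast values themselves.
    """
    b0, b1 = fit_rank_slope(np.stack([
        np.asarray(cs.small, dtype=float),
        np.asarray(cs.medium, dtype=float),
        np.asarray(cs.maximal, dtype=float),
    ]))
    return VsMeasures(
        sensitivity=b1,
        maximal=np.asarray(cs.maximal, dtype=float),
        average=np.asarray(cs.average, dtype=float),
        intercept=b0,
    )
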