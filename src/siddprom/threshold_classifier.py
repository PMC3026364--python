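"""The sumG threshold classifier and its precision-recall sweep.

sumG is the sum of the 250 destabilization free energies of a window.
Promoters sit in low-energy regions, so a window is tagged *promoter* when
sumG ≤ T (boundary inclusive) for a chosen threshold T (kcal/mol).  Sweeping
T over every distinct observed sumG value traces every achievable operating
point of the rule, yielding the method's precision-recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ConfusionCounts, PRCurve, PRPoint
from .sidd_io import NON_PROMOTER, PROMOTER, WINDOW_LENGTH, WindowInstance


@dataclass(frozen=True)
class ThresholdModel:
    """The decision threshold T, in kcal/mol of summed window energy."""

    threshold: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def compute_sumG(window: WindowInstance) -> float:
    """Sum of the 250 window energies — no weighting, no normalization."""
    if window.energies.size != WINDOW_LENGTH:
        raise ValueError(
            f"sumG requires a {WINDOW_LENGTH}-bp window, "
            f"got {window.energies.size} energies"
        )
    return float(np.sum(window.energies))


def classify_threshold(model: ThresholdModel, window: WindowInstance) -> str:
    """``promoter`` iff sumG(window) ≤ T."""
    return PROMOTER if compute_sumG(window) <= model.threshold else NON_PROMOTER


def sweep_thresholds(test_set) -> PRCurve:
    """Precision-recall curve of the threshold rule over a labeled set.

    Candidate thresholds are the distinct sumG values observed in the set
    (each taken as T) plus one sentinel below the minimum, which predicts
    nothing positive and carries an undefined-precision flag.  Points are
    returned sorted by recall; since raising T can only grow the predicted
    positive set, recall is non-decreasing in T (asserted).
    """
    instances = test_set.instances
    if not instances:
        raise ValueError("empty test set")
    sums = np.array([compute_sumG(w) for w in instances])
    truth = np.array([w.label == PROMOTER for w in instances])
    if not truth.any():
        raise ValueError("test set contains no positive instance")
    thresholds = np.unique(sums)
    sentinel = thresholds[0] - 1.0
    points = []
    prev_recall = -1.0
    for t in np.concatenate([[sentinel], thresholds]):
        predicted = sums <= t
        tp = int(np.sum(predicted & truth))
        fp = int(np.sum(predicted & ~truth))
        fn = int(np.sum(~predicted & truth))
        tn = int(np.sum(~predicted & ~truth))
        point = PRPoint.from_counts(
            ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn), f"T={t:.6g}"
        )
        assert point.recall >= prev_recall, "recall must be monotone in T"
        prev_recall = point.recall
        points.append(point)
    return PRCurve(points, label="sumG")
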