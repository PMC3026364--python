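"""Confusion counting, precision/recall/F-score and precision-recall curves.

The positive class is ``promoter`` throughout.  Precision = TP/(TP+FP) and
recall = TP/(TP+FN); when a denominator is zero the quantity is *undefined*
and represented as ``None`` — never silently substituted by 0 or 1, since
either substitution biases a precision-recall curve.  F-scores are the
harmonic mean 2PR/(P+R), scale-equivariant (percent inputs give a percent
result); curve points carry F on the conventional 0–100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sidd_io import NON_PROMOTER, PROMOTER

_VALID_LABELS = (PROMOTER, NON_PROMOTER)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predictions, truth) -> ConfusionCounts:
    """Tally a confusion matrix from parallel label sequences."""
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions, "
            f"{len(truth)} truth labels"
        )
    tp = fp = tn = fn = 0
    for pred, actual in zip(predictions, truth):
        if pred not in _VALID_LABELS or actual not in _VALID_LABELS:
            raise ValueError(f"unknown label in ({pred!r}, {actual!r})")
        if actual == PROMOTER:
            if pred == PROMOTER:
                tp += 1
            else:
                fn += 1
        elif pred == PROMOTER:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def precision_recall(counts: ConfusionCounts):
    """(precision, recall); ``None`` marks an undefined quantity."""
    precision = (
        counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    )
    recall = (
        counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    )
    return precision, recall


def fscore(precision, recall):
    """Harmonic mean 2PR/(P+R) on the scale of its inputs.

    Inputs must share a scale ([0,1] fractions or [0,100] percents); percent
    inputs yield a percent result (e.g. ``fscore(59, 66) == 62.3`` to one
    decimal).  Returns ``None`` (undefined) when either input is undefined
    or both are zero.
    """
    if precision is None or recall is None:
        return None
    if precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class PRPoint:
    """One operating point of a classifier.

    ``fscore`` is on the 0–100 scale; ``precision`` and ``fscore`` are
    ``None`` when undefined (no predicted positives).
    """

    operating_parameter: str
    counts: ConfusionCounts
    precision: float | None
    recall: float
    fscore: float | None

    @classmethod
    def from_counts(cls, counts: ConfusionCounts, operating_parameter: str):
        precision, recall = precision_recall(counts)
        if recall is None:
            raise ValueError("PR point requires at least one actual positive")
        f = fscore(precision, recall)
        return cls(
            operating_parameter=operating_parameter,
            counts=counts,
            precision=precision,
            recall=recall,
            fscore=None if f is None else 100.0 * f,
        )

    @property
    def precision_defined(self) -> bool:
        return self.precision is not None


@dataclass
class PRCurve:
    """Precision-recall points sorted by recall ascending."""

    points: list[PRPoint]
    label: str = ""

    def __post_init__(self) -> None:
        self.points = sorted(
            self.points, key=lambda p: (p.recall, p.precision or 0.0)
        )

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(
                "operating_parameter\ttp\tfp\ttn\tfn\tprecision\trecall\tfscore\n"
            )
            for p in self.points:
                prec = "NA" if p.precision is None else f"{p.precision:.6f}"
                fsc = "NA" if p.fscore is None else f"{p.fscore:.3f}"
                c = p.counts
                handle.write(
                    f"{p.operating_parameter}\t{c.tp}\t{c.fp}\t{c.tn}\t{c.fn}"
                    f"\t{prec}\t{p.recall:.6f}\t{fsc}\n"
                )


def max_fscore(curve: PRCurve) -> PRPoint:
    """The curve point with greatest F-score.

    Ties break toward higher recall, then higher precision.  Points with
    undefined F (flagged, zero predicted positives) never win.
    """
    defined = [p for p in curve.points if p.fscore is not None]
    if not defined:
        raise ValueError("curve has no point with a defined F-score")
    return max(defined, key=lambda p: (p.fscore, p.recall, p.precision))
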