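"""Classification and selection-comparison statistics.

Precision, recall and the F1 score summarize a binary single-hit classifier
under heavy class imbalance; intersection-over-union (IoU, reported as a
percentage ``alpha``) compares the id sets produced by different selection
strategies, pairwise or over several selections at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InvalidParameterError

__all__ = [
    "ConfusionCounts",
    "ComparisonResult",
    "confusion_counts",
    "precision_recall_f1",
    "f1_from_precision_recall",
    "iou",
    "iou_sets",
    "comparison_matrix",
    "comparison_table",
    "multiway_intersection",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts of a binary prediction."""

    TP: int
    FP: int
    FN: int
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise InvalidParameterError("confusion counts must be non-negative")


@dataclass(frozen=True)
class ComparisonResult:
    """One cell of a selection-comparison matrix."""

    pair: tuple[str, str]
    intersection_count: int
    alpha: float  # IoU percentage, full precision

    @property
    def alpha_rounded(self) -> int:
        """Nearest-integer percentage as displayed in comparison tables."""
        return int(round(self.alpha))


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(y_true & y_pred)),
        FP=int(np.sum(~y_true & y_pred)),
        FN=int(np.sum(y_true & ~y_pred)),
        TN=int(np.sum(~y_true & ~y_pred)),
    )


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

    Degenerate denominators follow the zero convention: a metric whose
    denominator vanishes is 0, and F1 = 0 whenever P + R = 0.
    """
    p = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    r = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    f1 = 2.0 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean ``2PR/(P+R)``; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def iou(size_a: int, size_b: int, intersection: int) -> float:
    """IoU percentage from set sizes: ``100 * |A∩B| / (|A| + |B| - |A∩B|)``."""
    if intersection > min(size_a, size_b):
        raise InvalidParameterError("intersection cannot exceed the smaller set")
    union = size_a + size_b - intersection
    if union == 0:
        raise DataError("IoU undefined: both sets are empty")
    return 100.0 * intersection / union


def iou_sets(a: Iterable, b: Iterable) -> tuple[int, float]:
    """Id-set overload; returns (intersection count, alpha percentage)."""
    sa, sb = set(a), set(b)
    inter = len(sa & sb)
    return inter, iou(len(sa), len(sb), inter)


def comparison_matrix(selections: Sequence) -> list[list[ComparisonResult]]:
    """All-pairs IoU comparison; symmetric with a 100% diagonal.

    ``selections`` are objects with ``name`` and ``ids`` attributes (see
    :class:`singlehit.infer.Selection`).
    """
    if len(selections) < 2:
        raise DataError("need at least two selections to compare")
    names = [s.name for s in selections]
    if len(set(names)) != len(names):
        raise InvalidParameterError(f"duplicate selection names: {names}")
    sets = [set(s.ids) for s in selections]
    matrix = []
    for i, (ni, si) in enumerate(zip(names, sets)):
        row = []
        for j, (nj, sj) in enumerate(zip(names, sets)):
            inter = len(si & sj)
            row.append(ComparisonResult(
                pair=(ni, nj), intersection_count=inter,
                alpha=iou(len(si), len(sj), inter),
            ))
        matrix.append(row)
    return matrix


def comparison_table(selections: Sequence) -> pd.DataFrame:
    """Matrix as a DataFrame: one counts row + one percentage row per selection."""
    matrix = comparison_matrix(selections)
    names = [f"{s.name} ({len(set(s.ids))})" for s in selections]
    rows = {}
    for name, row in zip(names, matrix):
        rows[(name, "count")] = [c.intersection_count for c in row]
        rows[(name, "alpha_pct")] = [c.alpha_rounded for c in row]
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


def multiway_intersection(selections: Sequence) -> tuple[int, float]:
    """IoU over >= 2 selections: ``100 * |∩ all| / |∪ all|`` plus the count."""
    if len(selections) < 2:
        raise DataError("need at least two selections")
    sets = [set(s.ids) for s in selections]
    inter = set.intersection(*sets)
    union = set.union(*sets)
    if not union:
        raise DataError("IoU undefined: all sets are empty")
    return len(inter), 100.0 * len(inter) / len(union)
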