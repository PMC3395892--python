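"""Performance measures for the structural-change classifier.

Positive class is "change" throughout.  A probability strictly above the
threshold predicts change; exactly at the threshold predicts neutral.
Class metrics follow the accuracy/coverage convention: accuracy of a class
is the fraction of its predictions that are correct, coverage the fraction
of its instances that are retrieved.  Undefined ratios (zero denominator)
are reported as None.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "BoxStats",
    "confusion",
    "class_metrics",
    "roc_auc",
    "evaluate",
    "accuracy_coverage_curve",
    "enrichment_curve",
    "ddg_label",
    "box_stats",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    threshold: float
    counts: ConfusionCounts
    tpr: Optional[float]
    fpr: Optional[float]
    q2: float
    acc_change: Optional[float]
    acc_neutral: Optional[float]
    cov_change: Optional[float]
    cov_neutral: Optional[float]
    roc: list[tuple[float, float]]
    auc: float


@dataclass(frozen=True)
class BoxStats:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float


def _validate(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape or probs.ndim != 1:
        raise ValueError("probs and labels must be equal-length 1-D arrays")
    if len(probs) == 0:
        raise ValueError("empty input")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary (1 = change)")
    return probs, labels


def confusion(
    probs: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts at a probability threshold (predict change iff > t)."""
    probs, labels = _validate(probs, labels)
    pred = probs > threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def class_metrics(counts: ConfusionCounts) -> dict[str, Optional[float]]:
    """Q2 plus per-class accuracy and coverage (None when undefined)."""
    return {
        "q2": _ratio(counts.tp + counts.tn, counts.total),
        "acc_change": _ratio(counts.tp, counts.tp + counts.fp),
        "cov_change": _ratio(counts.tp, counts.tp + counts.fn),
        "acc_neutral": _ratio(counts.tn, counts.tn + counts.fn),
        "cov_neutral": _ratio(counts.tn, counts.tn + counts.fp),
    }


def roc_auc(
    probs: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoid AUC, sweeping all distinct scores.

    Tied scores are grouped into one step, which makes the trapezoid area
    equal to the Mann-Whitney statistic with ties counted as one half.
    """
    probs, labels = _validate(probs, labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")

    order = np.argsort(-probs, kind="stable")
    sorted_probs = probs[order]
    sorted_labels = labels[order]
    # indices where a new distinct score ends
    distinct = np.nonzero(np.diff(sorted_probs))[0]
    cuts = np.concatenate([distinct, [len(probs) - 1]])
    tps = np.cumsum(sorted_labels == 1)[cuts]
    fps = np.cumsum(sorted_labels == 0)[cuts]

    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate(
    probs: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> EvalReport:
    """Full report: confusion at the threshold plus ROC/AUC."""
    counts = confusion(probs, labels, threshold)
    metrics = class_metrics(counts)
    roc, auc = roc_auc(probs, labels)
    return EvalReport(
        threshold=threshold,
        counts=counts,
        tpr=_ratio(counts.tp, counts.tp + counts.fn),
        fpr=_ratio(counts.fp, counts.fp + counts.tn),
        q2=metrics["q2"],
        acc_change=metrics["acc_change"],
        acc_neutral=metrics["acc_neutral"],
        cov_change=metrics["cov_change"],
        cov_neutral=metrics["cov_neutral"],
        roc=roc,
        auc=auc,
    )


def accuracy_coverage_curve(
    probs: Sequence[float],
    labels: Sequence[int],
    thresholds: Iterable[float],
) -> dict[str, list[tuple[float, Optional[float]]]]:
    """Per-class (coverage, accuracy) pairs over a threshold grid.

    Returns lists for "change" and "neutral", each sorted by coverage.
    """
    curves = {"change": [], "neutral": []}
    for t in thresholds:
        m = class_metrics(confusion(probs, labels, t))
        curves["change"].append((m["cov_change"], m["acc_change"]))
        curves["neutral"].append((m["cov_neutral"], m["acc_neutral"]))
    for cls in curves:
        curves[cls].sort(key=lambda pair: (pair[0] is None, pair[0]))
    return curves


def enrichment_curve(
    probs: Sequence[float],
    effect_labels: Sequence[int],
    thresholds: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
) -> list[tuple[float, Optional[float]]]:
    """Fraction of observed-effect mutants among predicted-change mutants.

    For each threshold t the numerator counts instances with prob > t and
    an external effect label, the denominator all instances with prob > t;
    None when nothing is predicted as change.
    """
    probs, effect_labels = _validate(probs, effect_labels)
    out = []
    for t in thresholds:
        predicted = probs > t
        denom = int(np.sum(predicted))
        frac = float(np.sum(predicted & (effect_labels == 1)) / denom) if denom else None
        out.append((float(t), frac))
    return out


def ddg_label(ddg: float) -> str:
    """Stability label from a folding free-energy change (kcal/mol).

    "effect" iff ddg < -1 or ddg > 1 (both stabilizing and destabilizing
    count); strict inequalities, so exactly +/-1 is neutral.
    """
    if not np.isfinite(ddg):
        raise ValueError(f"invalid ddG {ddg}")
    return "effect" if (ddg < -1.0 or ddg > 1.0) else "neutral"


def box_stats(values: Sequence[float]) -> BoxStats:
    """Quartiles (linear interpolation) and 1.5-IQR whiskers."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("box_stats requires at least one value")
    q1, median, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    in_low = values[values >= q1 - 1.5 * iqr]
    in_high = values[values <= q3 + 1.5 * iqr]
    return BoxStats(
        q1=float(q1),
        median=float(median),
        q3=float(q3),
        whisker_low=float(in_low.min()),
        whisker_high=float(in_high.max()),
    )
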