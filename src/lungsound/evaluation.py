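"""Confusion accounting, Se/Sp/ICBHI scoring, ROC/AUC, and k-fold CV.

The binary task is COPD (positive) vs non-COPD.  The headline metric is the
ICBHI score, the respiratory-sound challenge convention: the arithmetic mean
of sensitivity (true-positive rate) and specificity (true-negative rate).
Cross-validation uses stratified folds; pooled metrics are computed on the
summed test-fold confusion counts (micro-average), with per-fold metrics also
reported.  Augmentation, when enabled by the fold runner, is applied to each
fold's training portion only, never to held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .audio_io import AudioClip, Label


class UndefinedMetricError(ValueError):
    """A rate whose denominator class is empty (never silently 0)."""


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: Label = Label.COPD

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if other.positive_class != self.positive_class:
            raise ValueError("cannot add counts with different positive classes")
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.positive_class,
        )


@dataclass
class EvalMetrics:
    sensitivity: float
    specificity: float
    icbhi_score: float
    accuracy: float
    auc: float | None = None


def confusion(
    labels: Sequence, predictions: Sequence, positive_class=Label.COPD
) -> ConfusionCounts:
    """Standard binary confusion counts relative to ``positive_class``."""
    if len(labels) != len(predictions):
        raise ValueError(f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions")
    if len(labels) == 0:
        raise ValueError("cannot compute a confusion matrix on empty input")
    y = np.asarray([l == positive_class for l in labels])
    p = np.asarray([q == positive_class for q in predictions])
    pc = positive_class if isinstance(positive_class, Label) else Label.COPD
    return ConfusionCounts(
        tp=int(np.sum(y & p)),
        fp=int(np.sum(~y & p)),
        tn=int(np.sum(~y & ~p)),
        fn=int(np.sum(y & ~p)),
        positive_class=pc,
    )


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate TP/(TP+FN)."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate TN/(TN+FP)."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    return c.tn / (c.tn + c.fp)


def icbhi_score(se: float, sp: float) -> float:
    """ICBHI challenge score: the arithmetic mean of Se and Sp."""
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise ValueError(f"Se and Sp must lie in [0, 1], got ({se}, {sp})")
    return (se + sp) / 2.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero on the shortest decimal form of ``x``.

    Report tables print to 2 decimals with ties going up, so 0.595 -> 0.60 and
    0.525 -> 0.53 even though neither is exactly representable in binary.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def metrics_from_counts(c: ConfusionCounts, auc_value: float | None = None) -> EvalMetrics:
    se, sp = sensitivity(c), specificity(c)
    return EvalMetrics(
        sensitivity=se,
        specificity=sp,
        icbhi_score=icbhi_score(se, sp),
        accuracy=(c.tp + c.tn) / c.total,
        auc=auc_value,
    )


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """ROC points (FPR, TPR), monotone from (0, 0) to (1, 1).

    ``labels`` are 1 for the positive class; ``scores`` are the positive-class
    scores.  Both classes must be present.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def auc(curve: np.ndarray) -> float:
    """Area under an ROC polyline by the trapezoidal rule."""
    curve = np.asarray(curve, dtype=float)
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def auc_from_scores(scores: Sequence[float], labels: Sequence[int]) -> float:
    return auc(roc_curve(scores, labels))


#: A fold runner maps (train_clips, test_clips, fold_seed) to
#: (y_true, y_pred, y_score) for the held-out clips, with 1 = positive class.
FoldRunner = Callable[[list[AudioClip], list[AudioClip], int], tuple]


def kfold_cv(
    clips: Sequence[AudioClip],
    run_fold: FoldRunner,
    k: int = 10,
    seed: int = 0,
) -> tuple[list[EvalMetrics], EvalMetrics]:
    """Stratified k-fold cross-validation over labeled clips.

    Folds are stratified on the binary label with near-equal sizes; each clip
    is held out exactly once.  ``run_fold`` trains on the fold's training
    clips (applying any augmentation there only) and scores the held-out
    clips.  Returns per-fold metrics and pooled (micro-averaged) metrics over
    the summed test-fold confusion counts.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    clips = list(clips)
    y = np.array([1 if c.label == Label.COPD else 0 for c in clips])
    for cls, count in zip(*np.unique(y, return_counts=True)):
        if count < k:
            raise ValueError(f"class {cls} has {count} < k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[EvalMetrics] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    all_scores: list[float] = []
    all_true: list[int] = []
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_clips = [clips[i] for i in train_idx]
        test_clips = [clips[i] for i in test_idx]
        y_true, y_pred, y_score = run_fold(train_clips, test_clips, seed + 1000 * (fold_i + 1))
        c = confusion(list(y_true), list(y_pred), positive_class=1)
        fold_auc = None
        if len(np.unique(y_true)) == 2:
            fold_auc = auc_from_scores(y_score, y_true)
        per_fold.append(metrics_from_counts(c, fold_auc))
        pooled = pooled + c
        all_scores.extend(np.asarray(y_score, dtype=float).tolist())
        all_true.extend(np.asarray(y_true, dtype=int).tolist())
    pooled_auc = auc_from_scores(all_scores, all_true)
    return per_fold, metrics_from_counts(pooled, pooled_auc)
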