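"""Evaluation metrics for disc/cup segmentation and CDR-based screening.

Per structure (disc = rim + cup, cup = cup class alone) the pixel
confusion counts feed the Dice coefficient DC = 2TP/(2TP+FP+FN), the
Jaccard index JAC = TP/(TP+FP+FN) and the balanced accuracy
BA = (Se+Sp)/2 with Se = TP/(TP+FN), Sp = TN/(TN+FP).

The cup-to-disc ratio is the ratio of vertical extents,
CDR = VD_cup / VD_disc, and the CDR error over a test set is the mean
absolute difference between predicted and reference ratios.  Screening
calls an eye glaucomatous when CDR exceeds 0.5; sweeping that threshold
gives the ROC curve and its trapezoidal AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import ShapeError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if pred.shape != ref.shape:
        raise ShapeError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    tn = int(np.count_nonzero(~pred & ~ref))
    return ConfusionCounts(tp, fp, fn, tn)


def _degenerate(value_if_both_empty: float, other_side_empty: bool) -> float:
    if other_side_empty:
        return value_if_both_empty
    return 0.0


def dice_coefficient(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("dice of two empty masks defined as 1", stacklevel=2)
        return 1.0
    return 2 * c.tp / denom


def jaccard(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("jaccard of two empty masks defined as 1", stacklevel=2)
        return 1.0
    return c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        warnings.warn("sensitivity with empty reference", stacklevel=2)
        return 1.0 if c.fp == 0 else 0.0
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        warnings.warn("specificity with all-positive reference", stacklevel=2)
        return 1.0 if c.fn == 0 else 0.0
    return c.tn / (c.tn + c.fp)


def balanced_accuracy(c: ConfusionCounts) -> float:
    return 0.5 * (sensitivity(c) + specificity(c))


def vertical_diameter(mask: np.ndarray) -> int:
    """Inclusive vertical extent (in rows) of the occupied region."""
    mask = np.asarray(mask).astype(bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise ShapeError("vertical diameter of an empty mask is undefined")
    return int(rows[-1] - rows[0] + 1)


@dataclass(frozen=True)
class CDRValue:
    value: float
    vd_cup: int
    vd_disc: int


@dataclass(frozen=True)
class CDRRecord:
    """Predicted and reference cup-to-disc ratio for one image."""

    cdr_pred: float
    cdr_ref: float


def cdr(cup_mask: np.ndarray, disc_mask: np.ndarray) -> CDRValue:
    vd_disc = vertical_diameter(disc_mask)      # raises on empty disc
    if not np.asarray(cup_mask).any():
        warnings.warn("empty cup mask; CDR defined as 0", stacklevel=2)
        return CDRValue(0.0, 0, vd_disc)
    vd_cup = vertical_diameter(cup_mask)
    return CDRValue(vd_cup / vd_disc, vd_cup, vd_disc)


def cdr_error(records) -> float:
    """Mean absolute CDR error over a test set."""
    records = list(records)
    if not records:
        raise ValueError("cdr_error of an empty record list")
    return float(np.mean([abs(r.cdr_pred - r.cdr_ref) for r in records]))


@dataclass
class ScreeningReport:
    decisions: np.ndarray        # boolean, True = screened glaucomatous
    threshold: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def screen(records, labels, threshold: float = 0.5) -> ScreeningReport:
    """CDR-threshold glaucoma screening with ROC/AUC over a cohort.

    ``records`` may be CDRRecord instances (their predicted ratios are
    used) or plain CDR scores.  ``labels``: 1 = glaucomatous, 0 = normal.
    """
    scores = np.asarray([r.cdr_pred if isinstance(r, CDRRecord) else float(r)
                         for r in records], dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ShapeError("records and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    decisions = scores > threshold
    fpr, tpr, ths = _sk_roc_curve(labels, scores)
    return ScreeningReport(decisions=decisions, threshold=threshold,
                           fpr=fpr, tpr=tpr, thresholds=ths,
                           auc=float(_sk_auc(fpr, tpr)))


def structure_masks(label_mask: np.ndarray):
    """(disc, cup) binary masks from a 3-class label mask."""
    m = np.asarray(label_mask)
    return m >= 1, m == 2
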