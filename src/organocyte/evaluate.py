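"""Object-level scoring of detections against ground truth.

Detections and truth objects are matched one-to-one by greedy descending
IoU (ties broken by pred id, then truth id) above a threshold; matched
pairs are true positives, unmatched detections false positives, unmatched
truth objects false negatives.  Precision = TP/(TP+FP),
recall = TP/(TP+FN).  Area agreement is summarized by ordinary least
squares of detected on true areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError, RegressionError


@dataclass
class MatchResult:
    """One-to-one matching outcome between predicted and true objects."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    unmatched_pred: list[int] = field(default_factory=list)
    unmatched_truth: list[int] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(tp=self.tp + other.tp, fp=self.fp + other.fp,
                           fn=self.fn + other.fn)


def pairwise_iou(pred: np.ndarray, truth: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IoU matrix between positive labels of two label images.

    Returns (pred ids, truth ids, IoU matrix of shape |pred|×|truth|).
    """
    if pred.shape != truth.shape:
        raise ParameterError("pred and truth label images must share shape")
    pred_ids = np.unique(pred[pred > 0])
    truth_ids = np.unique(truth[truth > 0])
    if pred_ids.size == 0 or truth_ids.size == 0:
        return pred_ids, truth_ids, np.zeros((pred_ids.size, truth_ids.size))
    np_, nt = int(pred.max()), int(truth.max())
    joint = np.bincount(
        (pred.astype(np.int64) * (nt + 1) + truth.astype(np.int64)).ravel(),
        minlength=(np_ + 1) * (nt + 1)).reshape(np_ + 1, nt + 1)
    pred_area = joint.sum(axis=1)
    truth_area = joint.sum(axis=0)
    inter = joint[np.ix_(pred_ids, truth_ids)].astype(np.float64)
    union = (pred_area[pred_ids, None] + truth_area[None, truth_ids] - inter)
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return pred_ids, truth_ids, iou


def match_detections(pred: np.ndarray, truth: np.ndarray,
                     iou_min: float) -> MatchResult:
    """Greedy one-to-one matching by descending IoU above ``iou_min``."""
    if not 0.0 < iou_min <= 1.0:
        raise ParameterError("iou_min must lie in (0, 1]")
    pred_ids, truth_ids, iou = pairwise_iou(pred, truth)
    cand = [
        (float(iou[i, j]), int(pred_ids[i]), int(truth_ids[j]))
        for i in range(len(pred_ids)) for j in range(len(truth_ids))
        if iou[i, j] >= iou_min
    ]
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for score, p, t in cand:
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        pairs.append((p, t, score))
    unmatched_pred = [int(p) for p in pred_ids if p not in used_p]
    unmatched_truth = [int(t) for t in truth_ids if t not in used_t]
    return MatchResult(tp=len(pairs), fp=len(unmatched_pred),
                       fn=len(unmatched_truth), pairs=pairs,
                       unmatched_pred=unmatched_pred,
                       unmatched_truth=unmatched_truth)


def precision_recall(m: MatchResult) -> tuple[float, float, bool]:
    """(precision, recall, degenerate) with zero denominators yielding 0."""
    degenerate = (m.tp + m.fp == 0) or (m.tp + m.fn == 0)
    precision = m.tp / (m.tp + m.fp) if m.tp + m.fp else 0.0
    recall = m.tp / (m.tp + m.fn) if m.tp + m.fn else 0.0
    return precision, recall, degenerate


def area_regression(pairs: list[tuple[float, float]]
                    ) -> tuple[float, float, float]:
    """OLS of detected area on true area → (slope, intercept, R²)."""
    if len(pairs) < 3:
        raise RegressionError(f"need >= 3 area pairs, got {len(pairs)}")
    pred = np.asarray([p for p, _ in pairs], dtype=np.float64)
    truth = np.asarray([t for _, t in pairs], dtype=np.float64)
    if np.allclose(truth, truth[0]):
        raise RegressionError("true areas are all identical")
    fit = stats.linregress(truth, pred)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
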