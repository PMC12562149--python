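"""Segmentation metrics (Dice, IoU, precision, recall) and region matching.

The pipeline emits a multi-region partition without semantic labels, while
ground truth is usually a binary foreground mask or a small labelled
partition.  Scoring therefore needs an explicit reduction rule:

* binary truth — pick the predicted region (or, in ``union`` mode, a greedy
  union of regions) maximizing Dice against the foreground.  This emulates a
  user interactively selecting the region of interest from the structured
  output.
* multi-class truth — optimal one-to-one label assignment maximizing total
  Dice (Hungarian algorithm; class counts are small).

Degenerate 0/0 ratios follow one convention throughout: identical empty
masks score 1, any other empty-denominator case scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.transform import resize

from .errors import InvalidInputError
from .merging import SegmentationMask


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion counts for one binary comparison."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise InvalidInputError(f"{name} must be 2-D, got shape {arr.shape}")
    return arr.astype(bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Standard pixelwise TP/FP/FN/TN between two binary masks."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise InvalidInputError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, fn_plus_fp: int) -> float:
    if den == 0:
        # Empty denominator: 1 iff pred and truth are both empty.
        return 1.0 if fn_plus_fp == 0 else 0.0
    return num / den


def dice(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN)."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, c.fp + c.fn)


def iou(c: ConfusionCounts) -> float:
    """Intersection over union TP / (TP + FP + FN)."""
    return _ratio(c.tp, c.tp + c.fp + c.fn, c.fp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 1 only when prediction and truth are both empty."""
    return _ratio(c.tp, c.tp + c.fp, c.fp + c.fn)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 1 only when prediction and truth are both empty."""
    return _ratio(c.tp, c.tp + c.fn, c.fp + c.fn)


def all_metrics(c: ConfusionCounts) -> dict[str, float]:
    return {
        "dice": dice(c),
        "iou": iou(c),
        "precision": precision(c),
        "recall": recall(c),
    }


@dataclass
class RegionMatch:
    """Outcome of matching predicted regions to ground truth.

    mapping : truth class -> tuple of predicted labels assigned to it (a
        single label per class except in binary ``union`` mode).
    counts, scores : per truth class, the confusion counts of the matched
        prediction and its four metrics.
    """

    mapping: dict[int, tuple[int, ...]]
    counts: dict[int, ConfusionCounts]
    scores: dict[int, dict[str, float]]

    @property
    def mean_dice(self) -> float:
        return float(np.mean([s["dice"] for s in self.scores.values()]))

    @property
    def mean_iou(self) -> float:
        return float(np.mean([s["iou"] for s in self.scores.values()]))


def _resize_truth(truth: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize so label values survive intact."""
    if truth.shape == shape:
        return truth
    return resize(
        truth, shape, order=0, preserve_range=True, anti_aliasing=False
    ).astype(truth.dtype)


def _labels_of(mask: SegmentationMask | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(mask, SegmentationMask):
        return mask.labels, mask.n_labels
    arr = np.asarray(mask)
    return arr, int(arr.max()) + 1


def match_regions_to_truth(
    mask: SegmentationMask | np.ndarray,
    truth: np.ndarray,
    mode: str = "best",
) -> RegionMatch:
    """Match predicted regions to ground truth and score the matches.

    Binary truth (values in {0, 1}): returns one entry for class 1 scored
    against the best predicted region, or the greedy best union of regions
    when ``mode='union'``.  Multi-class truth: one-to-one assignment of
    predicted labels to truth classes maximizing total Dice; unmatched truth
    classes score against an empty prediction.
    """
    if mode not in ("best", "union"):
        raise InvalidInputError(f"unknown match mode {mode!r}")
    labels, n_labels = _labels_of(mask)
    truth = np.asarray(truth)
    if truth.ndim != 2:
        raise InvalidInputError("truth must be a 2-D label or binary mask")
    truth = _resize_truth(truth, labels.shape)

    truth_values = np.unique(truth)
    binary = truth_values.size <= 2 and set(truth_values.tolist()) <= {0, 1}
    if binary:
        return _match_binary(labels, n_labels, truth.astype(bool), mode)
    return _match_multiclass(labels, n_labels, truth.astype(np.int64))


def _match_binary(
    labels: np.ndarray, n_labels: int, fg: np.ndarray, mode: str
) -> RegionMatch:
    per_label = [confusion_counts(labels == lab, fg) for lab in range(n_labels)]
    dices = [dice(c) for c in per_label]
    best = int(np.argmax(dices))
    selected = [best]
    if mode == "union":
        current = dices[best]
        remaining = [l for l in range(n_labels) if l != best]
        improved = True
        while improved and remaining:
            improved = False
            trials = []
            for lab in remaining:
                pred = np.isin(labels, selected + [lab])
                trials.append((dice(confusion_counts(pred, fg)), lab))
            d_new, lab = max(trials)
            if d_new > current:
                selected.append(lab)
                remaining.remove(lab)
                current = d_new
                improved = True
        selected.sort()
    pred = np.isin(labels, selected)
    c = confusion_counts(pred, fg)
    return RegionMatch(
        mapping={1: tuple(selected)},
        counts={1: c},
        scores={1: all_metrics(c)},
    )


def _match_multiclass(
    labels: np.ndarray, n_labels: int, truth: np.ndarray
) -> RegionMatch:
    classes = np.unique(truth).tolist()
    dice_table = np.zeros((len(classes), n_labels))
    for ci, cls in enumerate(classes):
        t = truth == cls
        for lab in range(n_labels):
            dice_table[ci, lab] = dice(confusion_counts(labels == lab, t))
    rows, cols = linear_sum_assignment(-dice_table)
    assigned = dict(zip(rows.tolist(), cols.tolist()))

    mapping: dict[int, tuple[int, ...]] = {}
    counts: dict[int, ConfusionCounts] = {}
    scores: dict[int, dict[str, float]] = {}
    empty = np.zeros_like(labels, dtype=bool)
    for ci, cls in enumerate(classes):
        if ci in assigned:
            lab = assigned[ci]
            pred = labels == lab
            mapping[int(cls)] = (int(lab),)
        else:  # more truth classes than predicted regions
            pred = empty
            mapping[int(cls)] = ()
        c = confusion_counts(pred, truth == cls)
        counts[int(cls)] = c
        scores[int(cls)] = all_metrics(c)
    return RegionMatch(mapping=mapping, counts=counts, scores=scores)
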