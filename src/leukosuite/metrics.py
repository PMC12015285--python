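"""Evaluation indicators for leukocyte classification and segmentation.

Classification quality is summarized by per-class one-vs-rest confusion
counts and the derived accuracy / precision / recall / F1.  Segmentation
quality is summarized by set-overlap scores (Dice, Jaccard) on binary masks
and by the symmetric Hausdorff distance between mask boundaries.

Zero-denominator conventions are explicit: precision/recall/F1 return 0 with
a warning flag when undefined; Dice and Jaccard of two empty masks are
defined as 1; the Hausdorff distance of an empty mask is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .segment import extract_boundary

__all__ = [
    "ConfusionCounts",
    "confusion",
    "classification_scores",
    "overlap_scores",
    "hausdorff",
    "evaluate_masks",
]


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    labels_true: np.ndarray, labels_pred: np.ndarray, n_classes: int
) -> list[ConfusionCounts]:
    """Per-class one-vs-rest confusion counts.

    Returns a list with one :class:`ConfusionCounts` per class index; each
    class's counts sum to the number of samples.
    """
    t = np.asarray(labels_true, dtype=int)
    p = np.asarray(labels_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError("labels out of range")
    out = []
    for c in range(n_classes):
        tp = int(np.sum((t == c) & (p == c)))
        tn = int(np.sum((t != c) & (p != c)))
        fp = int(np.sum((t != c) & (p == c)))
        fn = int(np.sum((t == c) & (p != c)))
        out.append(ConfusionCounts(tp, tn, fp, fn))
    return out


@dataclass
class ClassScores:
    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = field(default=False)


def classification_scores(c: ConfusionCounts) -> ClassScores:
    """Accuracy, precision, recall and F1 from one-vs-rest counts.

    A zero denominator yields a score of 0 and sets ``degenerate`` so callers
    can distinguish "bad" from "undefined".
    """
    flag = False

    def _ratio(num: float, den: float) -> float:
        nonlocal flag
        if den == 0:
            flag = True
            return 0.0
        return num / den

    acc = _ratio(c.tp + c.tn, c.total)
    prec = _ratio(c.tp, c.tp + c.fp)
    rec = _ratio(c.tp, c.tp + c.fn)
    f1 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    return ClassScores(acc, prec, rec, f1, flag)


def macro_scores(counts: list[ConfusionCounts]) -> ClassScores:
    """Unweighted average of per-class scores."""
    per = [classification_scores(c) for c in counts]
    return ClassScores(
        float(np.mean([s.accuracy for s in per])),
        float(np.mean([s.precision for s in per])),
        float(np.mean([s.recall for s in per])),
        float(np.mean([s.f1 for s in per])),
        any(s.degenerate for s in per),
    )


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D mask")
    return mask.astype(bool)


def overlap_scores(predicted: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Dice and Jaccard overlap of two binary masks.

    Computed on the true-pixel sets: ``dice = 2|A∩B| / (|A|+|B|)`` and
    ``jaccard = |A∩B| / |A∪B|``.  Two empty masks score (1, 1) by convention.
    """
    a = _as_mask(predicted)
    b = _as_mask(truth)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    inter = int(np.sum(a & b))
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / (na + nb)
    jaccard = inter / (na + nb - inter)
    return dice, jaccard


def hausdorff(
    predicted: np.ndarray, truth: np.ndarray, pixel_spacing: float = 1.0
) -> float:
    """Symmetric Hausdorff distance between mask boundaries.

    Boundaries are the 1-pixel inner contours of each mask; the distance is
    the larger of the two directed max–min Euclidean distances, scaled by
    ``pixel_spacing`` (units per pixel).
    """
    a = _as_mask(predicted)
    b = _as_mask(truth)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance undefined for an empty mask")
    pa = np.argwhere(extract_boundary(a))
    pb = np.argwhere(extract_boundary(b))
    d = max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
    return float(d) * pixel_spacing


def evaluate_masks(
    pairs: list[tuple[np.ndarray, np.ndarray]], pixel_spacing: float = 1.0
) -> dict:
    """Per-sample and mean Dice/Jaccard/Hausdorff over mask pairs.

    Hausdorff is reported as ``None`` for pairs with an empty mask.
    """
    rows = []
    for pred, truth in pairs:
        dice, jac = overlap_scores(pred, truth)
        try:
            hd = hausdorff(pred, truth, pixel_spacing)
        except ValueError:
            hd = None
        rows.append({"dice": dice, "jaccard": jac, "hausdorff": hd})
    hds = [r["hausdorff"] for r in rows if r["hausdorff"] is not None]
    return {
        "per_sample": rows,
        "mean_dice": float(np.mean([r["dice"] for r in rows])),
        "mean_jaccard": float(np.mean([r["jaccard"] for r in rows])),
        "mean_hausdorff": float(np.mean(hds)) if hds else None,
    }
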