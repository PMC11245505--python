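"""Segmentation evaluation: per-class accuracy, IoU, Dice and macro means.

Predictions and ground truth are integer label maps over four classes —
background 0, cornea 1, pupil 2, lesion 3.  All metrics are derived from a
single confusion-count matrix, reported on the percentage scale, and macro
means are unweighted over all classes including background.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

#: Label codes of the combined label map.
CLASS_NAMES = ("background", "cornea", "pupil", "lesions")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as used in metric reports."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion_counts(pred, truth, n_classes: int) -> np.ndarray:
    """Pixel confusion matrix; entry (i, j) counts truth ``i`` predicted ``j``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.ravel().astype(np.int64)
    t = truth.ravel().astype(np.int64)
    for name, lab in (("pred", p), ("truth", t)):
        if lab.size and (lab.min() < 0 or lab.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    counts = np.bincount(t * n_classes + p, minlength=n_classes * n_classes)
    return counts.reshape(n_classes, n_classes)


def class_metrics(counts: np.ndarray, c: int) -> tuple[float, float, float]:
    """(accuracy, IoU, Dice) of class ``c``, in percent, unrounded.

    Accuracy is class-wise recall TP/(TP+FN); IoU = TP/(TP+FP+FN);
    Dice = 2TP/(2TP+FP+FN).  A class absent from both prediction and truth
    scores 100 on all three (vacuously perfect agreement).
    """
    counts = np.asarray(counts, dtype=np.int64)
    tp = counts[c, c]
    fn = counts[c, :].sum() - tp
    fp = counts[:, c].sum() - tp
    if tp + fp + fn == 0:
        return 100.0, 100.0, 100.0
    acc = 100.0 * tp / (tp + fn) if tp + fn else 100.0
    iou = 100.0 * tp / (tp + fp + fn)
    dice = 100.0 * 2 * tp / (2 * tp + fp + fn)
    return float(acc), float(iou), float(dice)


def dice_from_iou(iou: float) -> float:
    """Convert an IoU percentage to the equivalent Dice percentage.

    Uses the Jaccard-Dice identity Dice = 2J/(1+J), i.e. 200*J/(100+J) on
    the percentage scale.
    """
    return 200.0 * iou / (100.0 + iou)


def macro_mean(values: Sequence[float]) -> float:
    """Unweighted mean of per-class metric values."""
    return float(np.mean(np.asarray(values, dtype=float)))


@dataclass(frozen=True)
class SegReport:
    """Per-class and macro segmentation metrics, percentages, full precision."""

    class_names: tuple[str, ...]
    accuracy: tuple[float, ...]
    iou: tuple[float, ...]
    dice: tuple[float, ...]
    global_accuracy: float
    mean_iou: float
    mean_dice: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Flat report dict with half-up rounding, using Table-style row names."""
        out = {
            "global_acc": round_half_up(self.global_accuracy, ndigits),
            "mIoU": round_half_up(self.mean_iou, ndigits),
            "mDice": round_half_up(self.mean_dice, ndigits),
        }
        for i, name in enumerate(self.class_names):
            out[f"acc_{name}"] = round_half_up(self.accuracy[i], ndigits)
            out[f"iou_{name}"] = round_half_up(self.iou[i], ndigits)
            out[f"dice_{name}"] = round_half_up(self.dice[i], ndigits)
        return out


def report_from_counts(counts: np.ndarray, class_names: Sequence[str] = CLASS_NAMES) -> SegReport:
    counts = np.asarray(counts, dtype=np.int64)
    n = len(class_names)
    if counts.shape != (n, n):
        raise ValueError(f"counts must be {n}x{n} for {n} classes")
    per = [class_metrics(counts, c) for c in range(n)]
    acc, iou, dice = (tuple(p[k] for p in per) for k in range(3))
    total = counts.sum()
    glob = 100.0 * np.trace(counts) / total if total else 100.0
    return SegReport(
        class_names=tuple(class_names),
        accuracy=acc,
        iou=iou,
        dice=dice,
        global_accuracy=float(glob),
        mean_iou=macro_mean(iou),
        mean_dice=macro_mean(dice),
    )


def seg_report(pred, truth, class_names: Sequence[str] = CLASS_NAMES) -> SegReport:
    """Score one predicted label map against its ground truth."""
    return report_from_counts(confusion_counts(pred, truth, len(class_names)), class_names)


def seg_report_dataset(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]],
    class_names: Sequence[str] = CLASS_NAMES,
    mode: str = "pooled",
) -> SegReport:
    """Score a set of (pred, truth) label-map pairs.

    ``mode="pooled"`` (default) accumulates one confusion matrix over all
    pixels of all images; ``mode="per_image"`` scores each image separately
    and averages the resulting metric values across images.
    """
    if mode not in ("pooled", "per_image"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(class_names)
    if mode == "pooled":
        total = np.zeros((n, n), dtype=np.int64)
        seen = False
        for pred, truth in pairs:
            total += confusion_counts(pred, truth, n)
            seen = True
        if not seen:
            raise ValueError("no image pairs to score")
        return report_from_counts(total, class_names)
    reports = [seg_report(p, t, class_names) for p, t in pairs]
    if not reports:
        raise ValueError("no image pairs to score")
    mean = lambda xs: float(np.mean(xs))  # noqa: E731
    return SegReport(
        class_names=tuple(class_names),
        accuracy=tuple(mean([r.accuracy[c] for r in reports]) for c in range(n)),
        iou=tuple(mean([r.iou[c] for r in reports]) for c in range(n)),
        dice=tuple(mean([r.dice[c] for r in reports]) for c in range(n)),
        global_accuracy=mean([r.global_accuracy for r in reports]),
        mean_iou=mean([r.mean_iou for r in reports]),
        mean_dice=mean([r.mean_dice for r in reports]),
    )
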