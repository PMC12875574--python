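"""Segmentation evaluation: per-class Dice and Jaccard (IoU) overlap.

For a prediction P and ground truth G (pixel sets of one class),

    DSC = 2|P n G| / (|P| + |G|)        IoU = |P n G| / |P u G|

and the two are linked by DSC = 2 IoU / (1 + IoU).  When both sets are
empty the class is in perfect (vacuous) agreement and both metrics default
to 1.0; ``empty_value=float('nan')`` switches to NaN-and-exclude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import SegmentationMask, VALID_LABELS

__all__ = ["SegMetrics", "dice", "iou", "evaluate", "evaluate_batch", "pooled_evaluate"]

#: foreground classes reported by default (background excluded from mIoU)
DEFAULT_CLASSES = (1, 2)


@dataclass
class SegMetrics:
    dice_per_class: dict[int, float]
    iou_per_class: dict[int, float]
    mean_iou: float
    dice_overall: float


def _counts(P: np.ndarray, G: np.ndarray) -> tuple[int, int, int]:
    P = np.asarray(P, dtype=bool)
    G = np.asarray(G, dtype=bool)
    if P.shape != G.shape:
        raise ValidationError(f"mask shapes differ: {P.shape} vs {G.shape}")
    inter = int(np.count_nonzero(P & G))
    return inter, int(np.count_nonzero(P)), int(np.count_nonzero(G))


def dice(P: np.ndarray, G: np.ndarray, empty_value: float = 1.0) -> float:
    """Dice score coefficient 2|PnG|/(|P|+|G|); both-empty gives ``empty_value``."""
    inter, np_, ng = _counts(P, G)
    if np_ + ng == 0:
        return empty_value
    return 2.0 * inter / (np_ + ng)


def iou(P: np.ndarray, G: np.ndarray, empty_value: float = 1.0) -> float:
    """Jaccard index |PnG|/|PuG|; both-empty gives ``empty_value``."""
    inter, np_, ng = _counts(P, G)
    union = np_ + ng - inter
    if union == 0:
        return empty_value
    return inter / union


def evaluate(
    pred: SegmentationMask,
    gt: SegmentationMask,
    classes: tuple[int, ...] = DEFAULT_CLASSES,
    empty_value: float = 1.0,
) -> SegMetrics:
    """Per-class one-vs-rest Dice/IoU plus summary values.

    ``mean_iou`` averages the per-class IoU over the requested classes
    (default: osteocyte and dendrite; NaN entries from the both-empty
    convention are excluded).  ``dice_overall`` is the Dice of the union of
    all requested foreground classes treated as a single binary mask.
    """
    if pred.shape != gt.shape:
        raise ValidationError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    for c in classes:
        if c not in VALID_LABELS:
            raise ValidationError(f"unknown class id {c}")
    d = {c: dice(pred.labels == c, gt.labels == c, empty_value) for c in classes}
    j = {c: iou(pred.labels == c, gt.labels == c, empty_value) for c in classes}
    ious = np.array([j[c] for c in classes], dtype=float)
    mean_iou = float(np.nanmean(ious)) if np.isfinite(ious).any() else float("nan")
    fg = tuple(c for c in classes if c != 0) or classes
    overall = dice(np.isin(pred.labels, fg), np.isin(gt.labels, fg), empty_value)
    return SegMetrics(d, j, mean_iou, overall)


def evaluate_batch(
    pairs: list[tuple[SegmentationMask, SegmentationMask]],
    classes: tuple[int, ...] = DEFAULT_CLASSES,
) -> pd.DataFrame:
    """Evaluate many (pred, gt) pairs; one row per image plus a ``mean``
    row (per-image averaging, the reduction used for headline scores)."""
    rows = []
    for i, (p, g) in enumerate(pairs):
        m = evaluate(p, g, classes=classes)
        row = {"image": i, "dice_overall": m.dice_overall, "mean_iou": m.mean_iou}
        for c in classes:
            row[f"dice_{c}"] = m.dice_per_class[c]
            row[f"iou_{c}"] = m.iou_per_class[c]
        rows.append(row)
    df = pd.DataFrame(rows)
    mean = df.drop(columns="image").mean()
    mean["image"] = "mean"
    return pd.concat([df, mean.to_frame().T], ignore_index=True)


def pooled_evaluate(
    pairs: list[tuple[SegmentationMask, SegmentationMask]],
    classes: tuple[int, ...] = DEFAULT_CLASSES,
) -> SegMetrics:
    """Pooled-pixel reduction: accumulate intersections/unions over all
    images before forming the ratios (the alternative headline reduction)."""
    inter = {c: 0 for c in classes}
    sz_p = {c: 0 for c in classes}
    sz_g = {c: 0 for c in classes}
    o_inter = o_p = o_g = 0
    fg = tuple(c for c in classes if c != 0) or classes
    for p, g in pairs:
        for c in classes:
            i, a, b = _counts(p.labels == c, g.labels == c)
            inter[c] += i
            sz_p[c] += a
            sz_g[c] += b
        i, a, b = _counts(np.isin(p.labels, fg), np.isin(g.labels, fg))
        o_inter, o_p, o_g = o_inter + i, o_p + a, o_g + b
    d = {c: (2 * inter[c] / (sz_p[c] + sz_g[c])) if sz_p[c] + sz_g[c] else 1.0 for c in classes}
    j = {
        c: (inter[c] / (sz_p[c] + sz_g[c] - inter[c])) if sz_p[c] + sz_g[c] - inter[c] else 1.0
        for c in classes
    }
    mean_iou = float(np.mean([j[c] for c in classes]))
    overall = (2 * o_inter / (o_p + o_g)) if o_p + o_g else 1.0
    return SegMetrics(d, j, mean_iou, overall)
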