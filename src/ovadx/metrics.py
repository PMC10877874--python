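"""Segmentation evaluation: Dice similarity coefficient, sensitivity,
specificity and Hausdorff distance between mask boundaries.

DSC = 2TP/(2TP+FP+FN); Se = TP/(TP+FN); Sp = TN/(TN+FP); HD is the
symmetric max of directed furthest-nearest-neighbor Euclidean distances
between the two boundary point sets (4-connectivity boundaries, pixel
spacing 1 unless given).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ConfusionCounts",
    "SegScore",
    "confusion_counts",
    "dsc",
    "sensitivity",
    "specificity",
    "boundary_points",
    "hausdorff",
    "score_pair",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class SegScore:
    """One case's four metrics; dsc/se/sp as fractions in [0,1], hd in pixels."""

    dsc: float
    se: float
    sp: float
    hd: float


def _as_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(np.unique(a), (0, 1, True, False)).all():
        raise ValueError(f"{name} mask must be binary")
    return a.astype(bool)


def confusion_counts(pred: np.ndarray, gold: np.ndarray) -> ConfusionCounts:
    pred = _as_binary(pred, "pred")
    gold = _as_binary(gold, "gold")
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gold.shape}")
    tp = int(np.count_nonzero(pred & gold))
    fp = int(np.count_nonzero(pred & ~gold))
    fn = int(np.count_nonzero(~pred & gold))
    tn = int(np.count_nonzero(~pred & ~gold))
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def dsc(c: ConfusionCounts) -> float:
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        warnings.warn("both masks empty: DSC defined as 1")
        return 1.0
    return 2 * c.TP / denom


def sensitivity(c: ConfusionCounts) -> float:
    if c.TP + c.FN == 0:
        raise ValueError("sensitivity undefined: gold mask has no positives")
    return c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    if c.TN + c.FP == 0:
        raise ValueError("specificity undefined: gold mask covers whole image")
    return c.TN / (c.TN + c.FP)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of mask-positive pixels with a non-positive 4-neighbor
    (pixels on the image edge count as boundary)."""
    mask = _as_binary(mask, "mask")
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    return np.argwhere(boundary)


def hausdorff(pred: np.ndarray, gold: np.ndarray, spacing: float = 1.0) -> float:
    """Symmetric Hausdorff distance between boundary point sets (pixels)."""
    p = boundary_points(pred)
    g = boundary_points(gold)
    if len(p) == 0 or len(g) == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    d = cdist(p.astype(float), g.astype(float))
    return float(spacing * max(d.min(axis=1).max(), d.min(axis=0).max()))


def score_pair(pred: np.ndarray, gold: np.ndarray) -> SegScore:
    """All four metrics for one case.

    The strict metric functions refuse an empty mask; here an empty
    *prediction* (a network that finds no tumor at all) is scored with
    the worst defined values — DSC and Se follow from the zero counts,
    and HD is set to the image diagonal, the largest distance the frame
    allows — so dataset summaries stay defined.
    """
    c = confusion_counts(pred, gold)
    pred_arr = np.asarray(pred)
    if not pred_arr.any():
        diag = float(np.hypot(*pred_arr.shape))
        return SegScore(dsc=dsc(c), se=sensitivity(c), sp=specificity(c), hd=diag)
    return SegScore(
        dsc=dsc(c), se=sensitivity(c), sp=specificity(c), hd=hausdorff(pred, gold)
    )


def evaluate_dataset(preds, golds):
    """Mean ± sd of the four metrics over paired mask collections.

    Returns a DataFrame with rows DSC/%, Se/%, Sp/%, HD and columns
    mean/sd (percent scale for the first three, pixels for HD). The sd
    uses the sample (n−1) denominator.
    """
    import pandas as pd

    preds = list(preds)
    golds = list(golds)
    if len(preds) != len(golds):
        raise ValueError(f"length mismatch: {len(preds)} preds vs {len(golds)} golds")
    if not preds:
        raise ValueError("no cases to evaluate")
    scores = [score_pair(p, g) for p, g in zip(preds, golds)]
    return summarize_scores(scores)


def summarize_scores(scores) -> "pd.DataFrame":
    """Mean ± sd table from per-case :class:`SegScore` values."""
    import pandas as pd

    arr = np.array([[s.dsc * 100, s.se * 100, s.sp * 100, s.hd] for s in scores])
    ddof = 1 if len(arr) > 1 else 0
    return pd.DataFrame(
        {"mean": arr.mean(axis=0), "sd": arr.std(axis=0, ddof=ddof)},
        index=["DSC/%", "Se/%", "Sp/%", "HD"],
    )
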