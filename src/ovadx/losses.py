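"""Training objectives for the segmentation network.

Three pixelwise losses are compared: class-balanced cross-entropy (CBCE),
which reweights the tumor/background classes by β = |Y−|/|Y| and 1−β to
counter the heavy class imbalance of tumor slices; classical (unweighted)
cross-entropy; and soft Dice loss. All losses are summed over pixels by
default, matching their Σ definitions; pass ``average=True`` to divide by
the pixel count (convenient for optimizers).

Probabilities are clipped to [ε, 1−ε] with ε = 1e−7 before logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPSILON",
    "ClassBalance",
    "class_balance_weight",
    "cbce_loss",
    "ce_loss",
    "dice_loss",
    "LOSS_FUNCTIONS",
    "loss_and_logit_grad",
]

EPSILON = 1e-7
DICE_SMOOTH = 1.0


@dataclass(frozen=True)
class ClassBalance:
    """Class-equilibrium weight β = |Y−|/|Y| with the underlying tallies."""

    beta: float
    n_pos: int
    n_neg: int

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg


def _check_shapes(pred: np.ndarray, gold: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    gold = np.asarray(gold)
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gold {gold.shape}")
    return pred, gold


def class_balance_weight(mask: np.ndarray) -> ClassBalance:
    """β = |Y−|/|Y| for a binary mask (exact integer ratio)."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("mask is empty")
    n_pos = int(np.count_nonzero(mask))
    n_neg = int(mask.size - n_pos)
    return ClassBalance(beta=n_neg / mask.size, n_pos=n_pos, n_neg=n_neg)


def cbce_loss(pred: np.ndarray, gold: np.ndarray, average: bool = False) -> float:
    """Class-balanced cross-entropy:
    −β·Σ_{j∈Y+} log p_j − (1−β)·Σ_{j∈Y−} log(1−p_j).
    """
    pred, gold = _check_shapes(pred, gold)
    bal = class_balance_weight(gold)
    p = np.clip(pred, EPSILON, 1 - EPSILON)
    pos = gold.astype(bool)
    loss = -bal.beta * np.log(p[pos]).sum() - (1 - bal.beta) * np.log(1 - p[~pos]).sum()
    return float(loss / pred.size) if average else float(loss)


def ce_loss(pred: np.ndarray, gold: np.ndarray, average: bool = False) -> float:
    """Unweighted summed binary cross-entropy."""
    pred, gold = _check_shapes(pred, gold)
    p = np.clip(pred, EPSILON, 1 - EPSILON)
    pos = gold.astype(bool)
    loss = -np.log(p[pos]).sum() - np.log(1 - p[~pos]).sum()
    return float(loss / pred.size) if average else float(loss)


def dice_loss(pred: np.ndarray, gold: np.ndarray, smooth: float = DICE_SMOOTH,
              average: bool = False) -> float:
    """Soft Dice loss: 1 − (2·Σ p·g + s) / (Σ p + Σ g + s)."""
    pred, gold = _check_shapes(pred, gold)
    g = gold.astype(float)
    inter = float((pred * g).sum())
    denom = float(pred.sum() + g.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


LOSS_FUNCTIONS = {"cbce": cbce_loss, "ce": ce_loss, "dice": dice_loss}


def loss_and_logit_grad(name: str, prob: np.ndarray, gold: np.ndarray):
    """Loss value and its gradient with respect to pre-sigmoid logits.

    Gradients are of the pixel-averaged loss (stable step sizes across
    ROI sizes). For the cross-entropies the sigmoid is folded in
    analytically; for Dice the chain rule through p(1−p) is applied.
    """
    prob = np.asarray(prob, dtype=float)
    g = np.asarray(gold, dtype=float)
    n = prob.size
    if name == "cbce":
        beta = class_balance_weight(gold).beta
        value = cbce_loss(prob, gold, average=True)
        grad = np.where(g > 0, beta * (prob - 1.0), (1.0 - beta) * prob) / n
    elif name == "ce":
        value = ce_loss(prob, gold, average=True)
        grad = (prob - g) / n
    elif name == "dice":
        inter = (prob * g).sum()
        denom = prob.sum() + g.sum()
        value = 1.0 - (2.0 * inter + DICE_SMOOTH) / (denom + DICE_SMOOTH)
        # d/dp of the soft Dice ratio, then dp/dz = p(1-p)
        dp = -(2.0 * g * (denom + DICE_SMOOTH) - (2.0 * inter + DICE_SMOOTH)) / (
            (denom + DICE_SMOOTH) ** 2
        )
        grad = dp * prob * (1.0 - prob)
    else:
        raise ValueError(f"unknown loss {name!r}; options are cbce, ce, dice")
    return float(value), grad
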