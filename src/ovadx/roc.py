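"""ROC analysis: curve construction, AUC, Youden operating point, the
DeLong test for correlated AUCs, and partition-restricted evaluation.

AUC is computed in the Mann–Whitney rank form (ties contribute ½), which
is exactly the trapezoidal area under the empirical ROC curve. The
DeLong test uses the fast structural-components formulation; its p-value
is two-sided normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "DeLongResult",
    "roc_curve",
    "auc_mann_whitney",
    "youden_operating_point",
    "delong_test",
    "evaluate_by_partition",
]


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve of a score vector against binary labels.

    ``thresholds`` ascend over the distinct scores (plus −inf so that the
    all-positive rule is included); predictions call positive where
    score ≥ threshold, so sensitivity is non-increasing in threshold.
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    youden_point: tuple[float, float, float]


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int).ravel()
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the scaled Mann–Whitney U statistic (ties give ½ credit)."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float).ravel()
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_curve(scores, labels) -> ROCResult:
    """Curve points at every distinct threshold plus the AUC and the
    Youden-optimal operating point."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    thresholds = np.concatenate([[-np.inf], np.unique(s)])
    n1 = y.sum()
    n0 = len(y) - n1
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = s >= t
        sens[i] = (pred & (y == 1)).sum() / n1
        spec[i] = (~pred & (y == 0)).sum() / n0
    auc = auc_mann_whitney(s, y)
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j == j.max())[0])  # tie -> lowest threshold
    result = ROCResult(
        thresholds=thresholds, sensitivities=sens, specificities=spec,
        auc=auc, youden_point=(float(thresholds[best]), float(sens[best]),
                               float(spec[best])),
    )
    return result


def youden_operating_point(roc: ROCResult) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing Se + Sp − 1."""
    return roc.youden_point


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float


def _structural_components(scores, y):
    """DeLong V10 (per case) and V01 (per control) placement components."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # P(neg < pos) + 0.5 P(neg == pos), vectorized over pairs
    cmp_matrix = (pos[:, None] > neg[None, :]).astype(float)
    cmp_matrix += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_matrix.mean(axis=1)
    v01 = cmp_matrix.mean(axis=0)
    return v10, v01, float(cmp_matrix.mean())


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Two-sided DeLong z-test for the difference of two correlated AUCs
    measured on the same subjects."""
    y = _check_labels(labels)
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores_a, scores_b and labels must be paired")
    v10a, v01a, auc_a = _structural_components(a, y)
    v10b, v01b, auc_b = _structural_components(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if diff == 0:
        z, p = 0.0, 1.0
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, var_diff=var_diff,
                        z=float(z), p=p)


def evaluate_by_partition(scores, labels, partition) -> dict:
    """One ROCResult per partition tag.

    ``partition`` assigns each subject a tag or None; subjects tagged
    None are included in *every* evaluation (e.g. tag cases by FIGO
    stage and leave controls untagged to get early-vs-all-controls and
    advanced-vs-all-controls curves, or tag controls by subgroup and
    leave cases untagged). Single-class partitions are skipped with a
    warning.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).astype(int).ravel()
    tags = np.asarray([None if t is None or t == "" else t for t in partition],
                      dtype=object)
    shared = tags == None  # noqa: E711  (elementwise None comparison)
    results = {}
    for tag in sorted({t for t in tags if t is not None}, key=str):
        sel = shared | (tags == tag)
        if len(np.unique(y[sel])) < 2:
            warnings.warn(f"partition {tag!r} contains a single class; skipped")
            continue
        results[tag] = roc_curve(scores[sel], y[sel])
    if not results:
        warnings.warn("no evaluable partition")
    return results
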