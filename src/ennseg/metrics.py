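"""Evaluation primitives for binary segmentation and segmentation confidence.

This module provides the closed-form quantities the pipeline is scored with:
the Dice overlap coefficient, per-voxel binary Shannon entropy, the average
foreground entropy of a fused ensemble probability map (the confidence score),
the success dichotomization (Dice > 0.8), empirical ROC analysis with
Mann-Whitney AUC, the Youden-index operating cutoff, and confusion statistics.

Conventions
-----------
* Dice of two empty masks is 1 (never triggered on tumor-bearing slices;
  needed for totality). Exactly one empty mask gives 0.
* Entropy is measured in bits, so a fused probability of 0.5 scores the
  maximum entropy of 1 and the score lives on [0, 1].
* An empty predicted foreground has no voxels to average over; it is assigned
  the maximal entropy 1.0 so that total misses sort with low confidence.
* Success is *strictly* Dice > 0.8; a Dice of exactly 0.8 is inadequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "DICE_SUCCESS_THRESHOLD",
    "SliceEvaluation",
    "PatientEvaluation",
    "RocResult",
    "dice",
    "binary_entropy",
    "foreground_entropy",
    "is_success",
    "roc",
    "youden_cutoff",
    "confusion_stats",
    "patient_dice",
]

#: Dice score above which a segmentation counts as successful (strict >).
DICE_SUCCESS_THRESHOLD = 0.8


@dataclass(frozen=True)
class SliceEvaluation:
    """Per-slice evaluation record: overlap, confidence score and identity."""

    dice: float
    fg_entropy: float
    patient_id: str
    slice_index: int
    phase: str = "synthetic"

    @property
    def success(self) -> bool:
        return self.dice > DICE_SUCCESS_THRESHOLD


@dataclass(frozen=True)
class PatientEvaluation:
    """Per-patient summary: voxel-pooled Dice and mean slice entropy."""

    dice: float
    fg_entropy: float
    patient_id: str
    phase: str = "synthetic"

    @property
    def success(self) -> bool:
        return self.dice > DICE_SUCCESS_THRESHOLD


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC of a score against a binary outcome.

    ``polarity`` records whether a *low* score predicts the positive class
    (the foreground-entropy convention: low entropy => success). Candidate
    cutoffs are the observed score values plus a sentinel above the maximum;
    at cutoff theta the positive call is ``score < theta`` for low-positive
    polarity and ``score > theta`` for high-positive polarity, matching the
    strict inequality used when the cutoff is later applied to new data.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    polarity: Literal["low_is_positive", "high_is_positive"]
    n_positive: int
    n_negative: int

    def youden_index(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), got values {vals[:10]}")
    return arr.astype(bool)


def dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice overlap 2|P∩R| / (|P|+|R|) between two binary masks.

    Both masks empty returns 1.0 by convention; exactly one empty returns 0.
    """
    pred = _as_binary(pred, "pred")
    ref = _as_binary(ref, "ref")
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    p = int(pred.sum())
    r = int(ref.sum())
    if p + r == 0:
        return 1.0
    inter = int(np.logical_and(pred, ref).sum())
    return 2.0 * inter / (p + r)


def binary_entropy(p: "float | np.ndarray") -> "float | np.ndarray":
    """Binary Shannon entropy H(p) in bits, with 0*log(0) := 0.

    H(p) = -p log2 p - (1-p) log2 (1-p); maximal (1.0) at p = 0.5.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(arr * np.log2(arr)) - ((1.0 - arr) * np.log2(1.0 - arr))
    h = np.nan_to_num(h, nan=0.0, posinf=0.0, neginf=0.0)
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(h)
    return h


def foreground_entropy(
    fused_prob: np.ndarray, binary_mask: np.ndarray | None = None
) -> tuple[float, bool]:
    """Average foreground entropy of a fused probability map.

    The mean of H(p_v) over voxels v inside the predicted foreground
    (fused probability >= 0.5, or an explicitly supplied binary mask).
    Returns ``(entropy, empty_flag)``; an empty predicted foreground is
    assigned entropy 1.0 with the flag set.
    """
    fused_prob = np.asarray(fused_prob, dtype=float)
    if np.any(fused_prob < 0) or np.any(fused_prob > 1):
        raise ValueError("fused probabilities must lie in [0, 1]")
    if binary_mask is None:
        binary_mask = fused_prob >= 0.5
    else:
        binary_mask = _as_binary(binary_mask, "binary_mask")
        if binary_mask.shape != fused_prob.shape:
            raise ValueError("mask/probability shape mismatch")
    if not binary_mask.any():
        return 1.0, True
    return float(np.mean(binary_entropy(fused_prob[binary_mask]))), False


def is_success(d: float, threshold: float = DICE_SUCCESS_THRESHOLD) -> bool:
    """Success dichotomization: strictly greater than the Dice threshold."""
    return d > threshold


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # Midrank formulation: exactly the pairwise concordance with ties at 1/2.
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc(
    scores: Sequence[float],
    labels: Sequence[int],
    polarity: Literal["low_is_positive", "high_is_positive"] = "high_is_positive",
) -> RocResult:
    """Empirical ROC over all distinct score cutoffs.

    AUC is the Mann-Whitney pairwise concordance (ties counted 1/2), which
    coincides with the trapezoid area under the empirical curve. For
    ``low_is_positive`` polarity (entropy scoring: low entropy predicts
    success) the positive call at cutoff theta is ``score < theta``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "ROC analysis needs at least one positive and one negative label; "
            f"got {n_pos} positive / {n_neg} negative"
        )

    if polarity == "low_is_positive":
        oriented = -scores
    elif polarity == "high_is_positive":
        oriented = scores
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    auc = _mann_whitney_auc(oriented, labels)

    uniq = np.unique(scores)
    if polarity == "low_is_positive":
        # Candidate cutoffs: observed values plus one above the maximum so the
        # all-positive operating point is reachable under the strict '<' rule.
        step = max(np.spacing(uniq[-1]), 1e-12)
        thresholds = np.concatenate([uniq, [uniq[-1] + step]])
        pred_pos = scores[None, :] < thresholds[:, None]
    else:
        step = max(np.spacing(np.abs(uniq[0])), 1e-12)
        thresholds = np.concatenate([[uniq[0] - step], uniq])
        pred_pos = scores[None, :] > thresholds[:, None]

    tp = (pred_pos & labels[None, :]).sum(axis=1)
    fp = (pred_pos & ~labels[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        polarity=polarity,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def youden_cutoff(result: RocResult) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the cutoff with higher sensitivity, then toward
    the lower threshold value. Returns (cutoff, sensitivity, specificity)
    at the selected operating point.
    """
    j = result.youden_index()
    best = np.flatnonzero(j == j.max())
    # Higher sensitivity first, then lower threshold.
    best = best[result.sensitivity[best] == result.sensitivity[best].max()]
    idx = best[np.argmin(result.thresholds[best])]
    return (
        float(result.thresholds[idx]),
        float(result.sensitivity[idx]),
        float(result.specificity[idx]),
    )


def confusion_stats(
    predicted: Sequence[int], truth: Sequence[int]
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of binary predictions vs truth."""
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    tp = int((predicted & truth).sum())
    tn = int((~predicted & ~truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    n_pos = tp + fn
    n_neg = tn + fp
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    acc = (tp + tn) / truth.size
    return sens, spec, acc


def patient_dice(slice_pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Voxel-pooled Dice over all of one patient's tumor-bearing slices.

    Stacks every (predicted, reference) slice pair into one array each and
    computes a single Dice, so large slices weigh more than small ones; this
    differs from averaging per-slice Dice when slice areas differ.
    """
    if len(slice_pairs) == 0:
        raise ValueError("patient_dice needs at least one slice pair")
    preds = np.stack([np.asarray(p) for p, _ in slice_pairs])
    refs = np.stack([np.asarray(r) for _, r in slice_pairs])
    return dice(preds, refs)
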