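"""Entropy-based segmentation-confidence calibration and assessment.

The confidence score of an ensemble prediction is its average foreground
entropy: low entropy means the members agree inside the predicted tumor
region, which empirically tracks segmentation success (Dice > 0.8). This
module reproduces the two-stage design of that analysis: a cutoff on the
entropy is *calibrated* once on a hold-out set with known reference masks
(ROC of entropy vs. success, operating point by the Youden index), and then
*applied* to new predictions without any reference mask.

A prediction is called successful when its foreground entropy is strictly
below the calibrated cutoff; a value exactly at the cutoff is flagged as
inadequate (ties go to the review-needed side).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ensemble import EnsemblePrediction
from .metrics import (
    DICE_SUCCESS_THRESHOLD,
    PatientEvaluation,
    RocResult,
    SliceEvaluation,
    confusion_stats,
    foreground_entropy,
    roc,
    youden_cutoff,
)

__all__ = [
    "ConfidenceCalibration",
    "ConfidenceReport",
    "calibrate",
    "assess",
    "evaluate_calibration",
    "save_calibration",
    "load_calibration",
]


@dataclass(frozen=True)
class ConfidenceCalibration:
    """A fixed entropy cutoff with its calibration provenance."""

    entropy_cutoff: float
    dice_success_threshold: float
    roc: RocResult | None
    granularity: str  # slice | patient
    n_success: int
    n_inadequate: int
    auc: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ConfidenceReport:
    """Assessment of one prediction against a fixed calibration."""

    fg_entropy: float
    predicted_success: bool
    entropy_cutoff: float
    empty_foreground: bool = False


def calibrate(
    evaluations: Sequence["SliceEvaluation | PatientEvaluation"],
    granularity: str = "slice",
    provenance: dict | None = None,
) -> ConfidenceCalibration:
    """Calibrate the entropy cutoff on evaluations with known success labels.

    Builds the ROC of foreground entropy against segmentation success with
    low-entropy-is-positive polarity and selects the Youden-index cutoff.
    Requires both classes to be present.
    """
    entropies = np.array([e.fg_entropy for e in evaluations], dtype=float)
    successes = np.array([e.success for e in evaluations], dtype=bool)
    n_success = int(successes.sum())
    n_inadequate = int((~successes).sum())
    if n_success == 0 or n_inadequate == 0:
        raise ValueError(
            "calibration needs both successful and inadequate segmentations; "
            f"got {n_success} successful / {n_inadequate} inadequate — widen the "
            "calibration set or check the Dice success threshold"
        )
    roc_result = roc(entropies, successes, polarity="low_is_positive")
    cutoff, sens, spec = youden_cutoff(roc_result)
    return ConfidenceCalibration(
        entropy_cutoff=cutoff,
        dice_success_threshold=DICE_SUCCESS_THRESHOLD,
        roc=roc_result,
        granularity=granularity,
        n_success=n_success,
        n_inadequate=n_inadequate,
        auc=roc_result.auc,
        sensitivity_at_cutoff=sens,
        specificity_at_cutoff=spec,
        provenance=dict(provenance or {}),
    )


def assess(
    pred: "EnsemblePrediction | float",
    cal: ConfidenceCalibration,
    member_vote_entropy: bool = False,
) -> ConfidenceReport:
    """Apply a fixed calibration to a new prediction (no reference needed).

    ``pred`` may be an :class:`EnsemblePrediction` or a precomputed
    foreground-entropy value. By default the entropy is computed from the
    fused probability map; ``member_vote_entropy=True`` instead computes it
    from the fraction of members voting foreground per voxel (a documented
    alternative construction).
    """
    if cal is None:
        raise ValueError("a ConfidenceCalibration is required")
    empty = False
    if isinstance(pred, EnsemblePrediction):
        if member_vote_entropy:
            votes = (pred.member_probs >= 0.5).mean(axis=0)
            entropy, empty = foreground_entropy(votes, pred.binary_mask)
        else:
            entropy, empty = foreground_entropy(pred.fused_prob, pred.binary_mask)
    else:
        entropy = float(pred)
    return ConfidenceReport(
        fg_entropy=entropy,
        predicted_success=entropy < cal.entropy_cutoff,
        entropy_cutoff=cal.entropy_cutoff,
        empty_foreground=empty,
    )


def evaluate_calibration(
    cal: ConfidenceCalibration,
    evaluations: Sequence["SliceEvaluation | PatientEvaluation"],
) -> tuple[float, float, float]:
    """Apply a fixed cutoff to fresh labeled evaluations.

    Returns (accuracy, sensitivity, specificity) of the entropy-based
    success call against the true Dice-based success labels — the
    external-test usage pattern where the cutoff was frozen beforehand.
    """
    predicted = [assess(e.fg_entropy, cal).predicted_success for e in evaluations]
    truth = [e.success for e in evaluations]
    sens, spec, acc = confusion_stats(predicted, truth)
    return acc, sens, spec


def save_calibration(cal: ConfidenceCalibration, path: "str | Path") -> None:
    payload = {
        "entropy_cutoff": cal.entropy_cutoff,
        "dice_success_threshold": cal.dice_success_threshold,
        "granularity": cal.granularity,
        "n_success": cal.n_success,
        "n_inadequate": cal.n_inadequate,
        "auc": cal.auc,
        "sensitivity_at_cutoff": cal.sensitivity_at_cutoff,
        "specificity_at_cutoff": cal.specificity_at_cutoff,
        "provenance": cal.provenance,
        "roc_points": None
        if cal.roc is None
        else {
            "thresholds": cal.roc.thresholds.tolist(),
            "sensitivity": cal.roc.sensitivity.tolist(),
            "specificity": cal.roc.specificity.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(path: "str | Path") -> ConfidenceCalibration:
    payload = json.loads(Path(path).read_text())
    roc_result = None
    pts = payload.get("roc_points")
    if pts is not None:
        roc_result = RocResult(
            thresholds=np.asarray(pts["thresholds"]),
            sensitivity=np.asarray(pts["sensitivity"]),
            specificity=np.asarray(pts["specificity"]),
            auc=payload["auc"],
            polarity="low_is_positive",
            n_positive=payload["n_success"],
            n_negative=payload["n_inadequate"],
        )
    return ConfidenceCalibration(
        entropy_cutoff=payload["entropy_cutoff"],
        dice_success_threshold=payload["dice_success_threshold"],
        roc=roc_result,
        granularity=payload["granularity"],
        n_success=payload["n_success"],
        n_inadequate=payload["n_inadequate"],
        auc=payload["auc"],
        sensitivity_at_cutoff=payload["sensitivity_at_cutoff"],
        specificity_at_cutoff=payload["specificity_at_cutoff"],
        provenance=payload.get("provenance", {}),
    )
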