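"""End-to-end orchestration helpers: cohort -> split -> train -> evaluate.

These functions tie the modules together the way the full study design does:
slices are pooled per split set (patient-grouped, both contrast phases of a
patient in one set), an ensemble is trained on the training set with
model selection on the validation set, predictions on the hold-out set are
scored per slice (Dice, foreground entropy, success) and per patient
(voxel-pooled Dice, mean slice entropy), and the entropy cutoff is
calibrated on the hold-out evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .confidence import ConfidenceCalibration, calibrate
from .ensemble import (
    EnsembleConfig,
    EnsembleModel,
    EnsemblePrediction,
    predict_slices,
    train_ensemble,
)
from .io import CTSlice, DatasetSplit, MaskSlice, patient_split, tumor_slices
from .metrics import (
    PatientEvaluation,
    SliceEvaluation,
    dice,
    foreground_entropy,
    patient_dice,
)
from .phantom import PhantomCohort, PhantomParams, generate_cohort

__all__ = [
    "cohort_slice_pairs",
    "split_cohort",
    "evaluate_predictions",
    "patient_evaluations",
    "summarize_evaluations",
    "evaluations_to_frame",
    "PhantomPipelineResult",
    "run_phantom_pipeline",
]


def cohort_slice_pairs(
    cohort: PhantomCohort, patient_ids: Sequence[str] | None = None
) -> list[tuple[CTSlice, MaskSlice]]:
    """All tumor-bearing (slice, mask) pairs, optionally restricted to patients."""
    wanted = None if patient_ids is None else set(patient_ids)
    pairs: list[tuple[CTSlice, MaskSlice]] = []
    for case in cohort.cases:
        if wanted is not None and case.volume.patient_id not in wanted:
            continue
        pairs.extend(tumor_slices(case.volume, case.mask))
    return pairs


def split_cohort(
    cohort: PhantomCohort,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    return patient_split(cohort.patient_ids, fractions, seed)


def evaluate_predictions(
    preds: Sequence[EnsemblePrediction], refs: Sequence[MaskSlice]
) -> list[SliceEvaluation]:
    """Score each prediction against its reference slice."""
    if len(preds) != len(refs):
        raise ValueError("predictions and references must align")
    out = []
    for pred, ref in zip(preds, refs):
        d = dice(pred.binary_mask, ref.mask)
        entropy, _ = foreground_entropy(pred.fused_prob, pred.binary_mask)
        out.append(
            SliceEvaluation(
                dice=d,
                fg_entropy=entropy,
                patient_id=pred.patient_id or ref.patient_id,
                slice_index=pred.slice_index,
                phase=pred.phase,
            )
        )
    return out


def patient_evaluations(
    preds: Sequence[EnsemblePrediction], refs: Sequence[MaskSlice]
) -> list[PatientEvaluation]:
    """Per-(patient, phase) summaries: voxel-pooled Dice, mean slice entropy."""
    groups: dict[tuple[str, str], list[int]] = {}
    for i, pred in enumerate(preds):
        key = (pred.patient_id or refs[i].patient_id, pred.phase)
        groups.setdefault(key, []).append(i)
    out = []
    for (pid, phase), idx in sorted(groups.items()):
        pooled = patient_dice([(preds[i].binary_mask, refs[i].mask) for i in idx])
        entropies = [
            foreground_entropy(preds[i].fused_prob, preds[i].binary_mask)[0]
            for i in idx
        ]
        out.append(
            PatientEvaluation(
                dice=pooled,
                fg_entropy=float(np.mean(entropies)),
                patient_id=pid,
                phase=phase,
            )
        )
    return out


def evaluations_to_frame(evals: Sequence[SliceEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in evals],
            "slice_index": [e.slice_index for e in evals],
            "phase": [e.phase for e in evals],
            "dice": [e.dice for e in evals],
            "fg_entropy": [e.fg_entropy for e in evals],
            "success": [e.success for e in evals],
        }
    )


def summarize_evaluations(
    evals: Sequence["SliceEvaluation | PatientEvaluation"],
) -> dict:
    """Median and IQR of Dice per contrast phase plus overall, as reported
    summary statistics (25th-75th percentile, linear interpolation)."""
    frame = pd.DataFrame(
        {
            "phase": [e.phase for e in evals],
            "dice": [e.dice for e in evals],
            "fg_entropy": [e.fg_entropy for e in evals],
            "success": [e.success for e in evals],
        }
    )

    def stats(sub: pd.DataFrame) -> dict:
        q25, q50, q75 = np.percentile(sub["dice"], [25, 50, 75])
        return {
            "n": int(len(sub)),
            "median_dice": float(q50),
            "iqr_dice": [float(q25), float(q75)],
            "median_fg_entropy": float(sub["fg_entropy"].median()),
            "success_rate": float(sub["success"].mean()),
        }

    summary = {"overall": stats(frame)}
    for phase, sub in frame.groupby("phase"):
        summary[str(phase)] = stats(sub)
    return summary


@dataclass
class PhantomPipelineResult:
    """Everything the full phantom run produces, kept in memory."""

    cohort: PhantomCohort
    split: DatasetSplit
    model: EnsembleModel
    holdout_preds: list[EnsemblePrediction]
    holdout_refs: list[MaskSlice]
    slice_evals: list[SliceEvaluation]
    patient_evals: list[PatientEvaluation]
    calibration: ConfidenceCalibration | None
    summary: dict


def run_phantom_pipeline(
    phantom_params: PhantomParams,
    ensemble_config: EnsembleConfig,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    split_seed: int = 0,
    calibrate_confidence: bool = True,
) -> PhantomPipelineResult:
    """Simulate -> split -> train -> predict -> evaluate [-> calibrate].

    The hold-out set is never seen during training or model selection; the
    confidence calibration is fit on the hold-out evaluations, mirroring the
    internal-test design. Calibration is skipped (None) when the hold-out
    evaluations contain only one success class.
    """
    cohort = generate_cohort(phantom_params)
    split = split_cohort(cohort, fractions, split_seed)
    train_pairs = cohort_slice_pairs(cohort, split.train)
    val_pairs = cohort_slice_pairs(cohort, split.validation)
    holdout_pairs = cohort_slice_pairs(cohort, split.holdout)

    model = train_ensemble(train_pairs, val_pairs, ensemble_config)
    holdout_slices = [s for s, _ in holdout_pairs]
    holdout_refs = [m for _, m in holdout_pairs]
    preds = predict_slices(model, holdout_slices)

    slice_evals = evaluate_predictions(preds, holdout_refs)
    pat_evals = patient_evaluations(preds, holdout_refs)
    summary = summarize_evaluations(slice_evals)

    cal = None
    if calibrate_confidence:
        classes = {e.success for e in slice_evals}
        if len(classes) == 2:
            cal = calibrate(
                slice_evals,
                granularity="slice",
                provenance={"dataset": "phantom_holdout", "seed": phantom_params.seed},
            )
            summary["confidence"] = {
                "auc": cal.auc,
                "entropy_cutoff": cal.entropy_cutoff,
                "sensitivity": cal.sensitivity_at_cutoff,
                "specificity": cal.specificity_at_cutoff,
            }
    return PhantomPipelineResult(
        cohort=cohort,
        split=split,
        model=model,
        holdout_preds=preds,
        holdout_refs=holdout_refs,
        slice_evals=slice_evals,
        patient_evals=pat_evals,
        calibration=cal,
        summary=summary,
    )
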