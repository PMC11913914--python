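"""Reading and writing CT volumes, masks and splits.

Handles the KiTS-style directory layout (``case_XXXXX/imaging.nii.gz`` plus
``segmentation.nii.gz`` with labels 0 = background, 1 = kidney, 2 = tumor),
extraction of the tumor-bearing axial slices the 2D segmentation task is
trained on, patient-grouped train/validation/hold-out splits, and a
float NIfTI round-trip for per-member probability maps.

Orientation note: the NIfTI affine is consulted only for voxel spacing, never
for reorientation — the segmentation task is per axial slice and
orientation-agnostic. Axial slices are indexed along the last array axis and
addressed (row, col) = (y, x), 0-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CTVolume",
    "CTSlice",
    "MaskSlice",
    "DatasetSplit",
    "load_case",
    "tumor_slices",
    "patient_split",
    "save_probability_map",
    "load_probability_map",
    "save_split",
    "load_split",
]

#: KiTS 2019 label semantics; override via load_case(tumor_label=...).
KITS_TUMOR_LABEL = 2
KITS_KNOWN_LABELS = (0, 1, 2)


@dataclass
class CTVolume:
    """One CT volume: stored intensities (16-bit range), identity, geometry."""

    voxels: np.ndarray  # (y, x, z)
    spacing: tuple[float, float, float]  # (z, y, x) in mm
    patient_id: str
    phase: str = "synthetic"  # corticomedullary | nephrogenic | synthetic
    source_path: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume.voxels must be 3D (y, x, z)")
        if self.voxels.shape[0] != self.voxels.shape[1]:
            raise ValueError("axial plane must be square")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]


@dataclass
class CTSlice:
    """One axial slice with its identity and in-plane spacing."""

    pixels: np.ndarray
    slice_index: int
    patient_id: str
    phase: str = "synthetic"
    spacing_yx: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("CTSlice.pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("CTSlice.pixels must be finite")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")


@dataclass
class MaskSlice:
    """A binary mask aligned to a CTSlice (reference or predicted)."""

    mask: np.ndarray
    slice_index: int
    patient_id: str
    origin: str = "reference"  # reference | predicted

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask must be binary, got values {vals[:10]}")
        self.mask = mask.astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("MaskSlice.mask must be 2D")


@dataclass(frozen=True)
class DatasetSplit:
    """Patient-grouped train/validation/hold-out partition."""

    train: frozenset[str]
    validation: frozenset[str]
    holdout: frozenset[str]
    fractions: tuple[float, float, float]
    seed: int

    def set_of(self, patient_id: str) -> str:
        for name in ("train", "validation", "holdout"):
            if patient_id in getattr(self, name):
                return name
        raise KeyError(patient_id)


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    # Data axes are (i, j, k); we treat k as the axial stacking axis and
    # report spacing as (z, y, x).
    spacing = (float(zooms[2]), float(zooms[0]), float(zooms[1]))
    return data, spacing


def load_case(
    case_dir: "str | Path",
    tumor_label: int = KITS_TUMOR_LABEL,
    known_labels: Sequence[int] = KITS_KNOWN_LABELS,
    phase: str = "corticomedullary",
) -> tuple[CTVolume, np.ndarray]:
    """Load one KiTS-layout case directory.

    Returns the CT volume and a binary tumor mask (``segmentation == 2`` by
    default; the kidney label is dropped). Raises ``FileNotFoundError`` for a
    missing file, ``ValueError`` for an image/segmentation shape mismatch or
    a segmentation label outside ``known_labels``.
    """
    case_dir = Path(case_dir)
    img_path = _find_nifti(case_dir, "imaging")
    seg_path = _find_nifti(case_dir, "segmentation")

    voxels, spacing = _read_nifti(img_path)
    seg, _ = _read_nifti(seg_path)
    if voxels.shape != seg.shape:
        raise ValueError(
            f"image/segmentation shape mismatch in {case_dir.name}: "
            f"{voxels.shape} vs {seg.shape}"
        )
    seg = np.rint(seg).astype(np.int64)
    labels = np.unique(seg)
    unknown = sorted(set(labels.tolist()) - set(known_labels))
    if unknown:
        raise ValueError(
            f"segmentation in {case_dir.name} contains unknown label(s) {unknown}; "
            f"expected labels within {tuple(known_labels)}"
        )
    tumor = seg == tumor_label
    if not tumor.any():
        logger.warning("case %s has an empty tumor mask", case_dir.name)
    volume = CTVolume(
        voxels=voxels,
        spacing=spacing,
        patient_id=case_dir.name,
        phase=phase,
        source_path=str(img_path),
    )
    return volume, tumor


def _find_nifti(case_dir: Path, stem: str) -> Path:
    for suffix in (".nii.gz", ".nii"):
        candidate = case_dir / f"{stem}{suffix}"
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"no {stem}.nii[.gz] in {case_dir}")


def tumor_slices(
    volume: CTVolume, ref: np.ndarray
) -> list[tuple[CTSlice, MaskSlice]]:
    """Extract the axial slices that contain reference tumor.

    Returns (CTSlice, MaskSlice) pairs in ascending slice order for exactly
    the indices where the reference mask has at least one foreground voxel.
    An empty result is legal (and logged).
    """
    ref = np.asarray(ref)
    if ref.shape != volume.voxels.shape:
        raise ValueError("volume and reference mask must share shape")
    ref = ref.astype(bool)
    indices = np.flatnonzero(ref.any(axis=(0, 1)))
    if indices.size == 0:
        logger.warning("volume %s contains no tumor-bearing slices", volume.patient_id)
    spacing_yx = (volume.spacing[1], volume.spacing[2])
    pairs = []
    for k in indices:
        k = int(k)
        pairs.append(
            (
                CTSlice(
                    pixels=volume.voxels[:, :, k],
                    slice_index=k,
                    patient_id=volume.patient_id,
                    phase=volume.phase,
                    spacing_yx=spacing_yx,
                ),
                MaskSlice(
                    mask=ref[:, :, k],
                    slice_index=k,
                    patient_id=volume.patient_id,
                    origin="reference",
                ),
            )
        )
    return pairs


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    remainder = n - sum(counts)
    # Distribute leftover units to the largest fractional parts; ties go to
    # the later sets (validation/hold-out receive the remainders).
    order = sorted(
        range(len(fractions)), key=lambda i: (exact[i] - counts[i], i), reverse=True
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def patient_split(
    patients: Sequence[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Deterministic patient-level split with largest-remainder set sizes.

    Patients (not slices or phases) are the unit of assignment, so both
    contrast phases of a patient always land in the same set. The input
    order of ``patients`` does not affect membership: ids are sorted before
    the seeded shuffle.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    unique = sorted(set(patients))
    n_nonzero = sum(1 for f in fractions if f > 0)
    if len(unique) < max(n_nonzero, 3):
        raise ValueError(
            f"need at least {max(n_nonzero, 3)} patients, got {len(unique)}"
        )
    counts = _largest_remainder_counts(len(unique), fractions)
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(unique))
    train = frozenset(shuffled[: counts[0]])
    validation = frozenset(shuffled[counts[0] : counts[0] + counts[1]])
    holdout = frozenset(shuffled[counts[0] + counts[1] :])
    return DatasetSplit(
        train=train,
        validation=validation,
        holdout=holdout,
        fractions=tuple(fractions),
        seed=seed,
    )


def save_probability_map(
    prob: np.ndarray, path: "str | Path", spacing: tuple[float, ...] | None = None
) -> None:
    """Write a probability map (values in [0, 1]) as float32 NIfTI."""
    prob = np.asarray(prob, dtype=np.float32)
    if np.any(prob < 0) or np.any(prob > 1):
        raise ValueError("probability values must lie in [0, 1]")
    data = prob if prob.ndim == 3 else prob[:, :, None]
    affine = np.eye(4)
    if spacing is not None:
        # spacing given (z, y, x); NIfTI zooms are (i, j, k) = (y, x, z).
        affine[0, 0], affine[1, 1], affine[2, 2] = spacing[1], spacing[2], spacing[0]
    img = nib.Nifti1Image(data, affine)
    nib.save(img, str(path))


def load_probability_map(path: "str | Path") -> np.ndarray:
    """Load a probability map written by :func:`save_probability_map`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if np.any(data < -1e-6) or np.any(data > 1 + 1e-6):
        raise ValueError(f"{path} does not contain probabilities in [0, 1]")
    return np.clip(data, 0.0, 1.0)


def save_split(split: DatasetSplit, path: "str | Path") -> None:
    payload = {
        "train": sorted(split.train),
        "validation": sorted(split.validation),
        "holdout": sorted(split.holdout),
        "fractions": list(split.fractions),
        "seed": split.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_split(path: "str | Path") -> DatasetSplit:
    payload = json.loads(Path(path).read_text())
    return DatasetSplit(
        train=frozenset(payload["train"]),
        validation=frozenset(payload["validation"]),
        holdout=frozenset(payload["holdout"]),
        fractions=tuple(payload["fractions"]),
        seed=int(payload["seed"]),
    )
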