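"""Synthetic pseudo-CT phantom cohorts for desk-scale pipeline testing.

Real contrast-enhanced CT cohorts with expert tumor segmentations are not
shippable with a code repository, so every downstream stage (slice
extraction, patient-grouped splitting, ensemble training, confidence
calibration, visualization) is exercised on generated phantoms instead:
stacks of axial slices containing a single tumor-like bright blob over a
textured background with darker "organ" distractor ellipsoids.

The module also provides two oracles that need no training at all:

* :func:`degrade_mask` produces predicted masks of graded quality from a
  reference mask (erosion, dilation, shift, pixel dropout, or a disjoint
  wrong-region blob emulating a gross mislocalization with Dice 0).
* :func:`simulate_soft_prediction` produces fused-probability-like soft maps
  whose foreground entropy rises and whose thresholded Dice falls as the
  quality knob is lowered — the controlled analogue of an ensemble that is
  increasingly unsure.

What the phantoms deliberately do not model: anatomy, Hounsfield-accurate
tissue values, scanner physics, 3D tumor shape statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import CTVolume, MaskSlice

__all__ = [
    "PhantomParams",
    "PhantomCase",
    "PhantomCohort",
    "generate_cohort",
    "degrade_mask",
    "simulate_soft_prediction",
    "write_cohort",
]

# Stored-intensity scale: a 12-bit subrange of the 16-bit depth, roughly
# emulating CT stored values (soft tissue ~BACKGROUND_MEAN, enhancing tumor
# BACKGROUND_MEAN + tumor_contrast).
BACKGROUND_MEAN = 2000.0
BACKGROUND_TEXTURE_SD = 150.0
# Distractor organs span dark to bright; the bright tail approaches typical
# tumor contrast so that some cases contain a genuinely confusable structure
# (the "wrong bright organ" failure mode of clinical segmentation).
DISTRACTOR_OFFSET_RANGE = (-450.0, 400.0)
INTENSITY_RANGE = (1024.0, 5119.0)


@dataclass(frozen=True)
class PhantomParams:
    """Generator settings for one synthetic cohort.

    Defaults target fast desk-scale runs (64x64 slices); ``image_size`` can
    be raised to 512 for clinical-geometry parity. ``phases = 2`` emits a
    pseudo-corticomedullary and a pseudo-nephrogenic variant per patient
    that share geometry and reference mask but differ by a monotone
    intensity remapping and an independent noise draw.
    """

    image_size: int = 64
    n_patients: int = 10
    slices_per_patient_range: tuple[int, int] = (5, 20)
    tumor_radius_range: tuple[float, float] = (5.0, 12.0)
    tumor_contrast: float = 700.0
    background_texture_scale: float = 8.0
    noise_sd: float = 80.0
    psf_sigma: float = 0.8
    phases: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.slices_per_patient_range
        if not (0 < lo <= hi):
            raise ValueError("invalid slices_per_patient_range")
        rlo, rhi = self.tumor_radius_range
        if not (0 < rlo <= rhi):
            raise ValueError("invalid tumor_radius_range")
        if rhi >= self.image_size / 2:
            raise ValueError("tumor radius must be < image_size / 2")
        if self.phases not in (1, 2):
            raise ValueError("phases must be 1 or 2")
        if self.noise_sd < 0 or self.background_texture_scale <= 0:
            raise ValueError("invalid noise/texture settings")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")


@dataclass
class PhantomCase:
    """One generated volume with its ground truth and bookkeeping."""

    volume: CTVolume
    mask: np.ndarray  # 3D bool, aligned with volume.voxels
    tumor_slice_indices: list[int]
    slice_areas: dict[int, int]  # tumor area (voxels) per tumor-bearing slice


@dataclass
class PhantomCohort:
    params: PhantomParams
    cases: list[PhantomCase]

    @property
    def patient_ids(self) -> list[str]:
        return sorted({c.volume.patient_id for c in self.cases})


def _blob_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius_y: float,
    radius_x: float,
    wobble_amp: np.ndarray,
    wobble_phase: np.ndarray,
) -> np.ndarray:
    """Rasterize a perturbed ellipse: r(theta) = 1 + sum_k a_k cos(k theta + phi_k)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = (yy - center[0]) / max(radius_y, 1e-6)
    dx = (xx - center[1]) / max(radius_x, 1e-6)
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = np.ones_like(rho)
    for k, (a, phi) in enumerate(zip(wobble_amp, wobble_phase), start=2):
        boundary = boundary + a * np.cos(k * theta + phi)
    return rho <= boundary


def _smooth_noise(rng: np.random.Generator, shape, scale: float, sd: float) -> np.ndarray:
    raw = rng.standard_normal(shape)
    smoothed = ndimage.gaussian_filter(raw, sigma=scale)
    s = smoothed.std()
    return smoothed * (sd / s) if s > 0 else smoothed


def _patient_geometry(rng: np.random.Generator, params: PhantomParams):
    """Noiseless intensity offsets + tumor mask for one patient (shared by phases)."""
    size = params.image_size
    lo, hi = params.slices_per_patient_range
    n_slices = int(rng.integers(lo, hi + 1))

    # Body: large soft-tissue ellipse on a darker surround.
    body = _blob_mask(
        (size, size),
        (size / 2, size / 2),
        size * 0.46,
        size * 0.46,
        np.array([0.03]),
        rng.uniform(0, 2 * np.pi, 1),
    )
    base = np.full((size, size), BACKGROUND_MEAN - 700.0)
    base[body] = BACKGROUND_MEAN
    texture = _smooth_noise(
        rng, (size, size), params.background_texture_scale, BACKGROUND_TEXTURE_SD
    )
    offsets = np.repeat((base + texture)[:, :, None], n_slices, axis=2)

    # 1-3 darker organ distractors (ellipsoid cross-sections along z).
    for _ in range(int(rng.integers(1, 4))):
        cy, cx = rng.uniform(size * 0.25, size * 0.75, 2)
        cz = rng.uniform(0, n_slices)
        ry, rx = rng.uniform(size * 0.06, size * 0.16, 2)
        rz = rng.uniform(n_slices * 0.3, n_slices)
        level = rng.uniform(*DISTRACTOR_OFFSET_RANGE)
        for k in range(n_slices):
            frac = 1.0 - ((k - cz) / rz) ** 2
            if frac <= 0:
                continue
            shrink = np.sqrt(frac)
            disc = _blob_mask(
                (size, size), (cy, cx), ry * shrink, rx * shrink, np.empty(0), np.empty(0)
            )
            offsets[:, :, k][disc] += level

    # Tumor: perturbed ellipse spanning a contiguous run of slices, with the
    # in-plane radius waxing and waning along z (spherical-cap profile).
    r0 = rng.uniform(*params.tumor_radius_range)
    aspect = rng.uniform(0.8, 1.25)
    margin = r0 * 1.3 + 2
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    wobble_amp = rng.uniform(0.0, 0.12, 3)
    wobble_phase = rng.uniform(0, 2 * np.pi, 3)

    n_tumor = max(3, int(round(n_slices * rng.uniform(0.5, 0.85))))
    n_tumor = min(n_tumor, n_slices)
    z0 = int(rng.integers(0, n_slices - n_tumor + 1))
    mask = np.zeros((size, size, n_slices), dtype=bool)
    for j in range(n_tumor):
        # Waxing/waning radius; floor keeps >= 1 voxel on every tumor slice.
        prof = np.sqrt(max(np.sin(np.pi * (j + 0.5) / n_tumor), 0.0))
        ry = max(r0 * aspect * prof, 1.2)
        rx = max(r0 / aspect * prof, 1.2)
        mask[:, :, z0 + j] = _blob_mask(
            (size, size), (cy, cx), ry, rx, wobble_amp * prof, wobble_phase
        )
    offsets[mask] += params.tumor_contrast
    return offsets, mask


def _phase_transform(offsets: np.ndarray, phase_index: int) -> np.ndarray:
    if phase_index == 0:
        return offsets
    # Pseudo-nephrogenic: monotone affine remap toward a lower, flatter scale.
    return 0.8 * (offsets - BACKGROUND_MEAN) + BACKGROUND_MEAN - 300.0


def generate_cohort(params: PhantomParams) -> PhantomCohort:
    """Generate a deterministic phantom cohort from ``params.seed``.

    Each patient contributes one volume per contrast phase; phases share the
    tumor mask and geometry and differ only in the intensity transform and
    the noise realization.
    """
    root = np.random.SeedSequence([params.seed, 0x9E3779B9])
    patient_seeds = root.spawn(params.n_patients)
    phase_names = ["corticomedullary", "nephrogenic"][: params.phases]
    cases: list[PhantomCase] = []
    for i, seq in enumerate(patient_seeds):
        geom_rng = np.random.default_rng(seq)
        offsets, mask = _patient_geometry(geom_rng, params)
        tumor_idx = [int(k) for k in np.flatnonzero(mask.any(axis=(0, 1)))]
        areas = {k: int(mask[:, :, k].sum()) for k in tumor_idx}
        pid = f"P{i:04d}"
        noise_rngs = [np.random.default_rng(s) for s in seq.spawn(params.phases)]
        if params.psf_sigma > 0:
            # In-plane scanner point-spread blur: softens the tumor edge so
            # boundary voxels are genuinely ambiguous, as in real CT.
            offsets = ndimage.gaussian_filter(
                offsets, sigma=(params.psf_sigma, params.psf_sigma, 0.0)
            )
        for p, phase in enumerate(phase_names):
            vox = _phase_transform(offsets, p)
            if params.noise_sd > 0:
                vox = vox + noise_rngs[p].normal(0.0, params.noise_sd, vox.shape)
            vox = np.clip(vox, *INTENSITY_RANGE)
            volume = CTVolume(
                voxels=vox.astype(np.float32),
                spacing=(3.0, 1.0, 1.0),
                patient_id=pid,
                phase=phase if params.phases == 2 else "synthetic",
                source_path="",
            )
            cases.append(
                PhantomCase(
                    volume=volume,
                    mask=mask.copy(),
                    tumor_slice_indices=list(tumor_idx),
                    slice_areas=dict(areas),
                )
            )
    return PhantomCohort(params=params, cases=cases)


# ---------------------------------------------------------------------------
# Graded-quality prediction oracles
# ---------------------------------------------------------------------------

DEGRADE_MODES = ("erode", "dilate", "shift", "drop", "wrong_region")


def _equivalent_radius(mask: np.ndarray) -> float:
    return float(np.sqrt(mask.sum() / np.pi))


def degrade_mask(
    ref: MaskSlice, severity: float, mode: str, seed: int = 0
) -> MaskSlice:
    """Produce a predicted mask of controlled quality from a reference mask.

    ``severity`` 0 returns the reference unchanged; increasing severity
    lowers the expected Dice monotonically. ``wrong_region`` ignores
    severity and returns a blob disjoint from the reference (Dice 0), the
    gross-mislocalization failure picture.
    """
    if mode not in DEGRADE_MODES:
        raise ValueError(f"unknown degrade mode {mode!r}; choose from {DEGRADE_MODES}")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    mask = ref.mask.astype(bool)
    if mode != "wrong_region" and not mask.any():
        raise ValueError("reference mask is empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, DEGRADE_MODES.index(mode)]))

    if mode == "wrong_region":
        return replace(ref, mask=_disjoint_blob(mask, rng), origin="predicted")
    if severity == 0.0:
        return replace(ref, mask=mask.copy(), origin="predicted")

    r_eq = _equivalent_radius(mask)
    if mode == "erode":
        it = int(round(severity * max(r_eq * 0.9, 1.0)))
        out = ndimage.binary_erosion(mask, iterations=it) if it else mask.copy()
    elif mode == "dilate":
        it = int(round(severity * max(r_eq * 1.2, 1.0)))
        out = ndimage.binary_dilation(mask, iterations=it) if it else mask.copy()
    elif mode == "shift":
        mag = severity * 2.0 * r_eq
        ang = rng.uniform(0, 2 * np.pi)
        dy = int(round(mag * np.sin(ang)))
        dx = int(round(mag * np.cos(ang)))
        out = _shift_mask(mask, dy, dx)
    elif mode == "drop":
        idx = np.flatnonzero(mask.ravel())
        n_drop = int(round(severity * idx.size))
        keep = rng.permutation(idx)[n_drop:]
        out = np.zeros_like(mask).ravel()
        out[keep] = True
        out = out.reshape(mask.shape)
    return replace(ref, mask=out, origin="predicted")


def _shift_mask(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    ys = ys + dy
    xs = xs + dx
    ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    out[ys[ok], xs[ok]] = True
    return out


def _disjoint_blob(ref: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A blob of comparable size guaranteed disjoint from the reference."""
    h, w = ref.shape
    r = max(_equivalent_radius(ref), 2.0) if ref.any() else max(h * 0.08, 2.0)
    forbidden = ndimage.binary_dilation(ref, iterations=int(np.ceil(r)) + 2)
    for _ in range(200):
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if not forbidden[int(cy), int(cx)]:
            blob = _blob_mask((h, w), (cy, cx), r, r, np.empty(0), np.empty(0))
            if not (blob & ref).any():
                return blob
    # Dense reference: fall back to whatever background remains.
    blob = ~ndimage.binary_dilation(ref, iterations=1)
    return blob


def simulate_soft_prediction(
    ref: MaskSlice, quality: float, blur: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Simulate a fused ensemble probability map of controlled quality.

    ``quality`` 1 with ``blur`` 0 reproduces the reference exactly (a
    {0, 1}-valued map, foreground entropy 0). Lowering quality shifts the
    predicted region (localization error) and widens a Gaussian boundary
    blur, which simultaneously raises the average foreground entropy and
    lowers the Dice of the thresholded map — mimicking an ensemble whose
    members increasingly disagree.
    """
    if not 0.0 <= quality <= 1.0:
        raise ValueError("quality must lie in [0, 1]")
    if blur < 0:
        raise ValueError("blur must be >= 0")
    mask = ref.mask.astype(float)
    if quality == 1.0 and blur == 0.0:
        return mask
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    miss = 1.0 - quality
    r_eq = max(_equivalent_radius(ref.mask), 1.0)

    geom = ref.mask
    mag = miss * 0.8 * r_eq
    if mag > 0:
        ang = rng.uniform(0, 2 * np.pi)
        geom = _shift_mask(
            geom, int(round(mag * np.sin(ang))), int(round(mag * np.cos(ang)))
        )
    sigma = blur + miss * 3.0
    prob = geom.astype(float)
    if sigma > 0:
        prob = ndimage.gaussian_filter(prob, sigma=sigma)
        m = prob.max()
        if m > 1.0:
            prob = prob / m
    return np.clip(prob, 0.0, 1.0)


# ---------------------------------------------------------------------------
# KiTS-layout output
# ---------------------------------------------------------------------------

def write_cohort(cohort: PhantomCohort, out_dir) -> dict:
    """Write a cohort in the KiTS directory layout plus a JSON manifest.

    Each (patient, phase) volume becomes ``case_XXXXX/imaging.nii.gz`` and
    ``segmentation.nii.gz`` (tumor stored as label 2 so the clinical reader
    ingests phantoms unchanged). Returns the manifest dict; also writes it
    to ``out_dir/manifest.json``.
    """
    import json
    from pathlib import Path

    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cohort.params.seed, "image_size": cohort.params.image_size,
                "cases": []}
    for i, case in enumerate(cohort.cases):
        name = f"case_{i:05d}"
        case_dir = out_dir / name
        case_dir.mkdir(exist_ok=True)
        affine = np.eye(4)
        affine[0, 0], affine[1, 1], affine[2, 2] = 1.0, 1.0, 3.0
        nib.save(
            nib.Nifti1Image(case.volume.voxels.astype(np.float32), affine),
            str(case_dir / "imaging.nii.gz"),
        )
        seg = np.where(case.mask, 2, 0).astype(np.uint8)
        nib.save(nib.Nifti1Image(seg, affine), str(case_dir / "segmentation.nii.gz"))
        manifest["cases"].append(
            {
                "case": name,
                "patient_id": case.volume.patient_id,
                "phase": case.volume.phase,
                "n_slices": case.volume.n_slices,
                "tumor_slice_indices": case.tumor_slice_indices,
                "slice_areas": {str(k): v for k, v in case.slice_areas.items()},
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
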