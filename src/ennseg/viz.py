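"""Probability-overlay visualization of ensemble segmentations.

Renders the three panels used to present a segmentation to a radiologist:
the plain (windowed) CT slice, the voxelwise tumor-probability shading —
red at 0% probability sweeping through yellow to green at 100% — and
iso-probability contour lines at configurable thresholds, optionally with
the reference segmentation boundary drawn in purple. A JSON sidecar records
the per-slice Dice (when a reference is available), the foreground entropy,
and the calibrated confidence call (when a calibration is supplied).

Rendering is pure: identical inputs produce byte-identical PNG files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

from .confidence import ConfidenceCalibration, assess
from .ensemble import EnsemblePrediction
from .io import CTSlice, MaskSlice
from .metrics import dice as dice_score
from .metrics import foreground_entropy

__all__ = [
    "OverlayStyle",
    "RenderedPanel",
    "probability_colormap",
    "probability_overlay",
    "contour_overlay",
    "reference_overlay",
    "render_case",
    "save_panels",
]

PURPLE = (128, 0, 128)


@dataclass(frozen=True)
class OverlayStyle:
    """Appearance settings for the probability/contour overlays.

    ``floor`` suppresses shading below a small probability so the untouched
    CT remains visible outside the predicted region (set to 0.0 for literal
    every-voxel coloring). ``window`` is a (width, level) CT display window
    in stored-intensity units; None windows to the slice min/max (the
    phantom default).
    """

    alpha: float = 0.4
    floor: float = 0.05
    contour_thresholds: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9)
    reference_color: tuple[int, int, int] = PURPLE
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        th = self.contour_thresholds
        if list(th) != sorted(set(th)) or not all(0 < t < 1 for t in th):
            raise ValueError("contour thresholds must be strictly increasing in (0,1)")
        if th and self.floor >= th[0]:
            raise ValueError("floor must be below the smallest contour threshold")


@dataclass
class RenderedPanel:
    """An RGB rendering plus the metadata needed for a legend."""

    rgb: np.ndarray  # (H, W, 3) uint8
    legend: dict = field(default_factory=dict)

    def copy(self) -> "RenderedPanel":
        return RenderedPanel(rgb=self.rgb.copy(), legend=dict(self.legend))


def probability_colormap(p: np.ndarray) -> np.ndarray:
    """Monotone red -> yellow -> green colormap, linear in probability.

    Red channel non-increasing and green non-decreasing in p; the sweep
    through yellow keeps mid probabilities visually distinct from both ends.
    Returns float RGB in [0, 1] with shape p.shape + (3,).
    """
    p = np.asarray(p, dtype=np.float64)
    r = np.clip(2.0 * (1.0 - p), 0.0, 1.0)
    g = np.clip(2.0 * p, 0.0, 1.0)
    return np.stack([r, g, np.zeros_like(p)], axis=-1)


def _windowed_base(pixels: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    x = np.asarray(pixels, dtype=np.float64)
    if window is None:
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            hi = lo + 1.0
    else:
        width, level = window
        lo, hi = level - width / 2.0, level + width / 2.0
    gray = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return np.repeat(gray[:, :, None], 3, axis=2)


def probability_overlay(
    ct_slice: CTSlice, prob: np.ndarray, style: OverlayStyle = OverlayStyle()
) -> RenderedPanel:
    """Alpha-blend the probability colormap onto the windowed CT slice.

    Pixels with probability below ``style.floor`` are left untouched.
    """
    prob = np.asarray(prob, dtype=np.float64)
    if prob.shape != ct_slice.pixels.shape:
        raise ValueError("probability map must match the slice shape")
    base = _windowed_base(ct_slice.pixels, style.window)
    colors = probability_colormap(prob)
    shade = prob >= style.floor
    out = base.copy()
    out[shade] = (1.0 - style.alpha) * base[shade] + style.alpha * colors[shade]
    rgb = np.rint(out * 255.0).astype(np.uint8)
    return RenderedPanel(
        rgb=rgb,
        legend={
            "kind": "probability",
            "alpha": style.alpha,
            "floor": style.floor,
            "patient_id": ct_slice.patient_id,
            "slice_index": ct_slice.slice_index,
        },
    )


def _draw_contour_points(rgb: np.ndarray, contour: np.ndarray, color) -> None:
    h, w = rgb.shape[:2]
    # find_contours yields densely sampled fractional (row, col) points;
    # rasterizing each segment start keeps the line one pixel wide.
    prev = None
    for point in contour:
        r, c = int(round(point[0])), int(round(point[1]))
        r, c = min(max(r, 0), h - 1), min(max(c, 0), w - 1)
        if prev is not None:
            rr = np.linspace(prev[0], r, max(abs(r - prev[0]), abs(c - prev[1])) + 1)
            cc = np.linspace(prev[1], c, rr.size)
            rgb[np.rint(rr).astype(int), np.rint(cc).astype(int)] = color
        rgb[r, c] = color
        prev = (r, c)


def contour_overlay(
    panel: RenderedPanel, prob: np.ndarray, style: OverlayStyle = OverlayStyle()
) -> RenderedPanel:
    """Draw iso-probability contour lines at each style threshold.

    Each threshold is rendered in its own colormap color (marching-squares
    level sets, one pixel wide). Thresholds above the map maximum simply
    draw nothing.
    """
    prob = np.asarray(prob, dtype=np.float64)
    if prob.shape != panel.rgb.shape[:2]:
        raise ValueError("probability map must match the panel shape")
    out = panel.copy()
    drawn = []
    for t in style.contour_thresholds:
        color = np.rint(probability_colormap(np.array(t)) * 255.0).astype(np.uint8)
        contours = measure.find_contours(prob, t)
        if contours:
            drawn.append(t)
        for contour in contours:
            _draw_contour_points(out.rgb, contour, color)
    out.legend["contour_thresholds_drawn"] = drawn
    return out


def _boundary(mask: np.ndarray) -> np.ndarray:
    mask = mask.astype(bool)
    return mask & ~ndimage.binary_erosion(mask)


def reference_overlay(
    panel: RenderedPanel, ref: MaskSlice, style: OverlayStyle = OverlayStyle()
) -> RenderedPanel:
    """Draw the reference-mask boundary in purple over the panel."""
    if ref.mask.shape != panel.rgb.shape[:2]:
        raise ValueError("reference mask must match the panel shape")
    out = panel.copy()
    edge = _boundary(ref.mask)
    out.rgb[edge] = style.reference_color
    out.legend["reference_drawn"] = bool(edge.any())
    return out


def render_case(
    ct_slice: CTSlice,
    pred: EnsemblePrediction,
    ref: MaskSlice | None = None,
    cal: ConfidenceCalibration | None = None,
    style: OverlayStyle = OverlayStyle(),
) -> tuple[dict[str, RenderedPanel], dict]:
    """Render the full panel set for one slice plus its JSON-able sidecar.

    Panels: 'ct' (plain windowed slice), 'probability' (shaded overlay),
    'contour' (probability overlay plus contour lines and, when available,
    the purple reference boundary). The sidecar always carries the
    foreground entropy; Dice is added when a reference is given and the
    confidence call when a calibration is given.
    """
    base = RenderedPanel(
        rgb=np.rint(_windowed_base(ct_slice.pixels, style.window) * 255.0).astype(
            np.uint8
        ),
        legend={"kind": "ct", "slice_index": ct_slice.slice_index},
    )
    prob_panel = probability_overlay(ct_slice, pred.fused_prob, style)
    contour_panel = contour_overlay(prob_panel, pred.fused_prob, style)
    if ref is not None:
        contour_panel = reference_overlay(contour_panel, ref, style)

    entropy, empty = foreground_entropy(pred.fused_prob, pred.binary_mask)
    sidecar: dict = {
        "patient_id": ct_slice.patient_id,
        "slice_index": ct_slice.slice_index,
        "phase": ct_slice.phase,
        "fg_entropy": entropy,
        "empty_foreground": empty,
    }
    if ref is not None:
        sidecar["dice"] = dice_score(pred.binary_mask, ref.mask)
    if cal is not None:
        sidecar["predicted_success"] = bool(assess(entropy, cal).predicted_success)
        sidecar["entropy_cutoff"] = cal.entropy_cutoff
    panels = {"ct": base, "probability": prob_panel, "contour": contour_panel}
    return panels, sidecar


def save_panels(
    panels: dict[str, RenderedPanel], sidecar: dict, out_dir: "str | Path", stem: str
) -> list[Path]:
    """Write panels as PNG plus the sidecar JSON; returns written paths.

    PNG encoding carries no timestamps, so reruns with identical inputs are
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, panel in panels.items():
        path = out_dir / f"{stem}_{name}.png"
        Image.fromarray(panel.rgb).save(path, format="PNG")
        written.append(path)
    sidecar_path = out_dir / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    written.append(sidecar_path)
    return written
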