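"""Render the probability-overlay panels for one phantom slice.

Simulates a mid-quality soft prediction, then writes the three panels a
reader would see: the plain slice, the red-to-green probability shading,
and the contour panel with iso-probability lines plus the purple reference
boundary. The JSON sidecar records Dice and foreground entropy.
"""

import json
from pathlib import Path

from ennseg.ensemble import fuse
from ennseg.io import CTSlice, MaskSlice
from ennseg.phantom import PhantomParams, generate_cohort, simulate_soft_prediction
from ennseg.viz import OverlayStyle, render_case, save_panels

cohort = generate_cohort(PhantomParams(n_patients=2, phases=1, seed=5))
case = cohort.cases[0]
k = max(case.slice_areas, key=case.slice_areas.get)  # widest tumor slice

ct_slice = CTSlice(pixels=case.volume.voxels[:, :, k], slice_index=k,
                   patient_id=case.volume.patient_id)
ref = MaskSlice(mask=case.mask[:, :, k], slice_index=k,
                patient_id=case.volume.patient_id)
prob = simulate_soft_prediction(ref, quality=0.7, seed=3)
pred = fuse([prob], patient_id=ct_slice.patient_id, slice_index=k)

out_dir = Path("scratch/overlay_demo")
panels, sidecar = render_case(ct_slice, pred, ref=ref, style=OverlayStyle())
written = save_panels(panels, sidecar, out_dir, f"{ct_slice.patient_id}_s{k:03d}")

print("wrote:")
for p in written:
    print(" ", p)
print("\nsidecar:", json.dumps({k: v for k, v in sidecar.items()}, indent=2))
print("\nGreen regions are voxels the ensemble is sure about; red-to-yellow "
      "fringes mark disagreement, and the purple line is the reference.")
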