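"""Segment FLAIR-hyperintense lesions and compute the ICV-corrected load.

Lesions are thresholded at median + 3 robust SDs of the white-matter
intensities, small components are removed, and NAWM excludes a one-voxel
ring around the lesions.  At a contrast of 5 noise SDs the segmentation is
near-perfect (Dice > 0.9 against the ground truth).
"""

import numpy as np

from gratiokit import (
    LesionSphere,
    PhantomSpec,
    derive_nawm,
    lesion_volume_pct_icv,
    make_ground_truth,
    segment_lesions,
    simulate_flair,
)

spec = PhantomSpec(grid_shape=(24, 24, 12), lesions=[LesionSphere((12.0, 12.0, 6.0), 3.5)])
gt, masks = make_ground_truth(spec)
flair = simulate_flair(gt, masks, contrast=5.0, seed=3)

wml = segment_lesions(flair, masks.wm, z_threshold=3.0)
nawm = derive_nawm(masks.wm, wml, exclusion_dilation=1)
dice = 2 * np.sum(wml & masks.wml) / (wml.sum() + masks.wml.sum())
load = lesion_volume_pct_icv(wml, masks.icv, spec.voxel_size_mm)

print(f"true lesion voxels: {masks.wml.sum()}, segmented: {wml.sum()}, Dice: {dice:.3f}")
print(f"lesion load: {load:.2f}% of ICV "
      f"(the clinical stratification boundary in this analysis is 0.5%)")
print(f"NAWM voxels after 1-voxel exclusion ring: {nawm.sum()} of {masks.wm.sum()} WM voxels")
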