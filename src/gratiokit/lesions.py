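"""Lesion masking: FLAIR-intensity thresholding, NAWM derivation, lesion load.

Lesions are taken as the FLAIR-hyperintense white-matter voxels.  The
threshold statistics are robust — median and MAD-derived SD of the in-WM
intensities — because lesion voxels would contaminate moment-based
estimates.  Small connected components (default < 3 voxels under
26-connectivity) are removed as noise; NAWM is white matter minus a dilated
lesion mask so partial-volume lesion rims do not leak into the NAWM summary.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import SignalVolume

__all__ = ["segment_lesions", "derive_nawm", "lesion_volume_pct_icv"]

# normal-consistent MAD scale factor
_MAD_TO_SD = 1.4826
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def segment_lesions(
    flair: SignalVolume,
    wm_mask: np.ndarray,
    z_threshold: float = 3.0,
    min_component_voxels: int = 3,
) -> np.ndarray:
    """Threshold-based lesion segmentation within white matter.

    A voxel is lesional when its FLAIR intensity exceeds
    ``median + z_threshold * 1.4826 * MAD`` of the in-WM intensities, and it
    belongs to a 26-connected component of at least ``min_component_voxels``.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not wm_mask.any():
        raise ValueError("white-matter mask is empty")
    vals = flair.data[wm_mask]
    centre = np.median(vals)
    scale = _MAD_TO_SD * np.median(np.abs(vals - centre))
    thr = centre + z_threshold * scale
    wml = wm_mask & (flair.data > thr)
    if wml.sum() == wm_mask.sum():
        raise ValueError("degenerate contrast: every WM voxel is above the lesion threshold")
    if min_component_voxels > 1 and wml.any():
        labels, n = ndimage.label(wml, structure=_STRUCT_26)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_component_voxels
        keep[0] = False
        wml = keep[labels]
    return wml


def derive_nawm(
    wm_mask: np.ndarray, wml_mask: np.ndarray, exclusion_dilation: int = 1
) -> np.ndarray:
    """NAWM = WM minus the lesion mask dilated by ``exclusion_dilation`` voxels."""
    wm_mask = np.asarray(wm_mask, dtype=bool)
    wml_mask = np.asarray(wml_mask, dtype=bool)
    if np.any(wml_mask & ~wm_mask):
        raise ValueError("wml mask extends outside wm")
    if exclusion_dilation < 0:
        raise ValueError("exclusion_dilation must be >= 0")
    excluded = wml_mask
    if exclusion_dilation > 0 and wml_mask.any():
        excluded = ndimage.binary_dilation(
            wml_mask, structure=_STRUCT_26, iterations=exclusion_dilation
        )
    nawm = wm_mask & ~excluded
    if not nawm.any():
        raise ValueError("NAWM is empty after lesion exclusion")
    return nawm


def lesion_volume_pct_icv(
    wml_mask: np.ndarray,
    icv_mask: np.ndarray,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Lesion load as a percentage of intracranial volume.

    Voxel volumes cancel on a shared grid but are kept in the formula so
    masks resampled to different grids stay comparable.
    """
    icv_mask = np.asarray(icv_mask, dtype=bool)
    wml_mask = np.asarray(wml_mask, dtype=bool)
    if not icv_mask.any():
        raise ValueError("ICV mask is empty")
    vox_vol = float(np.prod(voxel_size_mm))
    return 100.0 * (wml_mask.sum() * vox_vol) / (icv_mask.sum() * vox_vol)
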