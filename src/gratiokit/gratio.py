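"""Aggregate g-ratio mapping: k calibration, MVF/AVF maps, regional summaries.

The aggregate g-ratio of a voxel is

    g = (1 + MVF / AVF)^(-1/2)

with the myelin volume fraction a linear scaling of MT saturation,
MVF = k * delta_app, and the axonal volume fraction derived from the NODDI
signal fractions, AVF = (1 - MVF)(1 - viso) * vic.  The constant k is
calibrated on healthy-control data so that the pooled control NAWM median
hits a chosen anchor — either a target median MVF or a target median g.
Higher g means thinner myelin relative to axon calibre; demyelinating
lesions push g up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GRatioMaps",
    "RegionalSummary",
    "calibrate_k",
    "compute_mvf",
    "compute_avf",
    "compute_gratio",
    "regional_summary",
    "DEFAULT_BIN_EDGES",
]

MVF_CEIL = 1.0 - 1e-6
AVF_FLOOR = 1e-3
#: shared histogram support so lesion and NAWM histograms are comparable
DEFAULT_BIN_EDGES = np.linspace(0.40, 0.80, 81)


@dataclass
class GRatioMaps:
    mvf: np.ndarray
    avf: np.ndarray
    g: np.ndarray
    validity: np.ndarray
    n_clipped: int = 0


@dataclass
class RegionalSummary:
    region: str
    median_g: float
    iqr: tuple[float, float]
    n_voxels: int
    bin_edges: np.ndarray
    counts: np.ndarray


def _pool(maps: list[np.ndarray], masks: list[np.ndarray]) -> np.ndarray:
    if len(maps) != len(masks) or not maps:
        raise ValueError("need one mask per control map, at least one control")
    vals = np.concatenate([np.asarray(m)[np.asarray(mk, dtype=bool)] for m, mk in zip(maps, masks)])
    if vals.size == 0:
        raise ValueError("pooled control mask is empty")
    return vals


def calibrate_k(
    control_delta_app: list[np.ndarray],
    control_nawm_masks: list[np.ndarray],
    target_median_mvf: float | None = None,
    target_median_g: float | None = None,
    control_viso: list[np.ndarray] | None = None,
    control_vic: list[np.ndarray] | None = None,
) -> float:
    """Calibrate the MTsat-to-MVF constant k on pooled control NAWM voxels.

    Exactly one target must be given.  With ``target_median_mvf``, k is the
    direct ratio target / median(delta_app).  With ``target_median_g``, k is
    found by root bracketing so that the pooled median of
    g(k * delta, viso, vic) equals the target (g is strictly decreasing in
    k, so the root is unique).
    """
    if (target_median_mvf is None) == (target_median_g is None):
        raise ValueError("specify exactly one of target_median_mvf / target_median_g")
    delta = _pool(control_delta_app, control_nawm_masks)

    if target_median_mvf is not None:
        if not 0.0 < target_median_mvf < 1.0:
            raise ValueError("target median MVF must be in (0, 1)")
        med = float(np.median(delta))
        if med <= 0:
            raise ValueError("non-positive pooled median delta_app; cannot calibrate")
        return target_median_mvf / med

    if control_viso is None or control_vic is None:
        raise ValueError("g-target calibration needs control viso and vic maps")
    viso = _pool(control_viso, control_nawm_masks)
    vic = _pool(control_vic, control_nawm_masks)
    if not 0.0 < target_median_g < 1.0:
        raise ValueError("target median g must be in (0, 1)")

    def median_g_minus_target(k: float) -> float:
        mvf = np.clip(k * delta, 0.0, MVF_CEIL)
        avf = (1.0 - mvf) * (1.0 - viso) * vic
        with np.errstate(divide="ignore"):
            g = np.where(avf > AVF_FLOOR, (1.0 + mvf / np.where(avf > 0, avf, 1.0)) ** -0.5, 0.0)
        return float(np.median(g[avf > AVF_FLOOR])) - target_median_g

    k_hi = MVF_CEIL / float(np.max(delta))
    lo, hi = 1e-9, k_hi
    f_lo, f_hi = median_g_minus_target(lo), median_g_minus_target(hi)
    if f_lo < 0:
        raise ValueError("target median g unattainable: even k~0 gives a lower median g")
    if f_hi > 0:
        raise ValueError("target median g unattainable within MVF < 1")
    return float(brentq(median_g_minus_target, lo, hi, xtol=1e-12, rtol=1e-14))


def compute_mvf(
    delta_app: np.ndarray,
    k: float,
    mask: np.ndarray | None = None,
    strict: bool = False,
) -> tuple[np.ndarray, int]:
    """MVF = k * delta_app, clipped to [0, 1).  Returns ``(mvf, n_clipped)``.

    Clipping is counted over the mask; if more than 5% of in-mask voxels
    clip, a warning is raised (an error under ``strict``).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    delta_app = np.asarray(delta_app, dtype=float)
    if mask is None:
        mask = np.ones(delta_app.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    raw = k * delta_app
    mvf = np.clip(raw, 0.0, MVF_CEIL)
    clipped = mask & ((raw < 0.0) | (raw > MVF_CEIL))
    n_clipped = int(clipped.sum())
    n_mask = int(mask.sum())
    if n_mask and n_clipped / n_mask > 0.05:
        msg = f"{n_clipped}/{n_mask} in-mask voxels clipped by the MVF bounds"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return mvf, n_clipped


def compute_avf(mvf: np.ndarray, viso: np.ndarray, vic: np.ndarray) -> np.ndarray:
    """AVF = (1 - MVF)(1 - viso) vic."""
    mvf, viso, vic = (np.asarray(a, dtype=float) for a in (mvf, viso, vic))
    if not mvf.shape == viso.shape == vic.shape:
        raise ValueError("mvf/viso/vic grids differ")
    return (1.0 - mvf) * (1.0 - viso) * vic


def compute_gratio(
    mvf: np.ndarray, avf: np.ndarray, avf_floor: float = AVF_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """g = (1 + MVF/AVF)^(-1/2); voxels with AVF <= floor are flagged invalid."""
    mvf = np.asarray(mvf, dtype=float)
    avf = np.asarray(avf, dtype=float)
    valid = (avf > avf_floor) & (mvf >= 0.0) & np.isfinite(mvf) & np.isfinite(avf)
    safe_avf = np.where(valid, avf, 1.0)
    g = np.where(valid, (1.0 + mvf / safe_avf) ** -0.5, 0.0)
    return g, valid


def regional_summary(
    g: np.ndarray,
    validity: np.ndarray,
    mask: np.ndarray,
    region: str,
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
) -> RegionalSummary:
    """Median, IQR and fixed-support histogram of g over valid in-region voxels."""
    sel = np.asarray(mask, dtype=bool) & np.asarray(validity, dtype=bool)
    vals = np.asarray(g, dtype=float)[sel]
    if vals.size == 0:
        raise ValueError(f"region {region!r}: no valid voxels in mask")
    counts, edges = np.histogram(vals, bins=np.asarray(bin_edges, dtype=float))
    q1, q3 = np.percentile(vals, [25.0, 75.0])
    return RegionalSummary(
        region=region,
        median_g=float(np.median(vals)),
        iqr=(float(q1), float(q3)),
        n_voxels=int(vals.size),
        bin_edges=edges,
        counts=counts,
    )
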