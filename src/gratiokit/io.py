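"""File formats: NIfTI-1 volumes, FSL-dialect bval/bvec, cohort CSV, JSON config."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS
from .protocol import AcquisitionProtocol, SpgrSettings
from .volume import SignalVolume

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_mask",
    "load_mask",
    "save_bvals_bvecs",
    "load_bvals_bvecs",
    "save_cohort_csv",
    "load_cohort_csv",
    "protocol_to_json",
    "protocol_from_json",
]


def save_nifti(vol: SignalVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.voxel_size_mm + ((1.0,) if vol.data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> SignalVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return SignalVolume(
        np.asarray(img.get_fdata(), dtype=float),
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine),
    )


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def save_bvals_bvecs(
    bvals: np.ndarray, bvecs: np.ndarray, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """FSL dialect: bvals on one row; bvecs as three rows (x, y, z components)."""
    np.savetxt(bval_path, np.asarray(bvals)[None, :], fmt="%.6g")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.8f")


def load_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(f"bvec shape {bvecs.shape} inconsistent with {bvals.size} b-values")
    return bvals, bvecs


def save_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def protocol_to_json(protocol: AcquisitionProtocol, path: str | Path) -> None:
    payload = {
        "spgr": {
            name: {
                "flip_angle_deg": float(np.rad2deg(s.flip_angle_rad)),
                "tr_s": s.tr_s,
            }
            for name, s in (("pdw", protocol.pdw), ("t1w", protocol.t1w), ("mtw", protocol.mtw))
        },
        "diffusion": {
            "bvals": protocol.bvals.tolist(),
            "bvecs": protocol.bvecs.tolist(),
            "d_parallel": protocol.d_parallel,
            "d_iso": protocol.d_iso,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def protocol_from_json(path: str | Path) -> AcquisitionProtocol:
    payload = json.loads(Path(path).read_text())
    spgr = {
        name: SpgrSettings.from_degrees(s["flip_angle_deg"], s["tr_s"])
        for name, s in payload["spgr"].items()
    }
    d = payload["diffusion"]
    return AcquisitionProtocol(
        pdw=spgr["pdw"],
        t1w=spgr["t1w"],
        mtw=spgr["mtw"],
        bvals=np.asarray(d["bvals"]),
        bvecs=np.asarray(d["bvecs"]),
        d_parallel=d.get("d_parallel", 1.7e-3),
        d_iso=d.get("d_iso", 3.0e-3),
    )
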