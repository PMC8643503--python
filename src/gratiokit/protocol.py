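"""Acquisition protocol: SPGR triplet settings and the diffusion gradient table.

Flip angles are stored in radians internally; every user-facing constructor
takes degrees (the classic unit bug lives here, so the boundary is explicit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpgrSettings",
    "AcquisitionProtocol",
    "default_protocol",
    "two_shell_table",
    "fibonacci_directions",
]

# Canonical NODDI diffusivities (mm^2/s); the tortuosity closure ties the
# extra-neurite perpendicular diffusivity to these.
D_PARALLEL = 1.7e-3
D_ISO = 3.0e-3


@dataclass(frozen=True)
class SpgrSettings:
    """One spoiled-gradient-echo acquisition: flip angle (rad) and TR (s)."""

    flip_angle_rad: float
    tr_s: float

    def __post_init__(self) -> None:
        if not 0.0 < self.flip_angle_rad <= np.pi / 2:
            raise ValueError(f"flip angle must be in (0, pi/2], got {self.flip_angle_rad}")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")

    @classmethod
    def from_degrees(cls, flip_angle_deg: float, tr_s: float) -> "SpgrSettings":
        return cls(float(np.deg2rad(flip_angle_deg)), float(tr_s))


def fibonacci_directions(n: int, hemisphere: bool = True) -> np.ndarray:
    """Deterministic, roughly uniform unit directions via the Fibonacci lattice."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n) + 0.5
    # restrict z to [0, 1) for a hemisphere (diffusion is antipodally symmetric)
    z = i / n if hemisphere else 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def two_shell_table(
    bvalues: tuple[float, float] = (700.0, 2000.0),
    n_dirs_per_shell: int = 32,
    n_b0: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """b-value vector (s/mm^2) and matching unit-direction rows for a 2-shell scheme."""
    dirs = fibonacci_directions(n_dirs_per_shell)
    bvals = np.concatenate([np.zeros(n_b0), *(np.full(n_dirs_per_shell, b) for b in bvalues)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), *([dirs] * len(bvalues))])
    return bvals, bvecs


@dataclass
class AcquisitionProtocol:
    """SPGR triplet settings plus a multi-shell diffusion gradient table.

    ``bvecs`` rows must be unit vectors where ``bvals > 0``; b=0 rows may be
    zero (the FSL convention).
    """

    pdw: SpgrSettings
    t1w: SpgrSettings
    mtw: SpgrSettings
    bvals: np.ndarray
    bvecs: np.ndarray
    d_parallel: float = D_PARALLEL
    d_iso: float = D_ISO

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvals.ndim != 1:
            raise ValueError("bvals must be 1-D")
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError(
                f"bvecs shape {self.bvecs.shape} does not match {self.bvals.size} b-values"
            )
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value in gradient table")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        if self.d_parallel <= 0 or self.d_iso <= 0:
            raise ValueError("diffusivities must be positive")

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.bvals[self.bvals > 0])


def default_protocol(
    n_dirs_per_shell: int = 32,
    bvalues: tuple[float, float] = (700.0, 2000.0),
    n_b0: int = 4,
) -> AcquisitionProtocol:
    """Conventional MT-SPGR triplet (PDw 6°, T1w 21°, MTw 6°, TR 25 ms) with a
    two-shell b=700/2000 s/mm^2 diffusion scheme."""
    bvals, bvecs = two_shell_table(bvalues, n_dirs_per_shell, n_b0)
    return AcquisitionProtocol(
        pdw=SpgrSettings.from_degrees(6.0, 0.025),
        t1w=SpgrSettings.from_degrees(21.0, 0.025),
        mtw=SpgrSettings.from_degrees(6.0, 0.025),
        bvals=bvals,
        bvecs=bvecs,
    )
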