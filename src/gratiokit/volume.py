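"""Core spatial containers: signal volumes on a common grid and region masks.

Everything downstream of the simulator works on plain :class:`numpy.ndarray`
data wrapped with voxel geometry.  Volumes are 3-D scalar images or 4-D
series (last axis = acquisition entry); masks are boolean 3-D arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SignalVolume", "RegionMasks", "default_affine"]


def default_affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    """Diagonal RAS affine for a grid with the given voxel spacing (mm)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class SignalVolume:
    """A 3-D scalar map or 4-D signal series with voxel geometry.

    Parameters
    ----------
    data
        Non-negative, finite array; 3-D ``(nx, ny, nz)`` or 4-D
        ``(nx, ny, nz, nvol)``.
    voxel_size_mm
        Voxel edge lengths in millimetres.
    affine
        4x4 voxel-to-world matrix (NIfTI convention).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3-D or 4-D data, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal volume contains non-finite values")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    def with_data(self, data: np.ndarray) -> "SignalVolume":
        """New volume sharing this volume's geometry."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class RegionMasks:
    """Boolean region masks on a shared grid.

    Invariants enforced at construction: ``wml ⊆ wm ⊆ icv`` and
    ``nawm = wm ∖ wml`` at minimum disjoint from ``wml``.
    """

    icv: np.ndarray
    wm: np.ndarray
    wml: np.ndarray
    nawm: np.ndarray

    def __post_init__(self) -> None:
        for name in ("icv", "wm", "wml", "nawm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        shapes = {getattr(self, n).shape for n in ("icv", "wm", "wml", "nawm")}
        if len(shapes) != 1:
            raise ValueError(f"mask grids differ: {shapes}")
        if np.any(self.wm & ~self.icv):
            raise ValueError("wm mask extends outside icv")
        if np.any(self.wml & ~self.wm):
            raise ValueError("wml mask extends outside wm")
        if np.any(self.nawm & ~self.wm):
            raise ValueError("nawm mask extends outside wm")
        if np.any(self.nawm & self.wml):
            raise ValueError("nawm and wml masks overlap")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.icv.shape)
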