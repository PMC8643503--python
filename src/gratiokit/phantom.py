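"""Digital phantom: ground-truth tissue maps and forward-simulated acquisitions.

The phantom carries voxel-wise true values of every quantity the pipeline
later estimates — MT saturation (delta_app), NODDI signal fractions (viso,
vic), orientation dispersion, fibre direction, R1 and signal amplitude —
plus the linear MTsat-to-MVF constant k.  From these it forward-simulates

* the SPGR triplet (PD-, T1- and MT-weighted) through the full steady-state
  signal equation, with the MT pulse entering as a per-TR (1 - delta)
  saturation of longitudinal magnetisation,
* the two-shell diffusion series through the three-compartment
  Watson-stick / tortuosity-zeppelin / free-water model, and
* a FLAIR-like volume in which lesions are hyperintense by a configurable
  contrast-to-noise ratio.

Geometry is deliberately simple: an ellipsoidal intracranial volume, an
inner ellipsoidal white-matter region, and spherical lesions inside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .protocol import AcquisitionProtocol, SpgrSettings
from .volume import RegionMasks, SignalVolume, default_affine
from .watson import kappa_from_odi, watson_stick_attenuation

__all__ = [
    "TissuePreset",
    "LesionSphere",
    "PhantomSpec",
    "GroundTruthMaps",
    "make_ground_truth",
    "spgr_signal",
    "simulate_spgr",
    "noddi_attenuation",
    "simulate_dwi",
    "add_rician_noise",
    "simulate_flair",
    "true_gratio",
]


@dataclass(frozen=True)
class TissuePreset:
    """True tissue parameters for one phantom compartment.

    ``delta_app`` is the per-excitation MT saturation (dimensionless, a few
    per cent in white matter); ``viso``/``vic`` are the NODDI isotropic and
    intra-neurite signal fractions; ``odi`` the orientation dispersion
    index; ``r1_s`` the longitudinal rate (1/s) and ``amplitude`` the
    equilibrium signal.
    """

    delta_app: float
    viso: float
    vic: float
    odi: float
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    r1_s: float = 1.0
    amplitude: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("viso", "vic", "odi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.r1_s <= 0 or self.amplitude <= 0:
            raise ValueError("r1_s and amplitude must be positive")
        n = math.sqrt(sum(c * c for c in self.direction))
        if not math.isclose(n, 1.0, rel_tol=1e-6):
            object.__setattr__(self, "direction", tuple(c / n for c in self.direction))


@dataclass(frozen=True)
class LesionSphere:
    """Spherical lesion: centre in voxel coordinates, radius in voxels."""

    centre_vox: tuple[float, float, float]
    radius_vox: float

    def __post_init__(self) -> None:
        if self.radius_vox <= 0:
            raise ValueError("lesion radius must be positive")


# Default tissue values.  NAWM and lesion presets carry the ground truth of
# the acceptance phantom: with k = 10, NAWM MVF = 0.415 / lesion MVF = 0.3375,
# and both imply AVF = 0.20, hence true aggregate g of 0.570 (NAWM) and
# 0.610 (lesion) — lower MT saturation in lesions means thinner myelin and a
# higher g-ratio, the direction of effect seen in demyelinating disease.
NAWM_PRESET = TissuePreset(
    delta_app=0.0415, viso=0.05, vic=0.3419 / 0.95, odi=0.20, r1_s=1.1, amplitude=1000.0
)
LESION_PRESET = TissuePreset(
    delta_app=0.03375, viso=0.15, vic=0.3552, odi=0.30, r1_s=0.85, amplitude=1000.0
)
BACKGROUND_PRESET = TissuePreset(
    delta_app=0.015, viso=0.60, vic=0.25, odi=0.80, r1_s=0.70, amplitude=900.0
)


def _default_lesions() -> list[LesionSphere]:
    return [
        LesionSphere((12.0, 16.0, 8.0), 4.0),
        LesionSphere((20.0, 12.0, 8.0), 3.0),
        LesionSphere((18.0, 21.0, 7.0), 3.0),
    ]


@dataclass
class PhantomSpec:
    """Complete description of a synthetic subject."""

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background: TissuePreset = BACKGROUND_PRESET
    nawm: TissuePreset = NAWM_PRESET
    lesion: TissuePreset = LESION_PRESET
    lesions: list[LesionSphere] = field(default_factory=_default_lesions)
    k_true: float = 10.0
    snr: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.k_true <= 0:
            raise ValueError("k_true must be positive")
        if not self.snr > 0:
            raise ValueError("snr must be positive (may be inf)")
        for preset in (self.background, self.nawm, self.lesion):
            if not 0.0 <= self.k_true * preset.delta_app < 1.0:
                raise ValueError("implied true MVF = k_true * delta_app must lie in [0, 1)")

    def control(self) -> "PhantomSpec":
        """The matched healthy-control phantom: same geometry, no lesions."""
        return PhantomSpec(
            grid_shape=self.grid_shape,
            voxel_size_mm=self.voxel_size_mm,
            background=self.background,
            nawm=self.nawm,
            lesion=self.lesion,
            lesions=[],
            k_true=self.k_true,
            snr=self.snr,
            seed=self.seed + 1,
        )


@dataclass
class GroundTruthMaps:
    """Voxel-wise true tissue parameters on the phantom grid."""

    delta_app: np.ndarray
    viso: np.ndarray
    vic: np.ndarray
    odi: np.ndarray
    direction: np.ndarray  # (..., 3) unit vectors
    r1_true: np.ndarray
    a_true: np.ndarray
    k_true: float
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.delta_app.shape)

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_size_mm)


def _ellipsoid_mask(shape: tuple[int, int, int], semi_axes: tuple[float, float, float]) -> np.ndarray:
    centre = [(s - 1) / 2.0 for s in shape]
    idx = np.indices(shape, dtype=float)
    q = sum(((idx[i] - centre[i]) / semi_axes[i]) ** 2 for i in range(3))
    return q <= 1.0


def _sphere_mask(shape: tuple[int, int, int], centre, radius: float) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d2 = sum((idx[i] - centre[i]) ** 2 for i in range(3))
    return d2 <= radius**2


def make_ground_truth(spec: PhantomSpec) -> tuple[GroundTruthMaps, RegionMasks]:
    """Build tissue-parameter maps and region masks from a phantom spec.

    The ICV is an ellipsoid covering ~90% of each grid axis, the WM an inner
    ellipsoid at ~70%, lesions are voxelised spheres (centre distance
    <= radius).  Raises if any lesion voxel falls outside the WM region.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    icv = _ellipsoid_mask(shape, tuple(0.45 * s for s in shape))
    wm = _ellipsoid_mask(shape, tuple(0.35 * s for s in shape))
    wm &= icv

    wml = np.zeros(shape, dtype=bool)
    for i, lesion in enumerate(spec.lesions):
        sph = _sphere_mask(shape, lesion.centre_vox, lesion.radius_vox)
        if np.any(sph & ~wm):
            raise ValueError(f"lesion {i} extends outside the white-matter region")
        wml |= sph
    nawm = wm & ~wml
    masks = RegionMasks(icv=icv, wm=wm, wml=wml, nawm=nawm)

    def paint(attr: str) -> np.ndarray:
        out = np.zeros(shape, dtype=float)
        out[icv] = getattr(spec.background, attr)
        out[nawm] = getattr(spec.nawm, attr)
        out[wml] = getattr(spec.lesion, attr)
        return out

    direction = np.zeros(shape + (3,), dtype=float)
    direction[icv] = spec.background.direction
    direction[nawm] = spec.nawm.direction
    direction[wml] = spec.lesion.direction
    # outside the head there is no fibre; keep a unit placeholder
    direction[~icv] = (0.0, 0.0, 1.0)

    gt = GroundTruthMaps(
        delta_app=paint("delta_app"),
        viso=paint("viso"),
        vic=paint("vic"),
        odi=paint("odi"),
        direction=direction,
        r1_true=np.where(icv, paint("r1_s"), 1.0),
        a_true=np.where(icv, paint("amplitude"), 0.0),
        k_true=spec.k_true,
        voxel_size_mm=spec.voxel_size_mm,
    )
    return gt, masks


def spgr_signal(
    a: np.ndarray | float,
    r1: np.ndarray | float,
    settings: SpgrSettings,
    delta_app: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Steady-state spoiled gradient-echo signal.

    S = A sin(alpha) (1 - E) / (1 - (1 - delta) cos(alpha) E),  E = exp(-TR R1).

    The MT pulse saturates longitudinal magnetisation by the factor
    (1 - delta) once per TR; delta = 0 recovers the plain SPGR signal.
    """
    alpha, tr = settings.flip_angle_rad, settings.tr_s
    if np.any(np.isclose(alpha, 0.0)):
        raise ValueError("zero flip angle produces zero signal")
    e = np.exp(-tr * np.asarray(r1, dtype=float))
    return np.asarray(a, dtype=float) * np.sin(alpha) * (1.0 - e) / (
        1.0 - (1.0 - np.asarray(delta_app, dtype=float)) * np.cos(alpha) * e
    )


def simulate_spgr(
    gt: GroundTruthMaps, protocol: AcquisitionProtocol
) -> tuple[SignalVolume, SignalVolume, SignalVolume]:
    """Noiseless PD-, T1- and MT-weighted steady-state volumes."""
    pdw = spgr_signal(gt.a_true, gt.r1_true, protocol.pdw)
    t1w = spgr_signal(gt.a_true, gt.r1_true, protocol.t1w)
    mtw = spgr_signal(gt.a_true, gt.r1_true, protocol.mtw, delta_app=gt.delta_app)
    vs = gt.voxel_size_mm
    return (
        SignalVolume(pdw, vs),
        SignalVolume(t1w, vs),
        SignalVolume(mtw, vs),
    )


def noddi_attenuation(
    viso: np.ndarray,
    vic: np.ndarray,
    odi: np.ndarray,
    direction: np.ndarray,
    protocol: AcquisitionProtocol,
) -> np.ndarray:
    """Three-compartment normalised diffusion signal for each gradient entry.

    S/S0 = (1 - viso) [vic A_ic + (1 - vic) A_ec] + viso exp(-b d_iso)

    A_ic is the Watson-dispersed stick, A_ec a zeppelin aligned with the mean
    fibre direction whose perpendicular diffusivity follows the tortuosity
    closure d_perp = d_par (1 - vic).  Parameter arrays share a leading voxel
    shape; ``direction`` adds a trailing 3-axis.  Output shape is
    ``voxel_shape + (n_volumes,)``.
    """
    viso = np.asarray(viso, dtype=float)[..., None]
    vic = np.asarray(vic, dtype=float)[..., None]
    odi = np.asarray(odi, dtype=float)
    b = protocol.bvals
    g = protocol.bvecs
    u = b * protocol.d_parallel

    cos2 = np.einsum("...i,ji->...j", np.asarray(direction, dtype=float), g) ** 2
    kappa = np.asarray(kappa_from_odi(odi))[..., None]
    a_ic = watson_stick_attenuation(u, cos2, kappa)

    d_perp = protocol.d_parallel * (1.0 - vic)
    a_ec = np.exp(-(b * d_perp + (protocol.d_parallel - d_perp) * b * cos2))
    a_iso = np.exp(-b * protocol.d_iso)

    att = (1.0 - viso) * (vic * a_ic + (1.0 - vic) * a_ec) + viso * a_iso
    return np.clip(att, 0.0, 1.0)


def simulate_dwi(gt: GroundTruthMaps, protocol: AcquisitionProtocol) -> SignalVolume:
    """Noiseless 4-D diffusion series; b = 0 entries equal ``a_true``."""
    att = noddi_attenuation(gt.viso, gt.vic, gt.odi, gt.direction, protocol)
    data = gt.a_true[..., None] * att
    return SignalVolume(data, gt.voxel_size_mm)


def add_rician_noise(
    vol: SignalVolume, snr: float, reference_signal: float, seed: int
) -> SignalVolume:
    """Magnitude-MRI (Rician) noise: sqrt((S + n1)^2 + n2^2), sigma = ref/snr.

    ``snr = inf`` returns an identical copy; a fixed seed gives bit-identical
    output.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return vol.with_data(vol.data.copy())
    sigma = float(reference_signal) / float(snr)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=vol.data.shape)
    n2 = rng.normal(0.0, sigma, size=vol.data.shape)
    return vol.with_data(np.hypot(vol.data + n1, n2))


def simulate_flair(
    gt: GroundTruthMaps,
    masks: RegionMasks,
    contrast: float = 5.0,
    nawm_mean: float = 100.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> SignalVolume:
    """FLAIR-like volume: lesions hyperintense over NAWM by ``contrast`` SDs.

    NAWM voxels ~ N(nawm_mean, noise_sd); lesion voxels are shifted up by
    contrast * noise_sd; other ICV tissue sits below WM and the exterior is
    noise around zero (clipped to be non-negative).
    """
    rng = np.random.default_rng(seed)
    mean = np.zeros(masks.grid_shape)
    mean[masks.icv] = 0.7 * nawm_mean
    mean[masks.wm] = nawm_mean
    mean[masks.wml] = nawm_mean + contrast * noise_sd
    data = mean + rng.normal(0.0, noise_sd, size=mean.shape)
    return SignalVolume(np.clip(data, 0.0, None), gt.voxel_size_mm)


def true_gratio(mvf: np.ndarray | float, viso: np.ndarray | float, vic: np.ndarray | float):
    """Closed-form aggregate g-ratio implied by true tissue parameters."""
    avf = (1.0 - np.asarray(mvf)) * (1.0 - np.asarray(viso)) * np.asarray(vic)
    return (1.0 + np.asarray(mvf) / avf) ** -0.5
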