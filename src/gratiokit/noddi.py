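"""Deterministic NODDI fit: grid-search initialisation + bounded refinement.

The model is the three-compartment orientation-dispersion model: a
Watson-dispersed intra-neurite stick (fraction vic of the tissue signal), an
extra-neurite zeppelin with tortuosity-coupled perpendicular diffusivity
d_perp = d_par (1 - vic), and isotropic free water (fraction viso).
Diffusivities are fixed at the canonical values carried by the protocol.

Fitting is per voxel on normalised attenuations with unweighted least
squares:

1. the mean fibre direction is the principal eigenvector of a log-linear
   tensor fit (exact for the noiseless model by axial symmetry);
2. (viso, vic, odi) are initialised from the best point of a fixed lattice;
3. scipy's bounded trust-region least squares refines (viso, vic, odi) and,
   by default, the two direction angles.

The returned objective never exceeds the best lattice objective, fractions
never leave [0, 1], and everything is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .protocol import AcquisitionProtocol
from .volume import SignalVolume
from .watson import ODI_FLOOR, kappa_from_odi, watson_stick_attenuation

__all__ = ["NoddiMaps", "NoddiFitConfig", "predict_signal", "fit_noddi"]


@dataclass
class NoddiMaps:
    viso: np.ndarray
    vic: np.ndarray
    odi: np.ndarray
    direction: np.ndarray  # (..., 3)
    fit_error: np.ndarray  # residual 2-norm
    valid: np.ndarray


def _lattice() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frac = np.arange(0.05, 1.0, 0.1)
    odi = np.array([0.04, 0.16, 0.36, 0.64, 1.0])
    return frac, frac, odi


@dataclass
class NoddiFitConfig:
    """Knobs of the deterministic fit; defaults match the documented scheme."""

    refine: bool = True
    refine_direction: bool = True
    odi_floor: float = max(0.01, ODI_FLOOR)
    tol: float = 1e-10
    max_nfev: int = 200
    lattice: tuple[np.ndarray, np.ndarray, np.ndarray] = field(default_factory=_lattice)


def predict_signal(
    viso: float | np.ndarray,
    vic: float | np.ndarray,
    odi: float | np.ndarray,
    direction: np.ndarray,
    protocol: AcquisitionProtocol,
) -> np.ndarray:
    """Normalised signal attenuation for each gradient-table entry.

    Shares its kernel with the phantom simulator by construction (single
    implementation), so simulation and fitting cannot drift apart.
    """
    from .phantom import noddi_attenuation  # local import avoids a cycle

    return noddi_attenuation(
        np.asarray(viso), np.asarray(vic), np.asarray(odi), np.asarray(direction), protocol
    )


def _tensor_directions(att: np.ndarray, protocol: AcquisitionProtocol) -> np.ndarray:
    """Principal diffusion direction per voxel from a log-linear tensor fit."""
    dw = protocol.bvals > 0
    b = protocol.bvals[dw]
    g = protocol.bvecs[dw]
    x = np.column_stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
    ) * (-b[:, None])
    y = np.log(np.clip(att[:, dw], 1e-8, None))  # (nvox, ndw)
    coef = y @ np.linalg.pinv(x).T  # (nvox, 6)
    d = np.empty((att.shape[0], 3, 3))
    d[:, 0, 0], d[:, 1, 1], d[:, 2, 2] = coef[:, 0], coef[:, 1], coef[:, 2]
    d[:, 0, 1] = d[:, 1, 0] = coef[:, 3]
    d[:, 0, 2] = d[:, 2, 0] = coef[:, 4]
    d[:, 1, 2] = d[:, 2, 1] = coef[:, 5]
    _, vecs = np.linalg.eigh(d)
    return vecs[:, :, -1]  # eigenvector of the largest eigenvalue


def _angles_from_vec(v: np.ndarray) -> tuple[float, float]:
    theta = float(np.arccos(np.clip(v[2], -1.0, 1.0)))
    phi = float(np.arctan2(v[1], v[0]))
    return theta, phi


def _vec_from_angles(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def fit_noddi(
    dwi: SignalVolume,
    protocol: AcquisitionProtocol,
    mask: np.ndarray | None = None,
    config: NoddiFitConfig | None = None,
) -> NoddiMaps:
    """Voxel-wise NODDI fit of a 4-D diffusion series.

    Voxels with non-positive mean b=0 signal are flagged invalid.  Warns if
    the table has fewer than 2 nonzero shells or < 12 directions in any
    shell (the fit still runs).
    """
    if config is None:
        config = NoddiFitConfig()
    if dwi.data.ndim != 4:
        raise ValueError("dwi must be a 4-D series")
    if dwi.data.shape[-1] != protocol.n_volumes:
        raise ValueError("dwi volume count does not match the gradient table")
    shells = protocol.shells
    if shells.size < 2:
        warnings.warn("fewer than 2 nonzero shells; NODDI fractions are weakly identified", stacklevel=2)
    for b in shells:
        if np.sum(protocol.bvals == b) < 12:
            warnings.warn(f"shell b={b:g} has fewer than 12 directions", stacklevel=2)

    grid = dwi.grid_shape
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    b0 = protocol.b0_mask
    if not b0.any():
        raise ValueError("gradient table has no b=0 entry to normalise against")
    s0 = dwi.data[..., b0].mean(axis=-1)
    ok = mask & (s0 > 0)

    vox = dwi.data[ok]  # (nvox, nvol)
    s0v = s0[ok][:, None]
    att = np.clip(vox / s0v, 0.0, 2.0)
    nvox = att.shape[0]

    mu = _tensor_directions(att, protocol)  # (nvox, 3)

    b = protocol.bvals
    g = protocol.bvecs
    u = b * protocol.d_parallel
    cos2 = (mu @ g.T) ** 2  # (nvox, nvol)
    a_iso = np.exp(-b * protocol.d_iso)  # (nvol,)

    viso_l, vic_l, odi_l = config.lattice
    # A_ic per odi lattice value: (nodi, nvox, nvol)
    kappas = np.asarray(kappa_from_odi(odi_l))
    a_ic = np.stack([watson_stick_attenuation(u, cos2, k) for k in kappas])
    # A_ec per vic lattice value: (nvic, nvox, nvol)
    d_perp = protocol.d_parallel * (1.0 - vic_l)
    a_ec = np.exp(
        -(b * d_perp[:, None, None] + (protocol.d_parallel - d_perp)[:, None, None] * b * cos2[None])
    )

    best_sse = np.full(nvox, np.inf)
    best = np.zeros((nvox, 3))
    for i, viso in enumerate(viso_l):
        for j, vic in enumerate(vic_l):
            for m, odi in enumerate(odi_l):
                model = (1.0 - viso) * (vic * a_ic[m] + (1.0 - vic) * a_ec[j]) + viso * a_iso
                sse = ((model - att) ** 2).sum(axis=1)
                better = sse < best_sse
                best_sse[better] = sse[better]
                best[better] = (viso, vic, odi)

    viso_f = best[:, 0].copy()
    vic_f = best[:, 1].copy()
    odi_f = best[:, 2].copy()
    mu_f = mu.copy()
    sse_f = best_sse.copy()

    if config.refine:
        eps = 1e-6
        for v in range(nvox):
            c2v = cos2[v]
            muv = mu[v]

            if config.refine_direction:
                theta0, phi0 = _angles_from_vec(muv)

                def resid(p):
                    viso, vic, odi, th, ph = p
                    gv = _vec_from_angles(th, ph)
                    c2 = (g @ gv) ** 2
                    return _model_att(viso, vic, odi, c2, u, b, a_iso, protocol) - att[v]

                x0 = [
                    np.clip(best[v, 0], eps, 1 - eps),
                    np.clip(best[v, 1], eps, 1 - eps),
                    np.clip(best[v, 2], config.odi_floor, 1 - eps),
                    theta0,
                    phi0,
                ]
                lb = [0.0, 0.0, config.odi_floor, theta0 - np.pi / 2, phi0 - np.pi / 2]
                ub = [1.0, 1.0, 1.0, theta0 + np.pi / 2, phi0 + np.pi / 2]
            else:

                def resid(p):
                    viso, vic, odi = p
                    return _model_att(viso, vic, odi, c2v, u, b, a_iso, protocol) - att[v]

                x0 = [
                    np.clip(best[v, 0], eps, 1 - eps),
                    np.clip(best[v, 1], eps, 1 - eps),
                    np.clip(best[v, 2], config.odi_floor, 1 - eps),
                ]
                lb, ub = [0.0, 0.0, config.odi_floor], [1.0, 1.0, 1.0]

            sol = least_squares(
                resid, x0, bounds=(lb, ub), method="trf",
                xtol=config.tol, ftol=config.tol, gtol=config.tol, max_nfev=config.max_nfev,
            )
            sse = float(2.0 * sol.cost)
            if sse <= sse_f[v]:
                sse_f[v] = sse
                viso_f[v], vic_f[v], odi_f[v] = sol.x[:3]
                if config.refine_direction:
                    mu_f[v] = _vec_from_angles(sol.x[3], sol.x[4])

    def unpack(values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(grid, fill)
        out[ok] = values
        return out

    direction = np.zeros(grid + (3,))
    direction[..., 2] = 1.0
    direction[ok] = mu_f / np.linalg.norm(mu_f, axis=1, keepdims=True)
    return NoddiMaps(
        viso=unpack(np.clip(viso_f, 0.0, 1.0)),
        vic=unpack(np.clip(vic_f, 0.0, 1.0)),
        odi=unpack(np.clip(odi_f, 0.0, 1.0)),
        direction=direction,
        fit_error=unpack(np.sqrt(sse_f)),
        valid=ok,
    )


def _model_att(viso, vic, odi, cos2, u, b, a_iso, protocol) -> np.ndarray:
    kappa = kappa_from_odi(odi)
    a_ic = watson_stick_attenuation(u, cos2, kappa)
    d_perp = protocol.d_parallel * (1.0 - vic)
    a_ec = np.exp(-(b * d_perp + (protocol.d_parallel - d_perp) * b * cos2))
    return (1.0 - viso) * (vic * a_ic + (1.0 - vic) * a_ec) + viso * a_iso
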