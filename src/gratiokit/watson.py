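"""Watson-distribution kernel for dispersed-stick diffusion signals.

The intra-neurite compartment is a stick (zero perpendicular diffusivity)
whose orientation n follows a Watson distribution W(n; mu, kappa) on the
sphere.  The dispersion-averaged stick attenuation

    A_ic(b, g) = E_n[ exp(-b * d_par * (g . n)^2) ]

is a ratio of two Bingham-type normalising integrals: the exponent
kappa*(mu.n)^2 - b*d_par*(g.n)^2 is a quadratic form n^T Q n whose nonzero
eigenvalues live in span{mu, g}, so

    A_ic = C(l1, l2, 0) / C(kappa, 0, 0),
    C(l)  = (1/4pi) \\int_{S^2} exp(sum_i l_i u_i^2) dS(u),

and C reduces to a 1-D integral over the polar cosine handled by
Gauss-Legendre quadrature with a Bessel-I0 azimuthal factor.  Everything is
evaluated in log space with `i0e` so large concentrations stay finite.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import i0e

__all__ = [
    "kappa_from_odi",
    "odi_from_kappa",
    "log_bingham_c",
    "watson_stick_attenuation",
]

#: minimum orientation-dispersion index accepted by the kernel; odi below this
#: maps to kappa > 6.4e3 where the quadrature would need more nodes than the
#: default and real tissue never goes.
ODI_FLOOR = 1e-4


def kappa_from_odi(odi: np.ndarray | float) -> np.ndarray | float:
    """Watson concentration from the orientation dispersion index.

    odi = (2/pi) * arctan(1/kappa); odi -> 0 is a perfectly coherent stick,
    odi = 1 is isotropic (kappa = 0).
    """
    odi = np.clip(odi, ODI_FLOOR, 1.0)
    return 1.0 / np.tan(np.pi / 2.0 * odi)


def odi_from_kappa(kappa: np.ndarray | float) -> np.ndarray | float:
    return (2.0 / np.pi) * np.arctan2(1.0, kappa)


@lru_cache(maxsize=8)
def _gl_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    # nodes/weights for integrating over t = cos(theta) in [-1, 1]
    t, w = np.polynomial.legendre.leggauss(n_nodes)
    return t, w


def log_bingham_c(l1, l2, l3, n_nodes: int = 96):
    """log of the Bingham normalising integral C(l1, l2, l3).

    C = (1/2) \\int_{-1}^{1} exp(l3 t^2 + a (1-t^2)) I0(d (1-t^2)) dt with
    a = (l1+l2)/2 and d = |l1-l2|/2 (polar axis along eigenvector 3).
    C(0,0,0) = 1.  Broadcasts over array arguments.
    """
    l1, l2, l3 = np.broadcast_arrays(
        np.asarray(l1, dtype=float), np.asarray(l2, dtype=float), np.asarray(l3, dtype=float)
    )
    t, w = _gl_nodes(n_nodes)
    t2 = (t**2)[(...,) + (None,) * l1.ndim]  # quadrature axis first
    one_m_t2 = 1.0 - t2
    a = 0.5 * (l1 + l2)
    d = 0.5 * np.abs(l1 - l2)
    # exponent includes the +d(1-t^2) factored out of I0 via i0e
    expo = l3 * t2 + (a + d) * one_m_t2
    m = expo.max(axis=0)
    integrand = np.exp(expo - m) * i0e(d * one_m_t2)
    c = 0.5 * np.tensordot(w, integrand, axes=(0, 0))
    return m + np.log(c)


def watson_stick_attenuation(b_times_d, cos2, kappa, n_nodes: int = 96):
    """Watson-dispersed stick attenuation.

    Parameters
    ----------
    b_times_d
        b * d_parallel, dimensionless (b in s/mm^2 times diffusivity in mm^2/s).
    cos2
        squared cosine of the angle between gradient direction and mean
        fibre orientation mu.
    kappa
        Watson concentration (>= 0).

    All arguments broadcast.  Returns values in [0, 1].
    """
    u, c2, kap = np.broadcast_arrays(
        np.asarray(b_times_d, dtype=float),
        np.asarray(cos2, dtype=float),
        np.asarray(kappa, dtype=float),
    )
    c2 = np.clip(c2, 0.0, 1.0)
    s2 = 1.0 - c2
    # eigenvalues of Q = kappa mu mu^T - u g g^T restricted to span{mu, g}
    tau = kap - u
    disc = np.sqrt(tau**2 + 4.0 * kap * u * s2)
    lp = 0.5 * (tau + disc)
    lm = 0.5 * (tau - disc)
    log_num = log_bingham_c(lp, lm, np.zeros_like(lp), n_nodes=n_nodes)
    log_den = log_bingham_c(kap, np.zeros_like(kap), np.zeros_like(kap), n_nodes=n_nodes)
    att = np.exp(log_num - log_den)
    return np.clip(att, 0.0, 1.0)
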