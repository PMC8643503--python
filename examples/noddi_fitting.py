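"""Fit the three-compartment dispersion model to a simulated diffusion series.

A handful of voxels with known (viso, vic, ODI) are simulated at SNR 30 and
refitted; the printed table shows per-parameter recovery.  viso is the
free-water fraction, vic the intra-neurite fraction of the tissue signal,
and ODI the orientation dispersion (0 = perfectly parallel fibres).
"""

import numpy as np

from gratiokit import default_protocol, fit_noddi, predict_signal
from gratiokit.volume import SignalVolume

protocol = default_protocol()
rng = np.random.default_rng(5)

truths = [
    (0.05, 0.36, 0.20),   # coherent white matter
    (0.15, 0.3552, 0.30), # lesional white matter
    (0.30, 0.50, 0.60),   # dispersed, partly fluid voxel
]
print(" truth (viso, vic, odi)      ->  fitted (viso, vic, odi)")
for viso, vic, odi in truths:
    mu = rng.normal(size=3)
    mu /= np.linalg.norm(mu)
    att = predict_signal(viso, vic, odi, mu, protocol)
    s0 = 1000.0
    sigma = s0 / 30.0
    noisy = np.hypot(s0 * att + rng.normal(0, sigma, att.shape), rng.normal(0, sigma, att.shape))
    maps = fit_noddi(SignalVolume(noisy.reshape(1, 1, 1, -1)), protocol)
    print(f" ({viso:.2f}, {vic:.4f}, {odi:.2f})  ->  "
          f"({maps.viso.ravel()[0]:.3f}, {maps.vic.ravel()[0]:.4f}, {maps.odi.ravel()[0]:.3f})")
print("Residual fit errors:", np.round(maps.fit_error.ravel(), 3),
      "(2-norm of attenuation residuals; ~sqrt(n)/SNR at this noise level)")
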