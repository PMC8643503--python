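"""Estimate MTsat, R1app and MTR from a simulated SPGR triplet.

The true MT saturation of the phantom's white matter is 0.0415 (4.15%);
the small-flip-angle estimator recovers it with a small, documented bias
(about -2.4% relative), and the exact-inversion path recovers it to
numerical precision.
"""

import numpy as np

from gratiokit import PhantomSpec, default_protocol, make_ground_truth, simulate_spgr
from gratiokit.relaxometry import compute_mtr, compute_mtsat, fit_t1app_amplitude

spec = PhantomSpec(grid_shape=(16, 16, 10), snr=np.inf, lesions=[])
protocol = default_protocol()
gt, masks = make_ground_truth(spec)
pdw, t1w, mtw = simulate_spgr(gt, protocol)

for method in ("helms", "exact"):
    rel = fit_t1app_amplitude(pdw, t1w, protocol, masks.wm, method=method)
    delta, valid = compute_mtsat(mtw, rel.r1app, rel.a_app, protocol, masks.wm, method=method)
    sel = valid & masks.wm
    print(f"[{method:5s}] median MTsat in WM: {np.median(delta[sel]):.5f} "
          f"(truth {gt.delta_app[sel].mean():.5f}), "
          f"median T1app: {np.median(1 / rel.r1app[sel]) * 1000:.0f} ms")

mtr, mvalid = compute_mtr(pdw, mtw, masks.wm, protocol)
print(f"median MTR in WM: {np.median(mtr[mvalid & masks.wm]):.4f} "
      "(fraction of signal removed by the MT pulse)")
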