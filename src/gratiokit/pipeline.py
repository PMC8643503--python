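"""End-to-end phantom pipeline: simulate, estimate, calibrate, summarise.

This is the desk-scale counterpart of the subject-level imaging analysis:
a patient phantom (with lesions) and a matched control phantom (without)
are simulated at the same protocol and SNR; MTsat is estimated on both; the
MVF constant k is calibrated on the control's white matter; NODDI, lesion
segmentation and the g-ratio map run on the patient; and the lesion / NAWM
median g-ratios are returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gratio import (
    GRatioMaps,
    RegionalSummary,
    calibrate_k,
    compute_avf,
    compute_gratio,
    compute_mvf,
    regional_summary,
)
from .lesions import derive_nawm, lesion_volume_pct_icv, segment_lesions
from .noddi import NoddiFitConfig, NoddiMaps, fit_noddi
from .phantom import (
    GroundTruthMaps,
    PhantomSpec,
    add_rician_noise,
    make_ground_truth,
    simulate_dwi,
    simulate_flair,
    simulate_spgr,
)
from .protocol import AcquisitionProtocol, default_protocol
from .relaxometry import RelaxometryMaps, compute_mtsat, fit_t1app_amplitude
from .volume import RegionMasks, SignalVolume

__all__ = ["PipelineResult", "simulate_subject", "run_phantom_pipeline"]


@dataclass
class PipelineResult:
    k: float
    relaxometry: RelaxometryMaps
    noddi: NoddiMaps
    gratio: GRatioMaps
    masks: RegionMasks
    wml_summary: RegionalSummary
    nawm_summary: RegionalSummary
    lesion_volume_pct_icv: float
    ground_truth: GroundTruthMaps


def simulate_subject(
    spec: PhantomSpec,
    protocol: AcquisitionProtocol,
    seed: int,
) -> dict:
    """Simulate all raw volumes for one subject at the phantom's configured SNR.

    The Rician noise SD is referenced to the NAWM PDw signal (the explicit
    SNR convention of the simulator); each volume gets an independent
    sub-seed derived from ``seed``.
    """
    gt, masks = make_ground_truth(spec)
    pdw, t1w, mtw = simulate_spgr(gt, protocol)
    dwi = simulate_dwi(gt, protocol)
    nawm_ref = masks.nawm if masks.nawm.any() else masks.wm
    ref = float(np.median(pdw.data[nawm_ref])) if nawm_ref.any() else float(pdw.data.max())
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    out = {
        "gt": gt,
        "masks": masks,
        "pdw": add_rician_noise(pdw, spec.snr, ref, seeds[0]),
        "t1w": add_rician_noise(t1w, spec.snr, ref, seeds[1]),
        "mtw": add_rician_noise(mtw, spec.snr, ref, seeds[2]),
        "dwi": add_rician_noise(dwi, spec.snr, ref, seeds[3]),
        "flair": simulate_flair(gt, masks, seed=seeds[0]),
    }
    return out


def run_phantom_pipeline(
    spec: PhantomSpec | None = None,
    protocol: AcquisitionProtocol | None = None,
    seed: int = 0,
    use_true_masks: bool = False,
    noddi_config: NoddiFitConfig | None = None,
    mtsat_method: str = "helms",
) -> PipelineResult:
    """Full patient-plus-control run returning regional median g-ratios.

    k is calibrated on the control phantom's white matter so that its median
    MVF equals the control tissue's true MVF (k_true * delta_app of the NAWM
    preset) — the phantom analogue of anchoring k to healthy-control data.
    With ``use_true_masks`` the ground-truth WML/NAWM masks replace the
    FLAIR segmentation (useful to isolate estimation error from
    segmentation error).
    """
    spec = spec or PhantomSpec()
    protocol = protocol or default_protocol()

    patient = simulate_subject(spec, protocol, seed)
    control_spec = spec.control()
    control = simulate_subject(control_spec, protocol, seed + 1)

    # --- MTsat stage (both subjects)
    def mtsat_maps(sub: dict) -> tuple[RelaxometryMaps, np.ndarray, np.ndarray]:
        wm = sub["masks"].wm
        rel = fit_t1app_amplitude(sub["pdw"], sub["t1w"], protocol, wm, method=mtsat_method)
        delta, valid = compute_mtsat(
            sub["mtw"], rel.r1app, rel.a_app, protocol, wm, method=mtsat_method
        )
        return rel, delta, valid & rel.valid

    rel_p, delta_p, valid_p = mtsat_maps(patient)
    _, delta_c, valid_c = mtsat_maps(control)

    # --- calibration on control NAWM (= all WM in the control)
    target_mvf = control_spec.k_true * control_spec.nawm.delta_app
    k = calibrate_k([delta_c], [control["masks"].nawm & valid_c], target_median_mvf=target_mvf)

    # --- lesion masking on the patient
    if use_true_masks:
        wml = patient["masks"].wml
        nawm = patient["masks"].nawm
    else:
        wml = segment_lesions(patient["flair"], patient["masks"].wm)
        nawm = derive_nawm(patient["masks"].wm, wml)
    lesion_load = lesion_volume_pct_icv(wml, patient["masks"].icv, spec.voxel_size_mm)

    # --- NODDI on the patient WM
    noddi = fit_noddi(patient["dwi"], protocol, patient["masks"].wm, config=noddi_config)

    # --- g-ratio map
    mvf, _ = compute_mvf(delta_p, k, patient["masks"].wm)
    avf = compute_avf(mvf, noddi.viso, noddi.vic)
    g, g_valid = compute_gratio(mvf, avf)
    validity = g_valid & valid_p & noddi.valid

    rel_p.delta_app = delta_p
    rel_p.valid = valid_p
    gmaps = GRatioMaps(mvf=mvf, avf=avf, g=g, validity=validity)

    return PipelineResult(
        k=k,
        relaxometry=rel_p,
        noddi=noddi,
        gratio=gmaps,
        masks=RegionMasks(
            icv=patient["masks"].icv, wm=patient["masks"].wm, wml=wml & patient["masks"].wm,
            nawm=nawm,
        ),
        wml_summary=regional_summary(g, validity, wml, "WML"),
        nawm_summary=regional_summary(g, validity, nawm, "NAWM"),
        lesion_volume_pct_icv=lesion_load,
        ground_truth=patient["gt"],
    )
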