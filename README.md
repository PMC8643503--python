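# gratiokit

Aggregate MRI g-ratio mapping with lesion/NAWM regional analysis and a
plasma-neurofilament cohort statistics engine — built around a fully
synthetic, forward-simulated test bed so every stage is verifiable without
any acquired data.

## The problem

In demyelinating disease (the motivating setting is newly diagnosed
relapsing–remitting multiple sclerosis), myelin loss inside white-matter
lesions is thought to drive axonal damage. Two non-invasive measurements
speak to this *in vivo*:

* **The aggregate g-ratio** — the ratio of inner axonal radius to outer
  fibre radius including the myelin sheath — estimated per voxel as

  $$g = \left(1 + \mathrm{MVF}/\mathrm{AVF}\right)^{-1/2}$$

  where the myelin volume fraction is a linear scaling of magnetization
  transfer saturation, $\mathrm{MVF} = k\,\delta_\text{app}$ with $k$
  calibrated on healthy-control data, and the axonal volume fraction comes
  from the NODDI diffusion model,
  $\mathrm{AVF} = (1-\mathrm{MVF})(1-v_\text{iso})\,v_\text{ic}$.
  Higher g means thinner myelin relative to axon calibre.

* **Plasma neurofilament light chain (NfL)** — an axonal cytoskeletal
  protein released into blood on axonal damage; "elevated" is defined as
  more than 3 SD above the healthy-control mean.

The package implements the whole chain: SPGR-triplet MTsat estimation,
NODDI fitting, FLAIR lesion masking, control-calibrated g-ratio maps with
lesion (WML) vs normal-appearing white matter (NAWM) summaries, and the
cohort-level stratified association analysis (Wilcoxon, Mann–Whitney,
Spearman, Fisher exact; lesion-load dichotomisation at 0.5% of intracranial
volume with 0.4%/0.6% sensitivity reruns; whole-cohort median g-ratio
split). Because no subject-level data are public, a digital phantom module
forward-simulates every raw input from known ground truth, so estimator
accuracy is measured, not assumed.

## Worked example

`examples/gratio_mapping.py` runs the full pipeline on a small noiseless
phantom whose lesion tissue is constructed with less myelin (MVF 0.3375 vs
0.415) at equal axonal volume fraction (0.20):

```
calibrated k: 10.255 (true 10.0)
lesion  median g: 0.6094  (truth 0.6100, n = 81 voxels)
NAWM    median g: 0.5703  (truth 0.5703, n = 375 voxels)
difference: +0.0391 - higher g in lesions means thinner myelin relative to axon calibre
```

The calibrated k differs from the true value by ~2.5% because the
small-flip-angle MTsat estimator carries a bias of that size; the
calibration absorbs it, which is exactly why k is anchored to control data.
The lesion/NAWM medians recover the closed-form ground truth (0.610/0.570)
to three decimals.

Other examples, one per capability: `phantom_simulation.py`,
`mtsat_mapping.py`, `noddi_fitting.py`, `lesion_segmentation.py`,
`cohort_analysis.py`. Each builds its own input and prints what it computes.

A thin CLI mirrors the stages for file-based workflows (NIfTI volumes, FSL
bval/bvec, CSV cohort tables):

```bash
gratiokit phantom --out phantom/ --seed 1
gratiokit mtsat --pdw phantom/pdw.nii.gz --t1w phantom/t1w.nii.gz \
    --mtw phantom/mtw.nii.gz --protocol phantom/protocol.json --out maps/
gratiokit noddi --dwi phantom/dwi.nii.gz --bval phantom/dwi.bval \
    --bvec phantom/dwi.bvec --mask phantom/mask_wm.nii.gz --out maps/
gratiokit segment --flair phantom/flair.nii.gz --wm phantom/mask_wm.nii.gz --out masks/
gratiokit gratio --mtsat maps/mtsat.nii.gz --noddi-dir maps/ \
    --wml masks/mask_wml.nii.gz --nawm masks/mask_nawm.nii.gz --k 10.0 --out g/
gratiokit analyze --cohort phantom/cohort.csv --out report/
```

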