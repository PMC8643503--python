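# Methods

## Scope and shape

gratiokit is a library-first package: the public API plus `examples/` are
the primary interface, with a thin `gratiokit` CLI for file-based use. All
inputs are synthetic — a digital phantom forward-simulates every raw volume
from voxel-wise ground truth, and a cohort generator produces subject-level
tables — so every estimator is validated by parameter recovery against a
known truth rather than by comparison to an external toolbox.

## Forward models

**SPGR triplet.** The spoiled gradient-echo steady state is simulated in
full, not in its small-angle approximation:

    S = A sin(α) (1 − E) / (1 − (1 − δ) cos(α) E),   E = exp(−TR·R1)

with δ = 0 for the PD- and T1-weighted volumes. The MT pulse enters the
MT-weighted volume as a per-TR factor (1 − δ) on longitudinal magnetisation
inside the steady-state recursion. This placement matters: it is the
construction under which the standard MTsat estimator is a first-order
inverse, and the only one under which noiseless round trips close. A naive
multiplicative (1 − δ) on the final signal is *not* equivalent and would
make the estimator wrong by orders of magnitude.

**Diffusion.** The three-compartment orientation-dispersion (NODDI) model:

    S/S0 = (1 − viso)[vic·A_ic + (1 − vic)·A_ec] + viso·exp(−b·d_iso)

* `A_ic`: stick with diffusivity d∥ dispersed by a Watson distribution;
  concentration κ relates to the orientation dispersion index by
  ODI = (2/π)·arctan(1/κ).
* `A_ec`: zeppelin along the mean fibre direction with tortuosity-coupled
  perpendicular diffusivity d⊥ = d∥(1 − vic).
* Diffusivities fixed at the canonical d∥ = 1.7×10⁻³ mm²/s and
  d_iso = 3.0×10⁻³ mm²/s (configurable on the protocol).

The Watson-dispersed stick integral is evaluated exactly (to quadrature
accuracy) as a ratio of Bingham normalising constants: the combined
exponent κ(μ·n)² − b d∥(g·n)² is a quadratic form whose nonzero eigenvalues
live in span{μ, g}, reducing the spherical integral to a 1-D Gauss–Legendre
quadrature over the polar cosine with a Bessel-I₀ azimuthal factor,
computed in log space with `i0e` for stability. With the default 96 nodes
the kernel agrees with a 1024-node reference to ~1×10⁻¹⁴ for κ ≤ 200;
ODI is floored at 0.01 (κ ≈ 64) in the fitter, far sharper than real
tissue dispersion.

**Noise.** Magnitude-MRI (Rician): each voxel becomes
√((S+n₁)² + n₂²) with n₁, n₂ ~ N(0, σ²) and σ = reference/SNR. The
reference is the median NAWM PDw signal — an explicit, testable convention.
SNR = ∞ is the exact identity. All randomness flows through
`numpy.random.default_rng` seeds; fixed seeds give bit-identical phantoms.

**FLAIR surrogate.** Lesions are hyperintense over NAWM by a configurable
contrast-to-noise ratio on a Gaussian background. This supports the
thresholding segmenter; it does not model inversion-recovery physics.

## Estimators

**MT relaxometry.** Two paths share one API:

* `method="helms"` (default): the small-flip-angle rational estimators for
  R1app and A, and δ = (Aα/S_MT − 1)·R1·TR − α²/2. At the default protocol
  (PDw 6°/25 ms, T1w 21°/25 ms, MTw 6°/25 ms) this carries a ≈ −2.4%
  relative bias on δ (≈ −1×10⁻³ absolute at δ = 0.0415), measured and
  bounded in the test suite. The bias is nearly multiplicative across
  tissue, so the control-based calibration of k absorbs it — mirroring why
  the calibration exists in practice.
* `method="exact"`: inversion of the full steady state (closed form for
  equal TRs, vectorised bisection otherwise); noiseless round trips recover
  R1, A to < 10⁻⁶ relative and δ to < 10⁻⁹.

Degenerate voxels (non-positive signals, vanishing denominators) are
flagged in a validity mask carried with every map; downstream regional
statistics intersect with it. Flip angles are radians internally, degrees
at every user boundary.

**NODDI fit.** Deterministic per voxel: (1) mean direction from the
principal eigenvector of a log-linear tensor fit (exact for the noiseless
model by axial symmetry); (2) best point of a fixed lattice
(viso, vic ∈ {0.05, …, 0.95} step 0.1; ODI ∈ {0.04, 0.16, 0.36, 0.64, 1});
(3) bounded trust-region least squares on (viso, vic, ODI) and, by default,
the two direction angles. Fitting is on attenuations normalised by the mean
b = 0 signal, unweighted; the Rician bias this admits is quantified at test
SNRs (at SNR 30, mean absolute error of vic stays below 0.05) rather than
corrected. The returned objective never exceeds the best lattice objective,
and fractions never leave [0, 1].

**g-ratio stage.** MVF = k·δ clipped to [0, 1) with clipped voxels counted
(warning above 5% in-mask, error under strict mode);
AVF = (1 − MVF)(1 − viso)·vic; g = (1 + MVF/AVF)^(−1/2) with voxels below
an AVF floor of 10⁻³ flagged invalid instead of producing unbounded ratios.
Calibration targets either a median control-NAWM MVF (direct ratio) or a
median control-NAWM g (unique root in k, found by bracketing). Regional
summaries use the numpy median (midpoint convention), percentile-based IQR,
and a fixed histogram support of [0.40, 0.80] in 80 bins so lesion and NAWM
histograms are directly comparable.

**Lesion masking.** Threshold at median + z·(1.4826·MAD) of in-WM FLAIR
intensities (robust statistics, because lesions contaminate moments),
z = 3 by default; 26-connected components smaller than 3 voxels removed;
NAWM = WM minus the lesion mask dilated by one voxel (partial-volume rim
guard). Lesion load is 100·(WML volume / ICV volume). These are explicit,
testable stand-ins for a manually edited clinical segmentation; parity with
any particular clinical pipeline is not claimed.

## Statistical engine

All tests two-sided, no multiple-testing correction (deliberately, matching
the analysis design it implements; every p is reported at nominal level).

* Wilcoxon signed rank: zeros dropped, mid-ranks for ties; exact
  enumeration of all 2ⁿ sign assignments for n ≤ 15, else normal
  approximation with continuity correction and tie-corrected variance.
  Both the approximate Z and the rank-biserial r are reported (a reported Z near
  0.8 alongside p < 0.001 at n = 73 is interpretable only as an effect
  size, not a standard normal deviate, so both are exposed).
* Mann–Whitney U: exact enumeration over all C(m+n, m) assignments for
  m + n ≤ 20, else tie-corrected normal approximation.
* Spearman: mid-rank Pearson; exact permutation for n ≤ 8, else the
  t-approximation with n − 2 df.
* Fisher exact: always exact; two-sided by the point-probability rule with
  10⁻⁷ relative slack for floating-point ties — bit-reproducible.
* Elevated NfL: control mean + 3 sample SDs (n − 1 denominator).

Exhaustive comparison of exact and approximate paths at the crossover sizes
shows agreement within 0.0111 for Wilcoxon at n = 15 (worst case at
p ≈ 0.45; below 0.01 throughout the decision region p < 0.1) and within
0.0086 for Mann–Whitney at m = n = 10.

**Stratified analysis.** The g-ratio split uses the *whole-cohort* median
of lesional g (the only reading consistent with unequal
stratum splits such as 23/15 and 13/22), with "normal" = ≤ median. Load
strata are ≤/> 0.5% ICV with 0.4% and 0.6% sensitivity reruns. The paired
lesion-vs-NAWM comparison defaults to Wilcoxon; a paired t-test is also
reported because the two appear interchangeably in practice.

## Synthetic cohort

Patient NfL is log-normal around a baseline raised by lesion volume and by
lesional g-ratio, with the g effect scaled by load:

    log NfL = log(4.5) + 0.756·L + 0.30·L·(g_wml − 0.606)/0.03 + 0.50·ε,
    L = log1p(vol / 0.5%)

Controls draw from the baseline log-normal (median 4.5 pg/ml, log-SD 0.45).
Lesion volume is log-normal with median 0.5% ICV; NAWM g is truncated
normal (0.570 ± 0.012) and lesional g adds a normal difference
(0.036 ± 0.030). These defaults were set analytically to the anchors of the
modelled clinical setting — patient median NfL ≈ 7.6 pg/ml, roughly a
quarter of patients elevated, volume–NfL correlation stronger than
g–NfL, and the g association concentrated in the substantial-load stratum —
and verified once by simulation. The generator emulates the *structure* of
such a cohort, not its full covariance: there is no age/sex structure, no
measurement error model for the imaging-derived medians, and the NfL
dependence is a chosen monotone form. Passing cohort tests therefore
demonstrates that the analysis machinery recovers associations that exist
by construction, not that such associations exist in any real population.

## Problem sizes and numerical choices

The reference phantom is 32×32×16 voxels of 2 mm (ellipsoidal ICV ≈ 6,900
voxels, WM ≈ 2,900, three spherical lesions ≈ 500), chosen so a full
patient-plus-control pipeline runs in minutes on one CPU while leaving
enough voxels for stable regional medians. The protocol is a conventional
MT-SPGR triplet plus a two-shell scheme (b = 700/2000 s/mm², 32
Fibonacci-lattice directions per shell, 4 × b = 0); actual clinical
protocol parameters vary by site, and all of these are configurable.
SNR 40 (against NAWM PDw) is the reference noise level. Ties in medians
use the midpoint convention; brentq tolerances for k are 10⁻¹²;
least-squares refinement tolerances are 10⁻¹⁰.

## Known limitations

* No B1+ inhomogeneity, motion, susceptibility or gradient-nonlinearity
  simulation, and no B1 correction of MTsat (a no-op hook marks where one
  would go).
* Single Watson compartment per voxel — no crossing fibres, no Bingham
  dispersion, no compartmental T2.
* The MVF–MTsat relationship is assumed linear with a single global k;
  regional variation of that coupling is not modelled.
* Lesion tissue in the phantom is homogeneous; real lesions have gradients
  and partial-volume rims beyond the 1-voxel exclusion ring.
* The FLAIR surrogate and threshold segmenter stand in for a reviewed
  clinical segmentation; segmentation-driven bias on real data is not
  bounded by these tests.
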