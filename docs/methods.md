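# Methods

## Signal models

The package analyses trace-weighted diffusion MRI magnitudes acquired on a
cross product of echo times and b-values; the default design is
TE ∈ {55, 73} ms × b ∈ {50, 700} s/mm², i.e. four measurements per voxel,
ordered TE-major. Units follow radiological convention — b in s/mm², ADC in
μm²/ms — so every exponent carries a single 10⁻³ conversion, implemented in
exactly one place (`signal_models.attenuation_basis`).

**Two-component model.** The voxel signal is a mixture of a slow-diffusion /
short-T2 pool and a fast-diffusion / long-T2 pool:

SI(TE, b) = SI₀ · [SF_slow · e^(−TE/T2_slow − b·ADC_slow·10⁻³) +
(1 − SF_slow) · e^(−TE/T2_fast − b·ADC_fast·10⁻³)],  SF_slow + SF_fast = 1.

The diffusivities are fixed a priori at 0.3 and 2.6 μm²/ms (literature
values for the corresponding bi-exponential decomposition of prostate
tissue); the T2 pair is a *population* property, calibrated once (below).
Each voxel therefore carries two free parameters, (SI₀, SF_slow).

**Baselines.** The bi-exponential model drops the T2 factors and is fitted
to the two b-values at the longest TE (exact 2×2 solution, fraction clipped
to [0, 1] with SI₀ refit under the clip). The mono-exponential ADC is the
closed-form two-point log-ratio at the same TE. Both baselines are
implicitly T2-weighted through their acquisition TE, which is the point of
the comparison.

## Per-voxel fitting

With all four decay constants fixed, the two-component model is linear in
the rescaled amplitudes (a, b) = (SI₀·SF_slow, SI₀·SF_fast), a ≥ 0, b ≥ 0.
The solver evaluates the closed form of this 2-column non-negative
least-squares problem (unconstrained 2×2 normal equations; if a sign
constraint activates, the better of the two single-column projections),
vectorized over voxels. The problem is convex with independent basis
columns, so the minimizer is unique and no initialization or random seed
exists anywhere in the fitting path. Residuals are evaluated directly
(`r = Ap − s`) rather than through the normal-equation identity, which
would lose ~7 digits to cancellation on near-perfect fits. SF_slow = a/(a+b)
is a physical proportion and lies in [0, 1] by construction. Degenerate
inputs (all-zero, non-finite) are flagged invalid and carry NaN — never
zero, since zero is a legal signal fraction.

## Voxel exclusion

Applied before any fitting, inside the prostate box mask:

* **Noise floor**: the mean magnitude over an explicit background (air)
  mask, across all measurements. A voxel is excluded if *any* measurement
  is ≤ 3× this floor (the boundary itself is excluded).
* **Negative apparent decays**: apparent ADC per TE
  (ln(S_b1/S_b2)/((b2−b1)·10⁻³)) and apparent T2 per b-value
  ((TE2−TE1)/ln(S_TE1/S_TE2)) must be non-negative for every adjacent pair
  in each direction; on a 2×2 design this reduces to the signal being
  non-increasing in both TE and b.

QC reports count each rule separately plus their union; excluded voxels
never receive a fitted value.

## T2 calibration

The population T2 pair minimizes the pooled cost = Σ over included training
voxels of the per-voxel fit RMSE, evaluated exhaustively on a grid (default
T2_slow ∈ {20, 25, …, 100} ms, T2_fast ∈ {100, 110, …, 400} ms; cells with
T2_slow ≥ T2_fast are infeasible and masked). The grid brackets published
prostate compartment T2s and the expected optimum near (45, 180) ms. Ties
break toward the smallest T2_slow, then smallest T2_fast (C-order argmin),
making the result deterministic. The cost is a sum over voxels, so a seeded
uniform subsample (default cap 8,000 voxels) rescales the surface without
moving its minimum in expectation; the pooled cost uses raw-intensity
residuals, so brighter patients carry proportionally more weight — an
optional per-voxel normalization is deliberately *not* the default, matching
the summed-RMSE definition of the cost.

## Phantom cohort

The synthetic cohort emulates the structure of a two-arm prostate MRI
study: 62 "cancer patients" split 31/31 into training and test arms (49
peripheral-zone, 13 non-PZ, fixed per arm as 25+6 / 24+7) and 14 BPH
patients. Each patient is a 48×48×8 volume (2×2×3 mm voxels) with a
28×28×6 tissue box surrounded by air; lesions are ellipsoids of ~200 voxels
(radii 5×5×2), PZ patients carry a tumor plus a normal-tissue ROI, non-PZ
patients a tumor ROI, BPH patients one nodule ROI.

Tissue classes and their slow-fraction distributions (patient-level ×
voxel-level spread):

| class  | SF_slow mean | between-patient sd | within-patient sd |
|--------|-------------:|-------------------:|------------------:|
| tumor  | 0.75 | 0.06 | 0.05 |
| bph    | 0.65 | 0.08 | 0.06 |
| stroma | 0.45 | 0.05 | 0.12 |
| normal | 0.30 | 0.06 | 0.05 |

All classes share the generating T2 pair (45, 180) ms and the fixed ADC
pair, so the calibration has a well-defined truth. Tumor > BPH > stroma >
normal reproduces the clinical contrast direction; the stroma ("rest of
prostate") spread is chosen so that voxel-wise tumor discrimination lands
in the high-but-imperfect regime observed clinically (AUC ≈ 0.95–0.97)
rather than at ceiling — that background class is what sets the ROC floor.

**Noise.** Magnitudes receive Rician noise,
`sqrt((S+ε₁)² + ε₂²)`, ε ~ N(0, σ) i.i.d., because MRI magnitude data are
root-sum-square combinations of noisy quadrature channels; this produces
the nonzero background floor the exclusion rule needs. σ is set from a
target tissue SNR of 40 at the lowest-(TE, b) measurement of a mean stroma
voxel. Per-voxel SI₀ is log-normal with CV 0.2 around the class mean of 100
(arbitrary scanner units).

**Signal voids.** 10 % of tissue voxels have SI₀ scaled by 0.02, emulating
calcifications, post-biopsy hemorrhage and susceptibility dropout. At
SNR 40 the noise-floor rule removes these with probability ≈ 1 while bright
voxels virtually never fail any rule (weakest tissue measurement ≈ 10–15 σ
against a 3.76 σ threshold), so the tissue-ROI excluded fraction is ≈ 10–12 %,
the regime reported for clinical data. Without such a void subpopulation the
exclusion rules are essentially inactive at this SNR.

**Grade labels.** Each cancer patient's Gleason Grade Group is
`clip(round(3 + z + N(0, 2)), 1, 5)` where z is the patient's tumor SF_slow
mean standardized by the between-patient sd. The label-noise sd of 2 gives
a pre-rounding correlation of 1/√(1+4) ≈ 0.45, i.e. the "fair"
(ρ ≈ 0.3–0.5) rank correlations seen in practice; it is a label-noise
mechanism only and encodes no claim about the biological SF–grade link.

**What the phantom does not model**: anatomically realistic geometry,
partial volume at lesion borders, EPI distortion, motion between scans
(inputs are co-registered by construction), coil-sensitivity shading,
diffusion-time dependence of ADC, and Rician bias on the fitted values is
present but uncorrected. Passing the cohort-level checks therefore
demonstrates that the *pipeline* recovers designed contrasts under
realistic noise — not that the clinical effect sizes themselves are
reproduced from tissue physics.

## Statistical evaluation

Mirrors the clinical analysis plan: Wilcoxon signed-rank (two-sided) for
paired PZ tumor vs normal ROI means on the test arm; Mann-Whitney U
(two-sided) for non-PZ tumor vs BPH across all patients (the BPH arm is
never split — it is too small); Bonferroni over the 9 comparisons
(3 models × {paired test, unpaired test, Spearman}), giving α = 0.05/9 ≈
0.006. Exact small-sample null distributions are used where tie-free
(SciPy's `method="auto"`); identical paired lists make the signed-rank test
undefined and are reported as p = 1 with a warning. Zero differences are
dropped per Wilcoxon's original rule.

Voxel-wise ROC compares valid tumor-ROI voxels of the test arm against all
other valid box voxels (normal ROIs and background prostate included), per
metric, with explicit polarity (signal fractions: higher = tumor; ADC:
lower = tumor). AUC is the tie-corrected rank statistic. The operating
threshold maximizes Youden's J on the *training* arm only — ties broken
toward the threshold classifying fewer voxels as tumor — and is then frozen
before test sensitivity/specificity are computed, so no test label ever
influences the threshold. Youden's J is a design choice; the criterion used
in the original clinical analyses of this kind is rarely stated, and J is
the conventional, reproducible reading.

Spearman's ρ (average ranks on ties, t-approximation p) relates test-arm
tumor ROI means to grade. Raw p-values and the adjusted α are reported
separately rather than folded into a single "significant" verdict.

## Problem sizes and determinism

Default desk-scale runs: 76 patients × 4,704 box voxels, calibration pool
capped at 8,000 voxels over a 17×31 grid; the full pipeline completes in a
few seconds on one core. Every random draw descends from a single integer
seed via independent `numpy` generator streams (geometry, parameters/noise,
cohort assignment, calibration subsampling), so reruns are bit-identical;
the fitting itself is deterministic closed-form algebra with no seed at
all.
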