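# t2dwi

Quantitative analysis of **combined T2- and diffusion-weighted prostate MRI**
(T2-DWI): a two-compartment signal-fraction model fitted voxel-by-voxel to a
2×2 grid of echo times and b-values, with population-level T2 calibration,
conventional ADC model baselines, and the diagnostic statistics used to
separate tumor from normal tissue and benign hyperplasia (BPH). A seeded
Rician-noise phantom cohort stands in for patient data, so every analysis in
the package is reproducible end to end on a laptop.

Intended users: MRI physicists and imaging scientists prototyping
multi-compartment diffusion-relaxometry analyses, and anyone who needs a
tested, deterministic reference pipeline for voxel-wise model comparison on
trace-weighted DWI.

## The model

Each voxel's magnitude signal at echo time TE (ms) and diffusion weighting b
(s/mm²) is modeled as water in two pools — a slow-diffusing, short-T2
compartment (intracellular/epithelial) and a fast-diffusing, long-T2
compartment (luminal/extracellular):

```
SI(TE, b) = SI0 · [ SF_slow · e^(−TE/T2_slow) e^(−b·ADC_slow)
                  + (1 − SF_slow) · e^(−TE/T2_fast) e^(−b·ADC_fast) ]
```

with ADC in μm²/ms (so the exponent carries a factor 10⁻³), fixed
diffusivities ADC_slow = 0.3 and ADC_fast = 2.6 μm²/ms, and SF_slow ∈ [0, 1]
the slow signal fraction. The component T2 values are not fitted per voxel:
they are **calibrated once per population** by an exhaustive grid search
minimizing the summed per-voxel fit RMSE over all included training voxels.
With the decays fixed, each voxel's fit is a 2-column non-negative linear
least-squares problem — convex, global, seed-free.

Two baselines are fitted from the two b-values at the longest TE: a
bi-exponential ADC-only model (same fixed diffusivities, free SF_slow) and
the conventional mono-exponential ADC.

Before any fitting, voxels are excluded if any measurement is at or below
3× the noise floor (mean background magnitude) or if any apparent decay rate
(ADC per TE, T2 per b) is negative.

## Worked example

```python
import numpy as np
from t2dwi import (AcquisitionScheme, ComponentBasis, two_component_signal,
                   fit_two_component_voxel)

scheme = AcquisitionScheme()                      # TE {55, 73} ms x b {50, 700} s/mm^2
basis = ComponentBasis(t2_slow=45, t2_fast=180)   # ADCs 0.3 / 2.6 um^2/ms

signal = two_component_signal(100.0, 0.67, basis, scheme)
print("clean signal:", np.round(signal, 2))

rng = np.random.default_rng(0)
noisy = np.sqrt((signal + rng.normal(0, 1.0, 4))**2 + rng.normal(0, 1.0, 4)**2)
si0, sf_slow, rmse, valid = fit_two_component_voxel(noisy, scheme, basis)
print(f"si0 = {si0:.1f}, sf_slow = {sf_slow:.3f}, rmse = {rmse:.2f}, valid = {valid}")
```

```
clean signal: [40.79 19.94 32.35 14.29]
si0 = 100.1, sf_slow = 0.660, rmse = 0.20, valid = True
```

The clean signal is the 2×2 measurement vector in (TE, b) order; at SNR ≈ 40
the fit recovers the generating fraction 0.67 to within ±0.01.

A full cohort analysis — 62 simulated cancer patients (31 train / 31 test)
plus 14 BPH patients — runs in a few seconds:

```python
from t2dwi.io import PipelineConfig
from t2dwi.pipeline import run_pipeline

result = run_pipeline(PipelineConfig(seed=1))
print(f"calibrated T2 pair: ({result.basis.t2_slow:g}, {result.basis.t2_fast:g}) ms")
for d in result.diagnostics:
    print(f"{d.metric:>18}: AUC={d.auc:.3f}  threshold={d.threshold:.2f}  "
          f"sens={d.sensitivity_pct:.1f}%  spec={d.specificity_pct:.1f}%")
```

```
calibrated T2 pair: (45, 180) ms
  sf_two_component: AUC=0.970  threshold=0.62  sens=92.4%  spec=90.4%
 sf_bi_exponential: AUC=0.956  threshold=0.31  sens=90.4%  spec=87.5%
               adc: AUC=0.956  threshold=1.41  sens=90.4%  spec=87.5%
```

The grid search recovers the generating T2 pair (45, 180) ms; the AUCs
compare voxel-wise tumor-ROI values against all other prostate voxels of the
test split, with the Youden-optimal threshold taken from the training split
only. `result.comparisons` holds the Wilcoxon / Mann-Whitney / Spearman
table with the Bonferroni-adjusted significance level.

The same pipeline is available from the shell:

```bash
t2dwi run-all --seed 1 --out results/
t2dwi simulate --seed 1 --out cohort/        # NIfTI volumes + masks + tables
t2dwi calibrate --seed 1 --out calib/        # cost surface CSV + optimum JSON
```

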