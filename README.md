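# strokemri

Multimodal quantitative MRI analysis of experimental mouse stroke
(transient middle-cerebral-artery occlusion, tMCAO), exercised end-to-end
on synthetic digital-phantom cohorts.

Stroke studies in mice compare strain groups — classically C57Bl/6 versus
Sv/129 — imaged serially after tMCAO with a multimodal protocol:
quantitative T2 relaxometry delineates infarction, diffusion-weighted
imaging measures the apparent diffusion coefficient (ADC) of tissue water,
and continuous arterial spin labeling (CASL) measures cerebral blood flow
(CBF). This package implements the full analysis chain for such studies —
and, because animal imaging data are rarely shareable, a digital
mouse-brain phantom that generates whole cohorts with known ground truth,
so every stage is testable against the truth that produced the images.

## What it computes

* **T2 relaxometry** — voxel-wise monoexponential fit
  `S(TE) = S0 exp(-TE/T2)` to the first 20 echoes of a 32-echo CPMG train
  (log-linear initialization + damped nonlinear least squares).
* **T1 relaxometry** — three-parameter magnitude inversion-recovery fit
  `|S0 (1 - B exp(-TI/T1))|` with polarity restoration.
* **ADC** — two-point diffusion map `ADC = -(1/b) ln(S_b/S_0)`; at
  b = 800 s/mm² the coefficient is exactly −0.00125.
* **CBF** — single-compartment CASL quantification

      CBF = 6000 · (λ / T1[s]) · (S_ctrl − S_lbl) / (2 α S_ctrl)   [mL/100 g/min]

  with inversion efficiency α = 0.7 and brain–blood partition coefficient
  λ = 0.95 mL/g.
* **Spatial normalization** — brain extraction and rigid 6-DOF
  registration to a common template (masked normalized cross-correlation,
  coarse-to-fine Powell search), step-wise for longitudinal data.
* **Infarct segmentation** — fixed 34 ms threshold on quantitative T2
  maps (strict inequality), intraventricular CSF removal, emulated manual
  whole-brain volumetry, infarct/hemisphere volume ratios.
* **Group statistics** — within-group infarct probability maps (voxel-wise
  mean of binary masks), ROI summaries as mean ± SEM, and exact
  matched-pairs Wilcoxon signed-rank tests (full sign-assignment
  enumeration for n ≤ 12).

## Worked example

Simulate a two-strain study (8 subjects per strain, 2 h and 24 h after
occlusion, SNR 40) on a scaled-down grid and run the full analysis:

```python
import logging; logging.disable(logging.INFO)
from strokemri import AcquisitionGeometry, default_config, run_pipeline

geometry = AcquisitionGeometry(matrix_size=(32, 32), fov_mm=(12.5, 12.5), n_slices=9)
config = default_config(
    geometry=geometry, master_seed=7, registration="identity",
    group_kwargs=dict(n_subjects=8, snr=40.0, misaligned=False))
result = run_pipeline(config)

for strain in ("C57Bl/6", "Sv/129"):
    for tp in ("2h", "24h"):
        s = result.summaries[strain][tp]
        print(f"{strain:8s} {tp:>3s} | "
              f"P(infarct) cortex {s['cortex']['probability_pct']['mean']:5.1f} ± {s['cortex']['probability_pct']['sem']:4.1f} % | "
              f"subcortex {s['subcortex']['probability_pct']['mean']:5.1f} ± {s['subcortex']['probability_pct']['sem']:4.1f} % | "
              f"CBF cortex {s['cortex']['cbf']['mean']:4.1f} ± {s['cortex']['cbf']['sem']:3.1f} | "
              f"ratio {s['volume_ratio']['mean']:.2f}")
w = result.wilcoxon["roi_comparisons"]["cbf_cortex_2h"]
print(f"Wilcoxon CBF cortex 2h (C57Bl/6 vs Sv/129): W={w['W']:.0f}, p={w['p_two_sided']:.3f}")
```

This prints:

```
C57Bl/6   2h | P(infarct) cortex  55.0 ±  7.3 % | subcortex  68.8 ±  8.8 % | CBF cortex 39.4 ± 1.9 | ratio 0.29
C57Bl/6  24h | P(infarct) cortex  91.5 ±  1.9 % | subcortex 100.0 ±  0.0 % | CBF cortex 24.8 ± 1.3 | ratio 0.46
Sv/129    2h | P(infarct) cortex  52.7 ±  8.9 % | subcortex  68.1 ±  6.5 % | CBF cortex 32.5 ± 2.0 | ratio 0.28
Sv/129   24h | P(infarct) cortex  83.9 ±  3.3 % | subcortex  99.7 ±  0.3 % | CBF cortex 21.4 ± 0.8 | ratio 0.44
Wilcoxon CBF cortex 2h (C57Bl/6 vs Sv/129): W=35, p=0.016
```

Reading the output: infarction is already (partially) established in the
subcortex at 2 h and extends toward the full MCA territory by 24 h — at
24 h the subcortical infarct probability reaches 100 % while cortical
probability climbs above 90 %; cortical CBF falls from ~35–40 to
~21–25 mL/100 g/min; the infarct/hemisphere volume ratio grows to ~0.45.
The CASL-based CBF values recover the generating group levels of the
phantom (e.g. C57Bl/6 cortex 2 h generated at 38.7 mL/100 g/min). The
24 h subcortical value of 99.7 % in one group is noise at work: a few
voxels of one subject's fitted T2 crossed the 34 ms threshold.

The command-line interface wraps the same stages
(`strokemri all --out run/ --seed 7`, plus per-step subcommands
`fit-t2`, `fit-t1`, `adc`, `cbf`, `register`, `apply-xfm`, `segment`,
`volumetry`, `probmap`, `roi-stats`, `compare`, `simulate`, `analyze`,
`report`); volumes are NIfTI-1 with JSON sidecars throughout.

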