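# Methods

`strokemri` re-implements, as a tested pipeline, a multimodal quantitative
MRI analysis of experimental mouse stroke (transient middle-cerebral-artery
occlusion, tMCAO): voxel-wise T2/T1 relaxometry, ADC and CASL-based CBF
mapping, rigid registration to a common template, threshold-based infarct
segmentation with CSF removal, within-group infarct probability maps,
volumetry, and exact matched-pairs Wilcoxon statistics. Because no real
image data are bundled, the pipeline is exercised end-to-end on a synthetic
digital mouse-brain phantom cohort with known ground truth.

## The digital phantom

**Geometry.** The default acquisition grid matches the emulated protocol:
64 x 64 in-plane matrix over a 2.5 x 2.5 cm field of view (0.39 mm pixels),
13 coronal slices of 0.5 mm thickness on a 1 mm pitch, a 32-echo CPMG train
with 4.2 ms echo spacing (TE_k = 4.2 k ms), diffusion weightings b = 0 and
800 s/mm^2, a CASL control/label pair and a 6-point inversion-recovery
series (TI = 0.1-6 s) for T1. The protocol line "TR/TE = 4.2/2000 ms" for
the CPMG sequence is read as echo spacing 4.2 ms with TR 2000 ms, by
analogy with the DWI line "TE/TR = 22.3/2000 ms" where 2000 ms is
unambiguously TR. The CASL acquisition's thick slab is treated as sharing
the common per-slice grid; no separate slab geometry is modelled.

**Anatomy.** The brain is an ellipsoid defined by closed-form inequalities
on voxel coordinates; within it sit a left and right hemisphere, one small
medial ventricle per hemisphere, a deep right-hemisphere subcortical ROI
(caudoputamen + pyramidal tract analogue) and a lateral superficial
cortical band standing in for the central MCA territory. The two ROIs
together cover about 45 % of the ipsilateral hemisphere, chosen so that a
complete MCA-territory infarction produces an infarct/hemisphere volume
ratio near the reported 24 h level (~0.43). Because the anatomy is
analytic, the phantom can be *evaluated at arbitrary continuous
coordinates*: a misaligned acquisition is synthesized by sampling the
phantom at the rigidly transformed voxel positions, exactly as a scanner
samples a moved head — no interpolation of voxel data is involved, so
posed images carry no resampling blur. On the integer grid the same
inequalities produce the bit-reproducible label template.

**Lesions.** The infarct grows from the subcortical territory into the
cortical MCA band: each ROI has a deterministic growth ordering
(breadth-first distance from a seed voxel, seeded-random tie-breaks within
layers), and a lesion covering fraction *f* of an ROI is the first
round(f·N) voxels of that ordering. One ordering per ROI is shared across
timepoints, so the 2 h lesion is nested inside the 24 h lesion by
construction and every prefix is connected. Default fractions are set to
the reported group-mean infarct probabilities: cortex 0.607/0.951 (2 h /
24 h) and subcortex 0.791/1.0 for C57Bl/6; 0.533/0.921 and 0.678/1.0 for
Sv/129; per-subject fractions are truncated-normal around these means (SD
0.28 at 2 h, 0.08 for 24 h cortex) so cohort SEMs land near the reported
ones. A known tension: the source report's 2 h ROI probabilities (53-79 %)
and its 2 h manual volume ratios (0.06-0.1 of hemisphere) cannot both be
matched by a single ground-truth lesion; the phantom follows the
probabilities, and 2 h volume ratios come out near 0.3.

**Tissue parameters.** Fields are piecewise constant per compartment. T2
and T1 distinguish healthy tissue (45 / 2200 ms), infarct (30 / 2400 ms)
and CSF (80 / 4500 ms); ADC and CBF carry ROI-level values on the cortical
and subcortical territories — the ground-truth analogue of the ROI means
the study design reports — parameterized per strain and timepoint from the
reported group means (e.g. Sv/129 cortex 2 h: CBF 34.1 mL/100 g/min, ADC
7.8e-4 mm^2/s), with healthy tissue at 110 mL/100 g/min and 8.0e-4 mm^2/s.
The proton-density scale s0 carries a smooth deterministic texture
(low-frequency sinusoids plus a radial profile), giving registration the
internal structure real anatomy provides. The T2 compartments are
deliberately separated from the 34 ms segmentation threshold by a 2 ms
margin on either side, so noise-free threshold segmentation is exact by
design; per-subject T2 draws are clipped to preserve the margins.

**Between-subject variability.** Each subject draws one multiplicative
truncated-normal factor per tissue parameter (CV 15 % for ADC/CBF/s0, 5 %
for T2, 10 % for T1) which is shared across timepoints: variability is a
property of the animal, so healthy-tissue parameters stay longitudinally
stable while group-mean levels evolve with the infarct. (Longitudinally
independent draws would also make the 2 h and 24 h images of one animal
differ everywhere, which defeats intra-subject registration.)

**Noise and averaging.** Noise is Rician — the magnitude of the
complex-Gaussian-corrupted signal — with sigma set from the target SNR
(default 40, relative to the subject's tissue s0). With zero signal the
background mean converges to sigma·sqrt(pi/2) (Rayleigh limit), which is a
tested property. Sequences acquired with multiple signal averages are
simulated as the mean of that many independent noisy repetitions: 12 for
the CASL pair and 3 for the b = 800 DWI, matching the emulated protocol.
This matters quantitatively: a single CASL pair at SNR 40 cannot resolve
the ~1 % control-label difference of ischemic flow levels.

**Forward models.** CPMG echoes `s0 exp(-TE_k/T2)`; DWI
`s0' exp(-b ADC)`; inversion recovery `|s0 (1 - 2 exp(-TI/T1))|`. The CASL
pair is constructed by inverting the analysis-side quantification
(`label = control (1 - 2 alpha CBF T1 / (6000 lambda))`), so applying the
CASL formula with the true T1 returns the ground-truth CBF exactly in the
noise-free limit. No Bloch simulation, k-space effects, partial-volume
averaging, B0/B1 inhomogeneity or motion are modelled.

**Seeds.** All randomness derives from one master seed through
`SeedSequence([master_seed, group_index, subject_index, slot])`: slot 0
for parameter/pose draws, slot 1 for lesion tie-breaks, slots 10+ for
per-sequence acquisition noise (one independent stream per sequence).
Identical configuration and master seed reproduce a cohort — and the
pipeline's results JSON — bit for bit. When every lesion-fraction SD is
zero the lesion tie-break seed collapses to a group-level seed, so a fully
degenerate between-subject distribution yields identical subjects, as a
degenerate distribution should.

## Quantitative mapping

**T2.** Per-voxel monoexponential fit `S = S0 exp(-TE/T2)` to exactly the
first 20 echoes of the 32-echo train, parameterized as (S0, R2=1/T2).
A signal-weighted log-linear regression provides the initializer; a
batched Levenberg-Marquardt refinement (per-voxel damping, relative
convergence tolerance 1e-8, at most 100 iterations) polishes it. Voxels
with any non-positive signal among the used echoes, failed convergence or
non-positive parameters are flagged invalid, never silently filled. No
noise-floor offset term is fitted (two-parameter model).

**T1.** Three-parameter magnitude inversion-recovery fit
`|S0 (1 - B exp(-TI/T1))|` with polarity restoration: both candidate sign
patterns around the signal minimum are fitted and the lower-residual
solution kept per voxel. Constant (non-recovering) series are invalid.

**ADC.** Closed form `-(1/b) ln(S_b/S_0)`; at b = 800 s/mm^2 the
coefficient is exactly -0.00125. Voxels with non-positive signal are
invalid; negative ADC values are *retained* and counted in diagnostics —
clamping would bias group means.

**CBF.** Single-compartment CASL quantification
`CBF = 6000 (lambda/T1[s]) (S_ctrl - S_lbl) / (2 alpha S_ctrl)` with
inversion efficiency alpha = 0.7 and partition coefficient lambda =
0.95 mL/g; the factor 6000 converts mL/g/s to mL/100 g/min. T1 comes from
the fitted map by default; a fixed literature T1 is configurable for
protocols without an IR series. No transit-time or slab-geometry
corrections are applied. Negative CBF is retained and flagged.

## Spatial normalization

Brain extraction either replays the phantom's ground-truth mask (emulating
the study's manual extraction) or runs automatically (Otsu threshold,
largest connected component, morphological closing on a padded array).

Registration is rigid with 6 degrees of freedom — three Euler angles
(x-y-z order, degrees) and three translations (mm) about the volume
center; the study's "affine procedure with six degrees of freedom" is read
as rigid. The similarity metric is masked normalized cross-correlation,
optimized by a derivative-free Powell search over two resolution levels
(2x in-plane downsampling at the coarse level, with a multi-start screen
of +/-2 deg / +/-4 deg and +/-1 / +/-2 voxel single-axis perturbations).
Three numerical choices matter on this kind of data and are worth stating:

* both images are Gaussian-smoothed identically before correlation
  (sigma = 2 voxels in-plane, 1.2 slices through-plane at the fine level),
  which equalizes the interpolation blur the warped moving image acquires;
* the correlation is evaluated over the *eroded* brain core (2 voxels
  in-plane, 1 slice axially), because rim voxels carry the
  tissue/background edge — dominated by sampling and interpolation
  effects — rather than pose information;
* in the pipeline, natively segmentable infarct voxels are excluded from
  the registration masks (cost-function masking): the lesion is the main
  contrast difference against the healthy template and across timepoints.

Longitudinal ("step-wise") mode registers the first timepoint to the
template, aligns later timepoints to the first intra-subject, and composes
the transforms. Estimated accuracy on noise-free default-grid phantoms at
the tested displacement is below 0.1 deg / 0.1 voxel; across arbitrary
poses within +/-5 deg / +/-2 voxels, worst-case errors of ~1 deg remain —
with only 13 slices at 1 mm pitch the out-of-plane pose information is
intrinsically limited. These residuals visibly erode warped mask overlap
in the noisy misaligned regime (subcortical probability ~90-96 % instead
of 100 %); the forced-probability validation therefore uses the noise-free
zero-misalignment configuration, which isolates the analysis path from
registration error.

Resampling is trilinear for intensity maps and nearest-neighbour for
labels, masks and validity (guarded: trilinear on a label volume raises
unless explicitly allowed). Out-of-field voxels get fill value 0 and are
removed from every validity mask so atlas-edge voxels never enter ROI
statistics.

## Lesion analysis

Automated segmentation thresholds the quantitative T2 map at 34 ms with a
*strict* inequality (a voxel exactly at the threshold is excluded; the
boundary is thereby deterministic). The comparison direction is
configurable and defaults to "below" (infarct T2 < 34 ms), matching the
phantom's compartment layout; note that at very high field the opposite
reading (vasogenic edema raising T2 above the cut, with long-T2 CSF then
needing manual removal) is also physically plausible, which is why the
direction is a parameter rather than a constant. Thresholding happens in
native space and the binary mask is pose-normalized by nearest-neighbour:
interpolating the T2 map across the sharp lesion boundary before
thresholding measurably erodes the mask. CSF removal subtracts the atlas
ventricle labels after thresholding and is idempotent. No
connected-component or minimum-size filtering is applied by default
(available as an option).

Manual whole-brain volumetry is emulated by replaying the phantom's
ground-truth lesion, optionally perturbed by a rater-error
dilation/erosion radius and seeded boundary jitter. Volume ratios divide
the lesion voxels inside the ipsilateral (right) hemisphere by the
hemisphere voxel count; lesion voxels outside the hemisphere trigger a
diagnostic warning and are excluded, keeping the ratio in [0, 1]. No
edema/swelling correction is applied.

## Group statistics

Within-group probability maps are the voxel-wise arithmetic mean of the
binary lesion masks; every value is a multiple of 1/n. The per-ROI
"probability of infarction" is the group mean of per-subject
percent-of-ROI-infarcted, which algebraically equals the ROI average of
the probability map (tested to 1e-12) and reproduces 100 +/- 0 when every
subject fully infarcts the ROI. All summaries are mean +/- SEM with the
sample-SD (n-1) convention.

The matched-pairs Wilcoxon signed-rank test discards zero differences
(classical convention; Pratt handling is available), ranks |d| with
mid-ranks for ties, and takes W as the sum of positive-difference ranks.
For n_eff <= 12 the two-sided p is exact: all 2^n sign assignments are
enumerated in integer arithmetic (mid-ranks doubled), and
p = min(1, 2 min(P(W <= w), P(W >= w))). Beyond 12 pairs a tie-corrected
normal approximation without continuity correction is used (Var(W) =
sum r_i^2 / 4). Between-strain comparisons pair subject i of one strain
with subject i of the other in cohort order, mirroring the study's
pairwise-matched design; the matching rule is configurable in principle
but cohort order is the only one implemented.

## Pipeline

A single `PipelineConfig` (YAML-serializable, hashed over its scientific
fields only) drives simulate → map → register → segment → remove CSF →
probability maps → volumetry → ROI statistics → Wilcoxon. Artifacts are
NIfTI-1 volumes plus JSON sidecars and a results JSON whose numbers all
trace to stored per-subject values; stage failures abort with a
stage-labelled error and retain partial outputs. `render_reports` writes
four figure panels (probability, T2, CBF maps, volume-ratio bars) and two
CSV tables shaped like the study's group tables; it is purely
presentational.

## Validation strategy and problem sizes

The test suite validates each stage against independent oracles: exhaustive
(S0, T2) grid search for the T2 fit, explicit sign-assignment enumeration
for the Wilcoxon null, closed-form hand values for ADC/CBF/SEM, and
synthetic-recovery experiments for registration. Noise-free identity-pose
phantoms must round-trip every map to relative error < 1e-6. Monte-Carlo
checks (estimator bias at SNR 40, segmentation Dice over 100 seeds,
group-mean recovery over 100 cohorts) run on the full 64 x 64 x 13 grid
where per-run cost is small and on a 32 x 32 x 9 scaled-down grid (same
voxel size, smaller brain) for the 100-cohort recovery study; the
scaled-down grid preserves all compartments and contrasts while keeping
the study cheap to repeat. Group-mean recovery is judged against the
*realized* cohort ground truth (the mean of the drawn per-subject values),
which isolates pipeline error from ordinary sampling variability of the
cohort draw.

What passing these tests does *not* show about real data: the phantom has
no partial-volume mixing, no B0/B1 or susceptibility effects, no motion,
piecewise-constant compartments instead of biological texture, and a
lesion whose T2 separates cleanly from healthy tissue; threshold
segmentation is therefore exactly recoverable here but only approximately
on real relaxometry. Registration accuracy claims are specific to
intra-modality phantom contrast.

## Known limitations

* Out-of-plane rotation recovery is limited by the 13-slice, 1 mm-pitch
  geometry; worst-case noise-free errors across the +/-5 deg pose range
  are ~1 deg.
* ROI-level CBF/ADC ground truth changes discontinuously at ROI borders,
  so any residual misregistration leaks healthy-tissue values into ROI
  means; real cortex has smoother gradients.
* Magnitude-noise (Rician) floors bias ADC and CBF slightly negative at
  SNR 40 (about -1 % and -3 % respectively at the tested levels); the
  estimators are unbiased in the Gaussian/high-SNR limit.
* The 2 h volume-ratio level cannot be made consistent with the 2 h ROI
  probabilities under a single ground-truth lesion (see *Lesions* above).
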