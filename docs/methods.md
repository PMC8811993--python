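# Methods

## The measurement

Fluorescein angiography (FA) shows vascular leakage as hyperfluorescence
that appears in late frames but not in early ones.  `faleak` quantifies
leakage in eyes with branch retinal vein occlusion (BRVO) from a single
pre-treatment frame pair — one frame ~1 min and one ~5 min after dye
injection — as follows:

1. **Alignment.** The 5-min frame is registered onto the 1-min reference
   with scale/rotation-invariant keypoints (SIFT), descriptor matching with
   cross-checking, and RANSAC over a similarity transform (rigid +
   optional uniform scale).  Fundus-camera inter-frame motion is small and
   rigid to good approximation; out-of-field pixels are zero-filled.  The
   5-min frame moves because the subtraction in step 5 is defined in the
   1-min frame's coordinates.
2. **Background removal.** A rolling ball of radius 50 px is rolled under
   each intensity surface; the envelope is subtracted.  This removes the
   smooth illumination/vignetting gradient while preserving vessels and
   focal hyperfluorescence.
3. **Fovea-centred crop.** A 384×384 px window centred on the manually
   supplied foveal centre.  This is the pipeline's only manual input.
4. **Auto-threshold and binarize.** Each cropped frame is thresholded with
   the iterative-intermeans ("Default"-dialect) rule — the fixed point
   `t = round((mean(values ≤ t) + mean(values > t)) / 2)` on the 256-bin
   histogram — and mapped to {0, 255}.  By default the threshold is
   computed per frame; a shared-threshold variant (both frames binarized at
   the 1-min threshold) is available in `QuantifyConfig`.
5. **Leakage map.** Pixelwise clamped subtraction `max(b5 − b1, 0)`:
   pixels hyperfluorescent at 5 min but not at 1 min.
6. **Regional scores.** The mean gray value (MGV) of the leakage map over
   two nested fovea-centred squares: parafoveal 120×120 px and perifoveal
   240×240 px (≈ the central 3 mm and 6 mm of the macula at this camera's
   sampling).  On a {0, 255} map the MGV equals 255 × (leak-pixel
   fraction), so it is a calibrated leak-area measure in gray-level units.

Two graders repeat the procedure (differing only in the fovea pick); their
scores are averaged.  Eyes are labelled *responsive* (< 5 anti-VEGF
injections in year one) or *refractory* (≥ 5, or persistent edema after
three monthly injections), and the scores are evaluated as predictors of
that label with Mann–Whitney AUCs, DeLong variances and paired DeLong
contrasts against pre-treatment central retinal thickness (CRT), plus a
backward-stepwise logistic model over the baseline predictors that differ
between groups at p < 0.05.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| rolling-ball radius | 50 | px | large vs vessel calibre (~5–15 px), small vs the illumination gradient; removes the latter only |
| crop size | 384 | px | central field around the fovea at 768×768 acquisition |
| region sizes | 120 / 240 | px | parafoveal / perifoveal macular windows |
| SIFT `min_matches` | 10 | correspondences | below this the similarity fit is unreliable → `AlignmentError` (callers may fall back to identity) |
| `p_stay` | 0.05 | — | Wald-removal threshold of the backward elimination (0.10 selectable) |

Numerical conventions: images are uint8 `(row, col)` arrays; crops use the
half-open convention `[c − s//2, c + s//2)` so nested crops compose
exactly; binarization is strict (`> t`); thresholds on constant images
raise rather than guess; when bin 0 or 255 holds more than half of all
pixels the saturated bin is ignored by the threshold iteration (reverting
to the full histogram if trimming leaves nothing to separate);
reports round p-values to 3 decimals ("< 0.001" below that) and scores to
1 decimal so repeated runs are byte-identical.

The perifoveal window is the full 240×240 square (the 120×120 parafoveal
square is a subset), matching how the nested crops are scored; an annulus
variant (`RegionSpec(..., annulus_inner_px=120)`) exists for sensitivity
analyses.  The stated pixel→mm equivalences are treated as metadata; all
computation is in pixels.

## Statistics

* `empirical_auc` — Mann–Whitney estimator, ties counted one-half;
  refractory is the positive class.
* `delong_variance_and_ci` / `delong_paired_test` — DeLong structural
  components; normal 95% CI clipped to [0, 1] (a logit-scale CI is not the
  default since the published CIs do not disclose their scale).
* `binormal_auc` — Φ(Δμ/√(σ₁²+σ₂²)); the analytic bridge from group
  moments to an implied AUC.
* `icc_agreement` — ICC(2,1): two-way random effects, absolute agreement,
  single measure, from the two-way mean squares.
* `two_sample_t` — Student's pooled test (the conventional default of
  clinical statistics packages); Welch behind a flag.
* `chi_square_2x2` — Pearson, df = 1, no continuity correction: the
  uncorrected test reproduces the published sex-distribution p (0.851);
  the Yates-corrected one does not.
* `backward_stepwise_logistic` — maximum-likelihood fits (statsmodels),
  removing the worst Wald p > `p_stay` each round.  (Quasi-)separated fits
  fall back to a Newton solver with a small L2 penalty (intercept
  unpenalised) and Wald statistics from the inverse penalised Hessian,
  flagged in the trace.

## What the synthetic data emulates — and what it does not

`synthetic.generate_fa_pair` renders: a smooth radial + linear background
(exercises the rolling ball), a branching random-walk vessel tree with
Gaussian cross-section (supplies keypoints and threshold structure — it
only needs to *behave* like vessels, not be anatomically faithful),
focal Gaussian leakage blobs whose amplitude grows between timepoints,
i.i.d. Gaussian sensor noise per frame, and an optional rigid inter-frame
motion.  The ground-truth leak mask is the set of pixels whose quantized
value increases between the noise-free, motion-free renderings, so on
clean scenes `frame_5min > frame_1min` equals the mask exactly.

It does **not** model dye-transit kinetics, capillary non-perfusion,
haemorrhage masking, photoreceptor shadowing, or non-rigid distortion.
Passing tests therefore demonstrate that the *operators* behave correctly
and that the end-to-end pipeline separates leakage severities under
controlled conditions — not that the scores are clinically valid on real
angiograms.

Scenario presets: `responsive_scenario` (3 small dim blobs within 70 px of
the fovea), `refractory_scenario` (9 large bright blobs within 110 px),
`extramacular_scenario` (heavy leakage placed entirely outside the 384 px
analysis crop — the occlusion-far-from-the-macula presentation in which
whole-image leakage is large but macular scores stay low).

`synthetic.generate_cohort` draws every continuous covariate from a normal
at the published group moments truncated at zero (non-negative physical
quantities; logMAR is left untruncated since negative acuities are valid).
The normal family is an assumption — the source tables give only
mean ± SD — and is recorded in the generated-data JSON sidecar.  Injection
counts follow the grouping rule by construction (responsive uniform on
1–4; refractory a rounded zero-truncated normal at (5.9, 1.6) floored
at 5), so generated labels and `classify_response` agree exactly.  Grader
replicates add independent N(0, σ) noise with σ defaulting to 6.4
(parafoveal) and 2.7 (perifoveal) gray levels, calibrated so the simulated
inter-grader ICCs match the study-level agreement (≈ 0.92 / 0.97).

## Known behaviours and limitations

* **Adaptive thresholds are not monotone in leak amplitude.**  With one
  threshold per frame, brightening the 5-min blobs raises that frame's
  threshold, which can *shrink* the binarized blob fringe at extreme
  amplitudes (measured: amplitude 130→160 moves the threshold 32→49 and
  lowers the parafoveal score 43.9→33.8).  At a fixed operating point
  (shared threshold) the score is strictly non-decreasing in amplitude.
  This is a property of the method, not a bug.
* **Sensor noise creates a leakage-map floor.**  Independent per-frame
  noise flips near-threshold pixels differently in the two frames, giving
  a few gray levels of MGV even with zero macular leakage.  Region
  locality is therefore exact only on clean scenes; on noisy scenes
  extramacular leakage still scores far below genuinely macular leakage.
* **Rolling-ball idempotence** holds within 2 gray levels on smooth
  content; on very rough scenes even the exact ball-opening drifts by ~3
  on a second pass.
* The fast background subtraction uses the classical
  shrink–smooth–roll–expand approximation (block-minimum downscale by a
  radius-dependent factor, exact ball roll on the small copy, bilinear
  expand, clip to the image); it stays within ≈ −1/+9 gray levels of the
  exact ball opening with mean |error| ≈ 1.
* 10-/15-min timepoints are accepted as inputs (any frame pair can be
  quantified) but are outside the validated path.

## Problem sizes used by the test and acceptance runs

Chosen to keep full runs fast while leaving no estimator under-sampled:
AUC reproduction averages 10,000 replicate 47-vs-42 cohorts per predictor;
threshold/AUC oracle equivalences use 1,000 random 32×32 images and 200
random score vectors; the DeLong check uses a 10,000-replicate permutation
oracle at n = 30; ICC and stepwise recoveries use 500 replicates at
n = 89; the end-to-end separation suite scores 50 seeded scene pairs at
512×512 (alignment exercised separately on 768×768 frames, where recovery
is ≤ 0.1 px and ≤ 0.02°).
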