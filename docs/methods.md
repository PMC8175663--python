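# Methods

This note documents the models, the numerical choices, and what the
synthetic cohorts do and do not establish.

## Trilinear PLS (NPLS)

For subjects *s* = 1…S with brain matrices **X**ₛ (V1 × V2) and behavior
vectors **y**ₛ (B × 1), the fitter maximizes the sample covariance of the
latent scores *c*ₛˣ = **w**ˣ¹ᵀ**X**ₛ**w**ˣ² and *c*ₛʸ = **y**ₛᵀ**w**ʸ over
unit-norm weight vectors. Choices:

- **Centering.** Every tensor entry is mean-centered across subjects, and
  so are the behavior columns (disable with `center=False`). The sample
  covariance in the objective is undefined without some centering
  convention; per-entry mode-0 centering is the standard one for
  multiway data. A useful corollary: entries that are constant across
  subjects — such as the retained insula self-correlations, which equal 1
  for everyone — carry exactly zero variance after centering and therefore
  zero weight influence. They are kept in the 12 × 246 submatrix for
  dimensional fidelity and are not special-cased.
- **Algorithm.** Alternating least squares: with *c*ʸ fixed,
  **w**ˣ¹ ∝ Σₛ *c*ₛʸ **X̃**ₛ**w**ˣ², then the symmetric **w**ˣ² step, then
  **w**ʸ ∝ **Ỹ**ᵀ*c*ˣ; iterated until the relative change in covariance is
  below `tol` (default 1e−10, `max_iter` 500 with a warning on
  non-convergence). The covariance is non-decreasing across sweeps and the
  test suite asserts this per iteration.
- **Initialization.** Deterministic, no RNG: **w**ˣ² starts at the top
  right-singular vector of the behavior-weighted contraction
  M₀ = Σₛ *c*ₛʸ **X̃**ₛ (projected orthogonal to earlier components). For
  B = 1 the global optimum *is* the leading singular pair of M₀, so ALS
  starts in the right basin and converges in a couple of sweeps; a plain
  tensor-unfolding start can stall for hundreds of iterations when the top
  two singular values of M₀ nearly tie.
- **Oracle.** For B = 1 the fitted covariance must equal the top singular
  value of Σₛ ỹₛ**X̃**ₛ/(S−1) and the weights its singular vectors; the
  acceptance suite checks 100 random instances at 1e−8 / cosine 1e−6.
- **Sign convention.** cov(*c*ˣ, *c*ʸ) ≥ 0, then a joint flip of
  (**w**ˣ¹, **w**ˣ²) — which leaves *c*ˣ unchanged — makes the
  largest-magnitude whole-brain salience positive. Direction (e.g. whether
  the concussed group sits high or low) is interpreted downstream, so a
  planted negative coupling appears as a flipped weight pair, not a
  negative covariance.
- **K > 1.** Later components enforce weight-vector orthogonality by
  Gram–Schmidt inside the ALS updates (residual-matrix deflation is the
  alternative; orthogonality was chosen because the model statement
  constrains the weight vectors themselves). The two-block `fit_pls` uses
  the SVD of the cross-covariance and rank-1 score deflation.

## Bootstrap inference

Subjects are resampled with replacement (X/Y rows paired), the model is
refitted, and each replicate is sign-aligned to the full-sample solution by
the sign of its inner product with the full-sample whole-brain salience —
flipping both tensor-mode weights jointly so replicate scores are
preserved. Element-wise BSR = bootstrap mean / bootstrap SE (the
point-estimate-over-SE variant used elsewhere in the PLS literature is not
the default here), p = 2(1 − Φ(|BSR|)), and Benjamini–Hochberg FDR at
q = 0.05 applied **jointly** over the concatenated (**w**ˣ¹, **w**ˣ²)
elements of a component (`fdr_family="per-block"` is available; the choice
of family is genuinely open and the joint family is the more conservative
default for the 12 + 246 elements). Replicates that fail to fit are
dropped and counted; more than 10% failures aborts. Empirical bootstrap
p-values are two-sided with a 1/n_boot floor.

Score-on-score regressions are ordinary least squares with subject
bootstrap for the CI/BSR/empirical p; covariates (age, sex, history of
concussion) are partialled from both sides (Frisch–Waugh), so the reported
slope is the adjusted coefficient. The covariate sensitivity check
bootstraps the *difference* between the adjusted and unadjusted slope on
shared resamples.

## Clinical scoring

- Normal scores use mid-ranks and the (r − 0.5)/n rankit convention
  (Φ⁻¹ applied to mid-rank quantiles); r/(n + 1) is available since both
  conventions are standard and the choice is not otherwise pinned down.
  Constant input degenerates to all-zero scores with a warning.
- z(SYM) and z(COG) are referenced to the concussed cohort; control
  subjects are mapped through the concussed cohort's empirical quantile
  map (clipped away from 0 and 1), so controls are expressed on the
  concussed z-scale rather than their own.
- The COG composite is the first principal component (eigendecomposition
  of the 4 × 4 covariance of transformed, centered subtests), sign-fixed so
  the loading sum is positive (larger COG = slower). Bootstrap replicates
  are sign-aligned to the full-sample loadings before forming CIs; the
  bootstrap pools both cohorts, matching how the component is fitted.
- The six cognitive symptom items default to their standard positions
  (10, 11, 12, 13, 14, 16, 1-based) in the 22-item checklist and are
  configurable.

## Outlier screen

The screen is a documented stand-in (the reference procedure is not
public): features are projected onto their top principal components, a
robust Mahalanobis distance is formed with per-component median/MAD
scaling, and each subject receives a leave-one-out empirical p — its rank
among the other subjects' distances — flagged at p < α. Being rank-based,
it always flags roughly the top α fraction; the pipeline therefore uses a
stricter default (α = 0.01) than the function's own default, which on a
195-subject cohort flags about one subject. Flags are invariant to global
rescaling of the features. Method metadata is embedded in the report.

## Diffusion follow-up

One-response PLS of masked voxel values against network expression scores;
the voxel salience is proportional to the voxelwise covariance map (an
oracle identity checked in the tests). Significant voxels (joint BH at
q = 0.05 on salience BSRs) are grouped by face connectivity
(6-neighborhood; 18/26 available) and clusters under 3 voxels are removed.
Cluster volume is voxel count × |det| of the affine's linear part; the peak
BSR is the signed value of maximum magnitude, so an FA-decreasing cluster
reports a negative peak. Under the cov ≥ 0 sign convention the
diffusivity-score regression slope is non-negative; the *direction* of a
diffusion effect lives in the salience signs, not in the slope.

## Synthetic cohorts

The generator emulates the study conditions the pipeline was built for:
136 controls and 59 concussed athletes.

- **Subtests.** Log-normal marginals matched to published medians/IQRs
  (SRT ~262 ms, CRT ~363 ms, TMT-A ~16 s, TMT-B ~32 s for controls), a
  shared slowness latent with loading 0.62 per subtest (giving the first
  principal component ≈ 54% of subtest covariance), and additive concussed
  shifts (11.3 ms, 22.9 ms, 1.65 s, 3.65 s).
- **Symptoms.** Zero-inflated: controls are 0 w.p. 0.6 else 1 + Poisson(0.8)
  (median 0, IQR [0, 1]); concussed are 0 w.p. 0.1 else a rounded
  log-normal exp(1.9 + 1.4 z) with z loading 0.35 on the slowness latent
  and 0.80 on a latent mismatch variable — yielding median ≈ 6,
  quartiles ≈ (2, 16) and a weak SYM–COG Spearman ρ ≈ 0.21–0.23. Item-level
  ratings are allocated unit-by-unit over the six cognitive items
  (cap 6 each).
- **Connectivity.** Latent time series (T = 191): six community signals
  with per-subject community-strength jitter (SD 0.5), parcel-specific
  noise, and a planted coupling signal h(t) expressed by the insula with a
  fixed smooth profile **u** and received by a sparse signed whole-brain
  pattern **v** scaled by the subject coupling
  sᵢ = −0.5·group(±1) + 0.15·mismatchᵢ + 0.03·ε. Correlation of the series
  yields valid (PSD, unit-diagonal) matrices with an approximately rank-1
  modulation ∝ sᵢ**u****v**ᵀ of the insular submatrix. The community
  jitter matters: without low-rank between-subject variability, PLS
  overfits i.i.d. sampling noise and the in-sample mismatch R² triples;
  with it, the default conditions give in-sample R² ≈ 0.10–0.14 and the
  full-cohort discriminant fit recovers (**u**, **v**) at combined cosine
  ≈ 0.95 (median over 20 seeds).
- **Mismatch is latent.** The same latent drives symptom inflation and
  connectivity coupling, so the observable z(SYM) − z(COG) *correlates
  with* (≈ 0.6) but never equals the planted score — recovery tests
  therefore exercise the full indirect measurement chain.
- **Diffusion.** 24³ voxels at 3 mm; WM is a central ellipsoid with
  baseline FA ≈ 0.45–0.50 (above the 0.30 mask threshold) and
  MD ≈ 7.5–8.0 × 10⁻⁴ mm²/s. Planted face-connected clusters add
  slope·sᵢ + noise per voxel, FA slope −0.05 (noise 0.015), MD slope
  +1.5 × 10⁻⁴ (noise 5 × 10⁻⁵), i.e. FA falls and MD rises with the
  planted score, with FA the cleaner effect.
- All draws come from explicitly passed, stage-keyed generators; identical
  specs (including seed) are bit-identical, and no global RNG state is
  touched.

### What the synthetic results do not show

The generator plants a single rank-1 effect in otherwise stationary
Gaussian series; real resting-state data have autocorrelation, motion and
physiological structure, non-Gaussian tails, and many overlapping
components. Passing recovery tests demonstrates that the estimator and its
inference machinery behave correctly under the stated conditions — not
that effects of this size are detectable in arbitrary real cohorts.
Notably, at the default (deliberately weak) mismatch coupling the fitted
concussed-only network score correlates only ≈ 0.2 with the planted score,
so the end-to-end diffusion stage driven by that fitted score is
underpowered and may report no clusters; the diffusion machinery is
validated against the planted network scores directly, which is the
module's intended testing mode.

## Problem sizes

The test suite and acceptance script run the full 195-subject,
246-parcel, 191-timepoint conditions for recovery (20 seeds) and scaled
cohorts (60 subjects, 80 parcels) for the 50-seed null calibration; these
sizes were chosen so the whole validation cycle completes in about a
minute while keeping the recovery checks at study scale.
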