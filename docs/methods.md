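# Methods

This note documents the models and procedures implemented in `facehouse`,
the choices made where the design was genuinely open, and what the
synthetic-data results do and do not demonstrate about real data.

## Synthetic cohort

The generator emulates a population-based cohort of 8–11-year-olds with
four social-competence subscales, per-emotion labeling accuracy and median
correct-trial reaction times.  Every bounded score is drawn from a
two-moment family whose parameters are solved so that, with no planted
effects, the population mean and SD equal the cohort's published
descriptive statistics (SDQ prosocial 8.49/1.69 and peer problems
1.07/1.56 on 0–10; IRI perspective taking 14.37/4.96 and empathic concern
18.44/4.40 on 0–28; accuracy per emotion on 0–8, e.g. happy 7.64/0.62):

* **SDQ subscales — beta-binomial on 0–10.**  Both subscales are strongly
  skewed and overdispersed relative to a binomial, exactly the regime the
  beta-binomial covers; (α, β) follow in closed form from the mean and the
  intraclass correlation ρ.
* **IRI subscales and accuracy — rounded-clipped normal.**  The observed
  score is `clip(round(N(μ_L, σ_L)), 0, hi)`; (μ_L, σ_L) are found by
  root-finding on the exact discretized moments.  This family was chosen
  over the beta-binomial for accuracy because the angry-face moments
  (4.28, SD 1.40 on 0–8) are slightly *under*-dispersed relative to a
  binomial, which no beta-binomial can represent, while the happy-face
  ceiling (mean 7.64 of 8) needs substantial mass at the bound — both fit
  naturally in a clipped-normal.
* **Reaction times — per-trial lognormal, median over correct trials.**
  Each child has a target median (happy 1.9 s; other emotions 2.5 s — happy
  faces are labeled fastest; between-child log-SD 0.27 reproduces the
  ~0.7 s spread of the cohort's fearful-face distribution) and a trial-level
  log-SD of 0.25; the recorded value is the median of the child's
  `accuracy` correct-trial draws and is missing when accuracy is 0.  This
  reproduces the estimator (median over correct identifications) and the
  missingness pattern that makes RT-model degrees of freedom vary.

**Planted effects.**  Age and sex effects are applied to the per-child
*mean* of the family — `m_i = m₀ + β_age·(age_i − ā) + β_sex·(sex_i − p̄)`,
centered at the design midpoints — holding the dispersion parameter fixed.
Hence `E[score_i]` is exactly linear in age and sex, OLS recovers the
planted slope without discretization bias, and the grand mean stays on
calibration.  Effects that would push a mean outside the score bounds are
rejected.  `DEFAULT_EFFECT_PLAN` carries the cohort-scale coefficients for
all 14 behavioral outcomes, with flags marking the effects strong enough
(Bonferroni-surviving at cohort scale) for sign-recovery checks; the weak
planted effects (e.g. neutral-RT sex difference of +18 ms, t ≈ 0.3 at
n ≈ 1000) have sign-error probabilities near 40% by construction and are
deliberately excluded from those checks.

For RT, effects shift the median scale before the multiplicative
child-level factor, so the recovered slope is the planted one inflated by
`exp(τ²/2) ≈ 1.04`; sign and approximate magnitude are preserved, which is
what the downstream checks assert.

## Task design and BOLD forward model

A run is 4 blocks; each block shows the four categories (happy, fearful,
neutral faces; houses) once each as a 9-stimulus sequence (1 s stimulus +
1 s fixation → 18 s), in a seeded uniform permutation per block; a red
circle (attention check) opens the run and follows each block (5 total);
blocks are separated by 10 s rest (the protocol specifies only "a period of
rest"; 10 s keeps the default run within the 389-volume scan).  The stated
block/volume bookkeeping cannot be exactly reconciled, so the simulator
treats the number of volumes as free (default 389, TR 1 s).

The forward model is `baseline + Σ_c a_c(v)·(HRF * box_c)(t) + drift +
AR(1) noise`.  The HRF is the canonical double-gamma (SPM parameterization:
delays 6/16 s, dispersion 1, undershoot ratio 1/6), normalized to unit
time-integral and shared — one implementation — between the simulator and
the design-matrix builder, so a noiseless simulation is inverted exactly
(β recovery ≤ 1e-6, verified).  Drift is spanned by the two lowest
discrete-cosine basis functions so the 128 s high-pass removes it exactly.
Noise is AR(1) in time with stationary SD `noise_sd`.  Amplitudes live in
spherical "blobs" with per-condition values (defaults: a face-selective
site, a happy-biased site, a fear-biased site).  Motion traces are random
walks with optional injected spikes (recorded as ground-truth high-motion
frames); an optional transient signal drop (frames × region × factor)
exercises the mask-hole exclusion downstream.

## First-level GLM

Condition regressors are boxcars over *sequences* convolved with the HRF on
a 20× oversampled grid and read at frame midpoints.  Circle events are not
modeled (the protocol does not state they were; rest is the implicit
baseline).  The six realignment parameters enter as regressors; identically
zero motion columns are dropped (they carry no information and would break
full rank).  High-pass filtering is implemented as
`floor(2·N·TR/cutoff)` DCT columns in the design matrix — the
design-matrix form is software-equivalent to filtering both sides and far
easier to test.  Estimation is plain voxelwise OLS without prewhitening
(documented limitation: with AR(1) noise first-level t values are mildly
miscalibrated; group-level inference operates on contrast estimates, not
first-level t).

The signal mask keeps voxels whose temporal mean reaches 80% of the global
mean over nonzero voxels.  "Holes" are operationalized as excluded
6-connected regions not reachable from the volume border — interior signal
drops — and flag the scan for exclusion.  Outside-mask voxels carry NaN
(never 0) so segment and ROI means are not biased.

Framewise displacement is the Power form, `Σ|Δtranslation| + 50 mm ×
Σ|Δrotation|`, first frame 0; a subject is low motion when at most 30% of
frames exceed 0.3 mm.  Smoothing is a separable Gaussian
(σ = FWHM/(2√(2 ln 2)) per axis, zero padding; FWHM 0 = identity), applied
to contrast maps with NaNs zero-filled during filtering and restored after.

## Group level

One-sample t maps are computed over the intersection of subject masks;
zero-variance voxels are flagged and carried as signed infinities.
Voxel-level FWE uses Bonferroni over in-mask voxels — a deliberate,
documented desk-scale substitute for random-field FWE; the published
data-dependent extent thresholds (k = 21/27/28) are therefore not
reproduction targets.  The conjunction "voxel FWE AND cluster extent" is
read as: a voxel survives iff it passes FWE *and* lies in a cluster-forming
component (|z-equivalent| ≥ 3.1, 18-connectivity) of size ≥ k
(`mode="voxel"`; `mode="cluster"` keeps whole forming components containing
an FWE voxel).  Negative contrasts are thresholded as −t with the same
spec.  The extent threshold k can be estimated by Monte Carlo: Gaussian
white-noise fields smoothed to the analysis FWHM, standardized, thresholded
at z; k is the (1−α) quantile of the max-cluster-size null plus one.
Overlap maps report the fraction of subjects whose first-level t exceeds
1.96, one-sided per contrast direction.

## Watershed subclustering

Within each cluster, local maxima (26-connectivity; a connected equal-value
plateau is one peak seeded at its lexicographically smallest voxel) seed a
priority flood in strictly decreasing statistic order with lexicographic
tie-breaks; a voxel adjacent to several segments goes to the segment with
the higher peak (tie → smaller id).  The segmentation is therefore an exact
partition of the suprathreshold mask, deterministic, one segment per peak,
and invariant under strictly increasing transforms of the statistic (it
depends only on value order).  Flooding adjacency is 18-connectivity to
match cluster components; no prominence/size merging happens unless
`min_segment_size` is set.  With two equal mirror-image peaks the single
minimum voxel between the basins goes to the smaller segment id, so "equal
basins" holds up to that one border voxel.  Per-subject segment means
average the in-mask β values; a segment entirely outside a subject's mask
yields a missing value.

## Inference

The residual-based permutation test is two-sided via absolute values, with
p = (1 + #{|t_i| ≥ |t_orig|})/(B + 1), B = 10,000 by default, so
p ∈ [1/(B+1), 1].  Surrogates are null-model fitted values plus a full
random permutation of null residuals (rows, without replacement).  Listwise
deletion is applied before both fits, reproducing the varying degrees of
freedom of the RT models.  The original fit is delegated to statsmodels
OLS; the permutation loop is a vectorized refit of the fixed full design to
permuted-outcome batches (per-iteration equivalence with a statsmodels
refit is tested).  Its type-I error is calibrated (empirical rate in
[.03, .07] at α = .05 over 500 null datasets) and it tracks the parametric
t-test p within ±0.02 under normality.

ANOVA is one-way between-groups (the published F(4) reporting is ambiguous
about a repeated-measures design; between-groups was implemented and the
divergence noted); F is clamped at 0 against floating-point cancellation.
Tukey HSD uses the studentized-range distribution (scipy).  Bonferroni is
reported as a fixed threshold α/m (as published: .0125 for m=4, .005 for
m=10), not as adjusted p values; FDR is Benjamini–Hochberg step-up, capped
at 1.

## Association families

RT quality control excludes a child when any per-emotion median rests on
fewer than 2 correct trials *and* lies more than 10 group SDs from the
group mean (the published exemplar — a single-trial 11.6 s median, 13 SDs
out — is the canonical test case); multi-trial outliers are retained.
Behavioral families use permutation p values (the outcomes are skewed);
brain families (segment/ROI means) default to parametric p, as their
FDR-adjusted reporting implies; both are switchable.  Contrast-matched
predictors: happy>neutral uses happy measures, fearful>neutral and
fearful>happy use fearful measures, faces>houses uses valence-independent
measures defined here as total correct across emotions and the median of
the per-emotion median RTs (no published formula exists).  Children missing
a modality are dropped per analysis, not imputed.  The default ROI set is a
rectangular grid parcellation; a user-supplied NIfTI atlas is accepted but
never required.

## Orchestration and reproducibility

One master seed expands through `numpy.random.SeedSequence` into
independent per-stage streams (cohort, task order, each scan, the extent
Monte Carlo, inference), so every stage is independently reproducible and a
rerun of the same config reproduces every p value bit for bit.  Each run
writes a provenance log (config digest, seeds, estimated k, versions).
Default problem sizes for the bundled end-to-end configuration are
deliberately small (24×24×14 grids, a handful of subjects) — chosen so the
whole chain and its tests run comfortably on a laptop while every planted
feature remains recoverable; cohort-scale behavioral runs use n = 1000+.

## What passing tests do and do not show

The synthetic volumes are already aligned, have stationary Gaussian AR(1)
noise, spherical activation sites and drift inside the high-pass span; real
data add realignment error, spatially correlated and non-stationary noise,
susceptibility dropout and anatomical variability, none of which are
modeled.  Calibration results (type-I error, FDR control, sign recovery)
therefore validate the *implementation* of the statistical machinery under
its stated assumptions, not the robustness of the protocol to fMRI
artifacts.  Bonferroni-over-voxels FWE is stricter than random-field FWE at
realistic smoothness, so synthetic cluster counts are conservative and the
published cluster/segment counts and data-dependent k values are not
comparable quantities.
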