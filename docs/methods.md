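# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `langlat`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohorts

The generator (`langlat.synth`) emulates a developmental language-localizer
study with four age groups (early/middle/late childhood, adults). It is the
package's specification of the study conditions, not a disposable fixture.

**Geometry.** A 3-D grid whose first axis is left–right and has even length,
so the mid-sagittal plane falls between voxels and reflection
`i -> X - 1 - i` is an exact involution. Five disjoint spherical LH parcels
(≥ 50 voxels each; three tagged frontal, two temporal) are placed on a
collision-free lattice and mirrored into the RH (labels 6–10). Default grid
32 × 36 × 32 with 80-voxel parcels — large enough for distinct parcels and
meaningful top-10% selection, small enough that a full cohort runs in
seconds per subject on one CPU.

**Task signal.** Each localizer run is an alternating Language/Control block
design (default 6 blocks per condition, 18 s blocks, 12 s lead-in/out,
TR 2 s). The voxel time series is

    y(v, t) = 100 · [1 + Σ_c amp_c(v)/100 · x_c(t)] + ε(v, t),

where `x_c` is the boxcar ⊛ canonical HRF regressor peak-normalized to 1 and
the baseline is fixed at 100 signal units so planted amplitudes `amp_c` read
directly in percent signal change — removing any PSC-scaling ambiguity from
the tests.

**Spatial profile.** Within each LH parcel, the condition amplitudes follow a
plateau-core profile: the ~15% of parcel voxels nearest a per-subject,
uniformly jittered centre sit at exactly the nominal amplitude, with Gaussian
falloff (FWHM ≈ 3 voxels) outside the plateau. The jitter makes top-10%
selection meaningful (subjects differ in *where* the response peaks inside
the parcel, as real subjects do); the plateau guarantees that, in the
noiseless limit, the top-10% fROI average equals the nominal amplitude
exactly, which the tests exploit (recovery to 1e−6). A pure Gaussian bump
cannot provide that exactness because the selected voxels would average
profile values below the peak.

**Lateralization.** RH homotopic voxels carry the same Control amplitude as
their LH mirror but a condition *difference* scaled by `lateral_bias ∈ [0,1]`
(1 = perfectly symmetric hemispheres). The mapping from bias to the resulting
volume-based LI depends on amplitude and threshold; at the replicate-test
scale (50-voxel parcels, 1.2/0.4% amplitudes, noise SD 0.8), biases
1.0/0.9/0.85/0.72 produce mean volume LIs of roughly 0/0.13/0.24/0.49, which
is how the "planted LI rising 0 → 0.5" recovery scenario is realized. The
cohort default is 0.9 for every group: a common, age-constant hemispheric
bias in the regime of a ~15–30% excess of LH voxels.

**Noise.** Temporally autocorrelated stationary Gaussian AR(1) noise with
coefficient `noise_ar` (default 0.2) — the covariance model the first-level
GLM whitens against, and the reason suprathreshold counts calibrate exactly
(a pure-noise 1000-voxel parcel at one-tailed p < 0.001 averages ~1
significant voxel). Setting `noise_ar = 0` gives white noise; note that
whitening truly white data with an AR(0.2) filter makes *t* statistics
conservative for smooth regressors (the filter attenuates low frequencies
where the task regressor lives by ≈ (1−a)² relative to the variance estimate),
so calibration claims are always made under the matched noise model.

**Rest.** Ten latent unit-variance series drawn from a multivariate normal
whose correlation is `tanh(connectivity_z)` within each hemisphere and
`0.8 ×` that between hemispheres (a plausible default; the inter-hemispheric
level is configurable and nothing downstream depends on it). Each latent
series is broadcast to its parcel's voxels on top of baseline and AR(1) voxel
noise. Cohort defaults plant age-increasing within-hemisphere z
(0.25/0.35/0.45/0.55) and age-increasing response amplitudes
(0.8/1.0/1.2/1.5% Language), the developmental pattern the group models are
meant to detect.

**Motion.** Baseline framewise displacement ~ |N(0.12, 0.06)| clipped below
0.5 mm; a Bernoulli(`outlier_rate`) subset of volumes gets FD > 0.9 mm plus a
global-signal spike an order of magnitude above typical volume-to-volume
change, so both outlier criteria fire on the same volumes.

**Reproducibility.** Every subject's randomness comes from one RNG stream
derived from `SeedSequence(cohort_seed, spawn_key=(subject_index,))`;
cohorts are pure functions of (spec, seed), and `generate_cohort` writes
byte-identical truth JSON across reruns. Planted truth is carried on run
objects for test code only; no pipeline stage reads it.

What the generator does **not** emulate: spin-history and physiological
noise, EPI distortion, spatial smoothness of noise, anatomy/segmentation,
surface geometry, scanner drift beyond what the DCT basis models. Passing
tests therefore show the *analysis logic* is correct under the stated model,
not that it is robust to every artifact of real data.

## First-level model

- **HRF**: double-gamma, response gamma shape 6 / scale 1 (peak ≈ 5 s),
  undershoot gamma shape 16 / scale 1, ratio 1:6, scaled to unit peak, zero
  for t < 0 — the conventional canonical form.
- **Design**: condition boxcars ⊛ HRF sampled at volume times from a 0.1 s
  grid and peak-normalized; first-order temporal derivatives per condition
  (nuisance, never in contrasts); DCT drift basis with
  `floor(2·T/128 s)` columns (all components with period above the cutoff);
  one indicator column per detected outlier volume (outliers are modelled,
  not deleted, so dof bookkeeping is explicit — each indicator costs exactly
  one dof); per-run constant.
- **Estimation**: exact AR(1) prewhitening (first row scaled by √(1−a²),
  then y_t − a·y_{t−1}) of both sides, ordinary least squares per voxel,
  σ² from whitened residuals, dof = N − rank. Multi-run fits concatenate
  runs with shared condition/derivative betas and per-run drift, outlier and
  constant columns — an SPM-style multi-session model — and the "all runs
  combined" contrast used for voxel counting comes from this single GLM, not
  from averaging per-run maps.
- **Contrast scaling**: effects are rescaled by 100 / baseline (mean of the
  per-run constant betas) so they are percent signal change regardless of
  the raw units.
- **Degenerate voxels**: a voxel whose raw series is constant reports t as
  missing (NaN), never infinite. A voxel with signal but numerically zero
  residual variance (the noiseless limit) gets σ² floored at
  `eps · mean(y_w²)`, yielding a huge but finite t; this keeps the fully
  noiseless symmetry scenario well defined while preserving the "never
  infinite" contract.
- **Outlier detection**: FD > 0.9 mm or absolute volume-to-volume change of
  the spatial mean more than 5 SD above its mean. The global criterion is
  implemented as signal *change* (not level); this choice is configurable
  conceptually and flagged here because the convention differs across
  toolchains.
- **Rest denoising**: because synthetic data have no tissue segmentation,
  the nuisance series are the five leading principal components of
  out-of-parcel background voxels plus outlier indicators — same contract
  (remove shared non-neuronal variance), no anatomy. Then a frequency-domain
  band-pass mask at 0.008–0.09 Hz (which also removes the mean).

## fROIs and cross-validation

Top `ceil(0.10 · parcel size)` voxels by t, per parcel (`ceil` guarantees
non-empty fROIs in small parcels). Ties — which occur in earnest only in
degenerate maps — break by ascending flat voxel index, a deterministic rule
chosen because no principled rule exists at the cut. No significance
threshold is applied to selection; top-k fROIs behave like threshold-based
ones in practice.

Two CV folds regardless of run count: even-indexed runs define / odd
estimate, then the reverse ("odd/even collapse"); this keeps the two splits
balanced and matches the two-way averaging of the magnitude measure. A
single run is split at the block boundary nearest the temporal midpoint
(each half must retain ≥ 2 blocks per condition). Voxel counting and the
bootstrap LI use the all-runs map — counts are threshold-defined rather than
estimate-defined, so selection independence is not at stake. fROIs for rest
connectivity also come from the all-runs localizer map, since rest data are
acquisition-independent of the localizer.

The circularity control is demonstrated, not assumed: on pure-noise
cohorts, same-data selection+estimation is positively biased (sign test
across subjects) while the cross-validated estimate centres on zero; both
facts are asserted in the test suite.

## Laterality measures

- Volume LI = (LH − RH)/(LH + RH) over one-tailed suprathreshold counts
  (p < 0.001 default, 0.01 available). A 0/0 denominator yields a *missing*
  value, never an imputed 0 — degenerate subjects are excluded, not zeroed.
- Bootstrap LI: 20 thresholds equally spaced in [0, max t); at each, 100
  resamples of 25% of the suprathreshold t values per hemisphere; LI from
  the summed resampled t mass; 25% total trimmed mean per threshold;
  threshold-proportional weights for the overall LI and for the pooled
  percentile CI (2.5/97.5). These internals follow the published defaults of
  the adaptive-threshold LI toolbox tradition and are all exposed in
  `BootstrapConfig`.
- Magnitude laterality: LH − RH Language>Control PSC per homotopic fROI
  pair, kept in long format so the hemisphere × age-group interaction model
  can use it directly.

## Group models

Fit with statsmodels MixedLM (REML). Crossed random intercepts for
participants and fROIs are realized as variance components over a single
grouping column — numerically the same model lme4 fits with
`(1|subject) + (1|froi)`; the test suite cross-checks one such fit against
lme4/lmerTest via Rscript to 1e−4 on the estimate and its SE. Hemisphere
slopes within participants and fROIs enter the interaction model the same
way. Singular or non-converging fits degrade along a fixed ladder (drop
fROI terms first, then slopes, finally OLS), and the structure actually
used is recorded in every output row.

Satterthwaite degrees of freedom are not available in statsmodels; Wald
tests use a configurable df rule instead — residual df (N − p) for
within-subject contrasts like condition, and n_subjects − p for terms that
vary between subjects — with large-sample z as a further option. The
calibration tests (type-I error within the binomial band of α = 0.05 over
200 replicates; 95% CI coverage for a planted 1-PSC effect) are the
acceptance surface for this choice. Child-vs-adult pairwise comparisons use
Šidák adjustment, p_adj = 1 − (1 − p)^m over the m = 3 comparisons. The
per-subject total outlier-volume count can be appended to any model spec as
a motion covariate; zero-variance covariates are dropped with a warning.

## Problem sizes

Test and acceptance computations run at deliberately small scale, chosen as
the smallest sizes at which the statistical claims are meaningful: grids of
20 × 24 × 20 to 24 × 28 × 24 voxels with 50–80-voxel parcels, 66–120 volumes
per run, 3–6 blocks per condition, cohorts of 2–20 subjects per group, 20
replicates for family-wise error/power checks and 200 for mixed-model
calibration, 300 rest volumes for connectivity recovery (Fisher-z sampling
SE 1/√297). The acceptance script uses 6 subjects per group on a
24 × 28 × 24 grid.

## Known limitations

- No spatial preprocessing (realignment, normalization, smoothing): the
  generator emits data already on a common grid, so these stages are out of
  scope by design.
- The AR coefficient is fixed, not estimated per voxel (no ReML variance
  components); this matches the linearized-AR analysis convention the
  pipeline implements.
- The df rules are approximations; with very small cohorts (< ~5 subjects
  per group) mixed-model p values should be treated with caution and the
  interaction model may degrade to simpler random structures.
- The bootstrap-LI CI is a pooled percentile interval, not a studentized
  one; its coverage is asserted only qualitatively (symmetric maps straddle
  zero; strong lateralization excludes zero).
- Volume-based LI is sensitive to overall amplitude (higher SNR pushes more
  mirror-hemisphere voxels over a fixed threshold, shrinking LI). The
  default cohort makes this visible by design; the magnitude and bootstrap
  measures are the cross-checks.
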