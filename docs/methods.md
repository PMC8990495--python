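# Methods

This note documents the models, estimators, numerical choices and known
limitations of `gazehmm`, in the order data flow through the pipeline.

## Fixation data model

A trial is an ordered sequence of fixations (x, y, duration). Coordinates are
face-centered: origin at the midpoint between the two eye centers, x
rightward, y downward, in pixels. Faces presented at varying screen positions
are re-expressed in this frame upstream, because the regions of interest the
models discover are anatomical (eyes, nose, forehead), not screen-anchored.
Durations are carried through I/O and the data model but never modelled: HMM
emissions are positions only. Tables on disk are plain CSV, one row per
fixation, with 1-based `fix_index` within trial.

## Person-specific HMMs (VBEM)

Each participant-condition's sequences are modelled by a K-state HMM with 2-D
Gaussian emissions. Fitting is variational Bayesian EM with conjugate priors:

* Dirichlet(α₀) on the prior vector and on each transition row; α₀ = 1
  (uniform, adds one pseudo-count per entry).
* Normal–Wishart on each state's (mean, precision): prior mean at the face
  center with strength β₀ = 0.01 (negligible pull), Wishart dof ν₀ = 5 and a
  scale chosen so the prior expectation of each ROI covariance is a quarter
  of the face box per axis (default box 320 × 400 px → prior sd 80/100 px).
  Weakly informative: it regularizes tiny or empty states without moving
  well-populated ones.

The E-step runs scaled forward–backward under the expected-log parameters,
batched over sequences of equal length; the lower bound is the sum of the
per-sequence log-normalizers minus the Dirichlet and Normal–Wishart KL terms,
and is checked (and tested) to be non-decreasing across iterations.
Initialization is a k-means hard labelling of the pooled fixations; restarts
(default 5) differ in the k-means seed, and the best bound wins. Convergence:
bound change < 1e−6 or 300 iterations. The returned point estimate uses
posterior means (Dirichlet means for π/Ψ, posterior mean for μ, inverse-
Wishart mean for Σ). States whose expected occupancy falls below 1e−3
fixations are pruned, so the effective K can be below the requested one —
this mirrors the automatic-selection behavior of variational Bayes.

Model selection refits each candidate K (default range 1–10) independently
and keeps the highest bound; ties within 1e−8 go to the smaller K. All
randomness flows from explicit integer seeds; identical inputs and seed are
bit-for-bit reproducible. Decoding uses the max-product (Viterbi) recursion
with ties broken toward the lower state index.

## Representative patterns (hierarchical EM over HMMs)

Individual HMMs are clustered into C group HMMs (C = 2 throughout the
face-recognition analysis; the group state count is the integer median of the
individual Ks, half-integers rounded up). The algorithm never revisits raw
fixations: it maximizes a variational lower bound on the expected
log-likelihood of length-τ sequences generated by each input model under
each group model, computed in closed form. The per-pair bound uses the
expected Gaussian cross log-density

    E_{x~N(μ_ρ,Σ_ρ)}[log N(x; μ_β, Σ_β)]
      = −½ [d log 2π + log|Σ_β| + tr(Σ_β⁻¹Σ_ρ) + (μ_ρ−μ_β)ᵀΣ_β⁻¹(μ_ρ−μ_β)]

inside a backward recursion over state correspondences, and the same
recursion yields expected start/transition/occupancy statistics for the
closed-form M-step. τ = 10 and a virtual-sample weight of N = 1000 per model
are the defaults; N scales each model's weight in the cluster
responsibilities. The objective (sum of per-model log-mixture bounds plus
Dirichlet/inverse-Wishart penalties matching the M-step pseudo-count 1 and
covariance ridge 1 px²) is a generalized-EM target and non-decreasing across
iterations.

An earlier Monte-Carlo variant that actually sampled virtual sequences was
discarded: with practical sample counts the noisy objective rewarded
clusters that overfit the sampling noise, and archetype recovery was
unreliable. The closed-form bound is deterministic and recovers planted
two-archetype populations in essentially every seeded replicate.

Initialization fits one global group (pooled ROI geometry via weighted
k-means over all input Gaussians), summarizes each input model by its
expected start/transition fingerprint under that global group, k-means the
fingerprints into C clusters, and builds initial groups from the cluster
members. This separates models that differ in scanpath dynamics even when
their ROI geometry is nearly identical. Restarts rerun the whole
initialization. Models are processed in a canonical parameter order, so the
result is invariant to the order callers list them (up to relabelling).
Emptied clusters are re-seeded from the worst-explained model up to three
times; persistent emptiness (e.g. all inputs identical) is flagged
`degenerate` and the empty cluster mirrors the dominant one so downstream
code sees well-formed output.

Labelling of the two clusters as Pattern A/B is a documented convention:
A is the group model with the higher conditional entropy h₂|₁ (the broader,
exploratory pattern), B the more consistent one; exact ties fall back to
cluster size, then to the first model's cluster.

Pattern separation tests whether participants' data prefer their own
pattern: per participant, the mean per-sequence log-likelihood under both
patterns; the F statistic is the one-way comparison of the (ll_A − ll_B)
difference between the two assignment groups, with partial η² and a 90%
noncentrality-inversion CI. Groups with fewer than two members raise an
error rather than report an unstable statistic.

## Gaze metrics

The A–B scale is (A − B)/(|A| + |B|) with A, B the *means* of per-sequence
log-likelihoods (means, not sums, so the scale is comparable across unequal
trial counts); it is antisymmetric under pattern swap and confined to
[−1, 1]. The degenerate case A = B = 0 is defined as 0 and flagged.
Entropies are computed from fitted model parameters (not decoded label
frequencies): h₁ from the prior, h₂|₁ as the prior-weighted transition-row
entropy, h₃|₂ the same under the one-step state distribution πΨ. Base-2 by
default, natural log available. The 0·log 0 := 0 convention applies.

## Behavioral statistics

* d′/criterion: equal-variance SDT, default 1/(2n) correction for rates of
  0 or 1 (`correction="none"` raises instead). RT summaries are means of
  correct trials, untrimmed by default.
* 2×2 within-subject ANOVA via difference-score contrasts; each effect's F
  is exactly the square of the paired t on its contrast, partial
  η² = F/(F + df_error) with a 90% CI by noncentral-F inversion
  (η² = λ/(λ + df₁ + df₂ + 1)).
* Paired contrasts report Cohen's d = mean(diff)/sd(diff) with a 95%
  noncentral-t CI.
* Correlations: Pearson; partial correlations by the residual method (both
  variables regressed on the covariates with intercept; df = n − 2 − k).
* Flanker effect: (I − C)/(I + C).
* Required sample size for a multiple-regression F test: smallest N whose
  noncentral-F power (numerator df = predictors, denominator df = N − p − 1,
  λ = f²·N) reaches the target; a doubling bracket plus binary search with a
  final backward walk guards the rare non-monotone corner at tiny df.
* No multiple-testing correction is applied anywhere; the planned-contrast
  structure is reported as-is.

## Synthetic studies and planted ground truth

The generator emulates a 2×2 within-subject masked-face recognition design:
88 participants × 8 blocks, 16 learning trials and 32 recognition trials per
block, four target faces per mask condition per block with matched foils,
Latin-square rotation of faces through conditions across participants, and
lighting/mask-color labels carried as metadata only. The default design
consumes 8 × 32 = 256 unique face identities. Learning exposure is 5 s;
learning-trial fixation counts are truncated-Poisson with mean 15 (range
3–25), recognition trials mean 6 (range 2–15) — self-terminating trials are
shorter. These count distributions are conventions; empirical fixation-count
distributions are not modelled.

Eye movements come from two archetype generators sharing a three-ROI layout
(broad center, eye band, forehead) with the eyes-focused archetype's eye ROI
tighter and higher and its forehead ROI larger. Pattern A starts broad and
wanders; Pattern B starts broad, switches to the eyes with probability .97
and stays there (self-transition .96). Participants get perturbed copies
(mean jitter sd 8 px, Dirichlet-resampled transition rows, log-normal
covariance scaling, all scaled by `perturb`); `perturb=0` reproduces the
prototypes exactly. Condition-specific generators encode the planted
structure:

* learning-phase models are identical for masked and unmasked faces (no
  planted learning-phase difference);
* recognizing masked faces (um, mm) pulls the generator 0.35 of the way
  toward Pattern B and tempers transition rows with exponent
  1 + 2.5·consistency_gain (prior untouched, so first-fixation entropy shows
  no planted effect);
* recognizing unmasked faces learned masked (mu) pulls toward Pattern B by
  0.8·strategy_shift.

Behavior follows equal-variance SDT with condition d′ = base + offset +
coupling·(trait − trait mean); offsets (uu 0, um −.38, mu −.42, mm −.32)
encode the group-level impairment with mismatch worst, and the coupling
slopes (2.0 d′-units per unit trait for both strategy→mu and
consistency→um, trait sd 0.3) plant the individual-difference effects:
participants who adjust more are impaired less. The slopes were calibrated
once so the planted couplings are decisively detectable at the design's own
measurement noise (32 old + 32 new trials per cell gives a d′-difference sd
near 0.5), giving replicate-level correlations near −0.27 (A–B change × mu
impairment) and −0.22 (h₃|₂ change × um impairment) — the same order as
typical empirical strategy–performance correlations. Cognitive covariates share a latent
factor with the consistency trait (loading .35; .15 for strategy), so
partial-correlation analyses have testable ground truth. RTs are log-normal
with small shifts for masked recognition and errors. Foils carry no
identity-level memory signal. One integer seed makes dataset files
byte-identical.

What passing on this generator does *not* show: the generator plants
Gaussian ROIs and first-order Markov dynamics, i.e. exactly the model class
being fitted, so recovery results certify the estimation machinery, not the
adequacy of HMMs for real scanpaths. Real eye-tracking data add calibration
drift, saccade-detection noise, non-stationarity within trials, and
duration/pupil structure that this package deliberately leaves out of scope.

## Pipeline

Per participant the pipeline fits 2 learning-phase and 4 recognition-phase
HMMs, clusters each phase's models separately into two patterns, scores A–B
and entropies per cell, summarizes behavior, and runs the 2×2 ANOVAs, the
three planned mask-use contrasts (mu, um, mm vs uu) for every dependent
variable, and the strategy-change × performance-change correlations with and
without covariate partialling. Cells with fewer than 10 sequences are
excluded from eye-movement (never behavioral) analyses and logged; input
trial counts always equal analyzed + excluded. Reports contain no
timestamps, so a rerun with the same config is byte-identical. The paper-
conventional pooled degrees of freedom sometimes seen in this literature
(e.g. follow-up t tests with df ≈ 2n) are not reproduced; paired contrasts
use df = n − 1.

## Problem sizes used in the shipped checks

The library defaults are the full study conditions (88 participants, ROI
range 1–10, 5 restarts). The shipped test suite and the acceptance script
run the end-to-end pipeline at 16 (script) or 16/12 (suite) participants
with ROI range {2,3,4} or {2,3} and 2 restarts, recovery simulations at the
sizes stated in their docstrings (60 trials × 10 fixations for VBEM; 40
models for VHEM; 20 seeds each), and the replicate sign-recovery study at
the full n = 88 via the responses-only simulation path with eye-movement
change scored from the generating models. These sizes are the package's own
choices for routine validation; all are raised by changing one config
object.

## Known limitations

* Emissions are stationary within a trial; no duration, pupil or saccade
  modelling; no input–output or hierarchical-participant HMM variants.
* The VHEM E-step is a lower bound, not the exact expected log-likelihood;
  like all EM-type procedures both fitting layers find local optima, managed
  by restarts and the fingerprint initialization.
* Entropy measures derive from the fitted model, so model misspecification
  propagates into consistency scores.
* The statistics layer implements the analyses this design needs
  (difference-score ANOVA, paired t, partial r); it is not a general
  mixed-model toolbox.
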