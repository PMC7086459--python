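# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the known limits of what the tests demonstrate.

## Problem setting

A two-class stream of per-trial feature vectors `x ∈ R^D` is classified
online.  During the training phase the input distribution is stationary
and labels are available; during the evaluation phase labels are withheld
and the input marginal `P(x)` may shift at unknown change points while the
conditional `P(y|x)` is preserved (covariate shift).  Every prediction is
prequential: trial `i` is predicted before anything learned from trial `i`
can influence the model.

## Signal path (raw EEG)

* **Filter bank.** Ten overlapping 4-Hz Butterworth band-pass filters,
  8–12 … 26–30 Hz, band-pass order 8 (four pole pairs), applied
  forward–reverse (`sosfiltfilt`) for exactly zero phase.  Reflect padding
  spans the whole trial because a 4-Hz-wide band at 250 Hz rings for
  hundreds of samples; windows are cut *after* filtering so edge
  transients never reach the analysed segment.  The forward–reverse
  identity `filt(reverse(x)) = reverse(filt(x))` holds to ~1e-7 relative
  error — the residual is float64 noise from the near-unit-circle poles,
  not phase distortion.
* **Windowing.** The motor-imagery window is `[cue, cue+3 s)`, half-open,
  first sample `floor(t·fs)`, 0-based; at 250 Hz that is exactly 750
  samples.  Labels are never reordered by any preprocessing step.
* **CSP.** Per band, per-trial spatial covariances `C·Cᵀ/trace` are
  class-averaged (ridge `1e-8·I` guarantees positive definiteness; a
  Ledoit–Wolf-style shrinkage fallback engages only on failure) and the
  generalized eigenproblem `Σ̄₁ w = μ (Σ̄₁+Σ̄₂) w` is solved.  Rows of `W`
  are ordered by descending eigenvalue for class ω₁ and satisfy the
  whitening identity `W(Σ̄₁+Σ̄₂)Wᵀ = I` to 1e-8.  Each filter is scaled so
  its largest-magnitude coefficient is positive, making the output
  independent of the eigensolver's sign conventions.  `h = 2` extreme
  pairs are retained by default (configurable); features are the
  normalized log-variances, so `exp(features)` sums to one within a band
  and trial scaling cancels exactly.
* **PCA for monitoring.** Fitted on training features only and frozen; the
  smallest component count reaching 90% cumulative variance is kept.  The
  detector runs in this reduced space; classifiers use the full
  concatenated features — the reduction exists to keep the multivariate
  monitor well-conditioned, not to help classification.

## Shift detector

* **λ selection.** Grid {0.00, 0.01, …, 1.00}, minimizing the summed
  squared 1-step-ahead prediction errors over all monitored components;
  ties take the smallest λ, and a constant series returns 0 with a
  warning.  The smoothed state is initialized at the training mean and
  left at the end of the training pass, so streaming continues seamlessly.
  On serially independent features the argmin is λ = 0 (predict the mean);
  autocorrelated series select larger λ.
* **Stage I.** A warning fires when `|x_j(i) − z_j(i−1)| > L·σ_e,j` on any
  monitored component (OR rule), with `σ_e,j` the training residual SD.
  The general-purpose default is `L = 3`.  For short streams where a
  shift of ~2 pooled SDs must be confirmed within ~10 trials, the
  *prompt-detection profile* uses `L = 1.6` and a Hotelling window
  `n_w = 10`: a 2-SD prediction error then warns with per-trial
  probability ≈ Φ(2−1.6) ≈ 0.65, giving several stage-II attempts inside
  the budget, while the ~11% per-trial false-warning rate is screened by
  stage II at level α.  The profile was fixed by this normal-theory power
  analysis plus a design-time simulation grid before the test suite was
  frozen.
* **Stage II.** Hotelling's `T² = (n₁n₂/(n₁+n₂))·d̄ᵀS⁻¹d̄` with the exact
  F transform `F = (n−p−1)/(p(n−2))·T²` on `(p, n−p−1)` degrees of
  freedom (`n = n₁+n₂`); the pooled covariance is ridge-regularized only
  when singular, and the event records that.  Sample A is the `n_w` most
  recent trials ending at the warning (padded from the reference tail very
  early in the stream); sample B is `n_w` trials drawn, seeded, from the
  *current training pool*.  Identical windows give `T² = 0, p = 1`; in one
  dimension `T²` equals the pooled two-sample t² exactly.
* **Reference semantics.** The reference pool is *not* re-anchored by the
  detector: a persisting shift keeps re-validating against the training
  data, and only when the adaptive learner merges post-shift trials into
  the pool (`CseDetector.update_reference`) does detection quench — the
  system has adapted.  This coupling is what lets the active scheme keep
  adding classifiers while the pool still under-represents the new regime,
  and stop on its own afterwards.
* **Refractory.** Validations are spaced by a refractory gap, default
  `n_w`, so consecutive validation windows never share trials.  When the
  goal is *counting distinct shifts* rather than triggering adaptation,
  use `isolated_shift_refractory(n_w) = 2·n_w + 1`: two validations closer
  than two windows can be produced by the same physical transition (their
  recent windows straddle the same change), and counting both would
  double-count one shift.

## PWKNN

Distances are Euclidean on the full feature vector; the kernel width σ
defaults to the median pairwise distance of the store (recomputed whenever
the store is enriched).  Neighbour ties at the K-th distance resolve to
the smallest store indices (stable sort); an exact posterior tie
(CR = 0.5) predicts the class of the single nearest neighbour.  The gate
is strict (`CR > Γ`).  Prediction is a deliberate O(m·D) scan — the
linear-time contract of instance-based learning — and the doubling test in
the suite verifies the empirical scaling.  `K` and `Γ` can be selected on
the 30% validation split (`select_parameters`): K by validation accuracy,
Γ by the net benefit (correct-minus-wrong accepted trials) with ties
toward the larger, safer threshold.

## Adaptive ensemble

* New classifiers are standard two-class LDAs (pooled ML covariance,
  empirical priors); a shrinkage refit engages on singular covariance.
* Voting is weighted majority on hard labels; a member's weight is its
  accuracy on the validation split at creation time, clipped to
  [0.01, 1] (uniform mode available).  Exact ties go to the most recently
  added member, which reflects the newest distribution.
* The gate stores the *PWKNN's transductive label* with a gated trial, not
  the ensemble's own output.  Enriching a classifier with its own
  predictions is an echo chamber — it re-encodes the training set's
  existing boundary estimate and adds nothing; the non-parametric
  neighbour vote contributes genuinely new local information.  The
  streaming gate threshold defaults to `Γ = 0.8`: at that level the gated
  pseudo-labels' purity on the reference scenario (~0.92) roughly matches
  the labelled pool's own purity (1 − ε = 0.95), so enrichment adds sample
  size without materially adding label noise.
* In C-3 the gating PWKNN store is refreshed with the merged pool at every
  adaptation, keeping gate and ensemble synchronized.  Old classifiers are
  never removed.  If a merged pool would lack a class, the adaptation is
  skipped and logged, never crashing mid-stream.

## Synthetic study design

* **Feature level.** Trials are drawn from a D = 8 Gaussian whose diagonal
  variances decay geometrically (ratio 0.25), mimicking the fast-decaying
  spectrum of concatenated log-variance CSP features.  Labels come from a
  fixed linear rule `sign(w·x + b)` (w loads 0.2 on the dominant axis and
  0.98 on the second), flipped with probability ε = 0.05; the offset is
  derived from the requested class balance.  At each change point the
  *whole marginal* is translated; shift vectors are expressed in pooled
  within-class SDs, computed in closed form from truncated-normal moments.
  Because the rule never changes, `P(y|x)` is identical across segments by
  construction.  Defaults: 120 stationary training trials, 160 test
  trials, one change point at test trial 80, shift 1.5 pooled SDs.
* **Shift geometry.** The default direction is dominantly *along* the
  decision boundary with a small (0.15) across-boundary component.  For a
  translated marginal under a fixed linear rule, a purely across-boundary
  translation moves mass away from the boundary region and is benign —
  even mildly helpful — to a fitted classifier; what degrades it is
  lateral translation, which widens the wedge between the fitted and true
  hyperplanes at the new position.  The mixed direction makes the shift
  cross the boundary (the class mix changes) while retaining the lateral
  degradation the adaptive scheme is designed to repair.
* **Signal level.** Ten channels at 250 Hz, 4-s trials: pink-noise
  background (1/f amplitude shaping with seeded phases) plus a mu-band
  sinusoid (9–11 Hz, random phase) whose amplitude drops by the
  attenuation factor on the first half of the channels for class ω₁ and
  the second half for class ω₂ from the cue onward — an
  ERD-like contrast.  Post-change segments rescale the rhythm amplitude
  for all trials: a covariate shift in band-power space that leaves the
  class contrast intact.
* **What this does not emulate.** No volume conduction, artefacts,
  inter-channel correlation structure, or non-linear label functions.
  Passing tests show the pipeline behaves correctly under controlled
  covariate shift; they do not certify performance on recorded EEG, where
  shifts are gradual, multivariate and entangled with `P(y|x)` changes.

## Problem sizes and expected outcomes

The suite and the acceptance script use desk-scale sizes chosen as the
smallest that make the statistical assertions stable: 2,000 replicates for
the stage-II null calibration (rejection rate in [0.03, 0.07] at
α = 0.05), 200 seeded runs for detector power (a 2-SD shift confirmed
exactly once within 10 trials of truth in well over 90% of runs under the
prompt profile), 500 random instances for the PWKNN oracle, and 20 seeds
for the adaptive-versus-static comparison.  On the reference scenario the
adaptive effect is real but small (≈ +0.5–1 accuracy point, per-seed SD
≈ 1.4): with 20 paired seeds the one-sided Wilcoxon resolves it most of
the time but not always — a larger seed budget tightens it, at the cost of
runtime.

## Degenerate inputs and numerical conventions

Non-finite observations are rejected without touching monitor state;
zero-variance CSP components are floored at an epsilon-scaled constant
with a warning; `K` larger than the store is clamped with a warning; an
empty store, a missing class, Nyquist violations and window overruns raise
immediately.  All randomness flows from one root seed through
`numpy.random.SeedSequence` substreams, making full runs bit-for-bit
reproducible.
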