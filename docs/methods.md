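# Methods

This note documents the decoding pipeline, the synthetic data model and its
calibration, and the numerical choices made in `cveptl`.

## 1. Stimulation protocol and codebook

All targets flicker with one 63-bit m-sequence presented at 60 Hz
(`cveptl.codes`). The sequence is produced by a 6-stage Fibonacci LFSR with
feedback polynomial x⁶ + x⁵ + 1 (taps (6, 5), all-ones start state). The
generator *verifies* rather than assumes primitivity: the measured period must
be 2⁶ − 1 = 63 and the balance 32 ones / 31 zeros, and the two-valued circular
autocorrelation (63 at lag 0, exactly −1 elsewhere) is exposed for testing.
Target z plays the base code delayed by `4·z` bits modulo 63; with 16 targets
the shifts are pairwise distinct. One code cycle lasts 63/60 = 1.05 s. The
reference target (index 10 by default) is the only one a user fixates during
calibration.

At the default 600 Hz sampling rate one code bit spans exactly 10 samples, so
one 4-bit target step is exactly 40 samples and trial shifting
(`preprocess.shift_trials`) is a lossless circular roll. At rates where the
step is fractional the shift is rounded to the nearest sample and a warning is
logged.

## 2. Decoding pipeline

1. **Band-pass filtering** — Butterworth 2–30 Hz, overall order 8, zero-phase
   (forward–backward `sosfiltfilt`). "Order 8" is interpreted as the overall
   band-pass order; SciPy's `butter(N, ...)` doubles the prototype order for
   band-pass designs, so the prototype order is 4.
2. **Trial synthesis** — the first `n_train` reference-target trials are
   circularly rolled to every class lag, yielding `n_train` labeled trials per
   class from a single-target recording.
3. **Templates** — per-class arithmetic means X̄₁…X̄_Z of the labeled trials.
4. **Super-trials** — each trial X is stacked under all Z templates:
   X′ = [X̄₁; …; X̄_Z; X] ∈ R^{Nc(Z+1)×Nt} (153 × 630 at the defaults).
   The covariance of a raw c-VEP trial carries no class information (a
   circular lag leaves second-order statistics unchanged); the super-trial's
   trial–template cross-covariance blocks carry it.
5. **Covariance estimation** — row-centered SCM `X′X′ᵀ/(Nt−1)` followed by
   shrinkage `λΓ + (1−λ)P`. Targets: `schafer_strimmer` Γ = diag(P) (package
   default), `blankertz` Γ = (tr P / n)·I, `ledoit_wolf` Γ = tr(P)·I. When λ
   is not fixed, the analytic plug-in intensity
   λ\* = Σ V̂ar(s_ij) / Σ (s_ij − t_ij)², clipped to [0, 1], is estimated from
   the super-trial samples. The 153-dim SCM of a 630-sample stack is
   rank-deficient; shrinkage restores positive definiteness.
6. **MDM classification** — per-class mean covariances; a test covariance is
   assigned to the nearest class mean. With the log-Euclidean metric
   (default) the class mean is exp(mean of logs) and all distances are
   Frobenius norms in the log domain, so each covariance's matrix logarithm
   is computed once and cached. The affine-invariant metric (Karcher mean by
   fixed-point iteration, generalized-eigenvalue distance) is selectable.

### Alignment (LEDA)

A subject's trials are whitened by M = (log-Euclidean mean of their trial
SCMs)^(−1/2): X ← M·X. For labeled trials the reference is computed per class
(*supervised*); for the target user's unlabeled test trials one global
reference is used (*unsupervised*). Alignment happens at the raw-trial stage
before templates are formed (applying it to assembled super-trials instead is
available behind `ExperimentConfig.alignment_stage`).

### Source selection (TSS)

Given aligned, labeled source subjects and the target's (synthesized) training
covariances: each source is scored by the accuracy of an MDM trained on that
source alone and tested on the target's training set; sources are ranked; for
c = 1…n the top-c sources are pooled, retrained and retested on the same
training set; the smallest c attaining the maximum pooled accuracy is kept.
The final model pools the selected sources *and* the target's training
covariances. By default the inner retraining pool contains sources only:
including the evaluation set in the training pool makes the profile saturate
at 1.0 and the selection degenerate to c = 1
(`ExperimentConfig.include_target_in_tss` restores the variant that includes
it).

### Jackknife templates

With few training trials, a trial's own noise inside its class template
creates a spurious ‖noise‖²/n term in exactly the true-class cross-covariance
block. Under the shifted-training protocol it is worse: all 16 class trials
derived from one reference recording share that recording's noise, so the
noise appears in *every* class template and the training covariances become
almost perfectly classifiable regardless of how hard the test set is. That
bias (a) distorts the MDM class means relative to the leakage-free test
covariances and (b) saturates TSS's training-accuracy criterion. The harness
therefore builds each labeled super-trial with templates recomputed without
its own underlying recording (`evaluate._jackknife_supertrials`); classes left
with a single trial keep the full template, which preserves the exactness of
the zero-noise, one-trial-per-class case. Test super-trials use the full
templates.

### Evaluation

Leave-one-subject-out: each subject in turn is the naive target (only its
first `n_train` reference trials are used for training; its test trials are
scored), all others are sources. The information-transfer rate is Wolpaw's

ITR = [log₂M + P log₂P + (1−P) log₂((1−P)/(M−1))] · 60/T bits/min,

with T = (cycles · 1.05 + 1.0) s per selection (1 s gaze shift) and ITR
clamped to 0 at or below chance. M = 16, P = 1, T = 2.05 s gives
117.07 bits/min.

## 3. Synthetic data model

`synthdata.simulate_population` generates a multi-subject study. Per subject:

* **Response kernel** — difference of two gamma bumps (positive peak,
  weighted undershoot), 300 ms long. The code waveform (0/1 at 60 Hz,
  sample-and-hold) is circularly convolved with the kernel to give the
  steady-state single-source response for each target lag.
* **Spatial model** — a mixing vector projects the source onto `n_channels`
  (default 9) channels; an invertible channel transform
  T = I + `shift_strength`·G (G random Gaussian, redrawn if cond(T) ≥ 1e6)
  models the subject-specific channel frame; a lognormal global amplitude
  factor (σ = `amplitude_log_sd`) models severalfold gain differences.
* **Clusters** — subjects are assigned round-robin to `similarity_clusters`
  prototypes that differ in kernel peak latency, undershoot weight, response
  delay, and mixing direction; within-cluster jitter is small.
* **Trial generation** — per trial: latency jitter (roll by
  N(0, `trial_latency_jitter_s`)), lognormal gain jitter
  (σ = `trial_amp_jitter`), additive per-channel AR(1) Gaussian noise with
  coefficient `noise_ar` and stationary RMS set from the subject's SNR, then
  the channel transform. `n_train` trials at the reference target plus
  `n_test_per_target` at every target.
* **SNR definition** — amplitude SNR against the realized pre-transform
  signal: noise RMS = (mean |mixing| · RMS of the source cycle) / SNR, SNR
  drawn uniformly from `snr_range` per subject. `snr_range=(inf, inf)` gives
  noiseless subjects.

### What the generator does and does not emulate

It reproduces the *structure* the pipeline exploits: code-locked responses
identical across targets up to circular lag, linear per-subject channel
frames, amplitude spread, kernel-shape clusters, temporally correlated
background noise, and trial-to-trial response variability. It does not
emulate real EEG's nonstationarity, artifacts, volume-conduction physics,
multiple neural sources, or electrode-specific noise, and absolute accuracies
are not comparable to hardware studies — only the *relative* behavior of the
four algorithms is meaningful.

### Calibration of the generator defaults (design-time)

The defaults were fixed once, while designing the generator, so that the
synthetic population occupies the qualitative regime the method targets —
they are study conditions, not fitted quantities:

* `shift_strength = 0.3`, `amplitude_log_sd = 0.5` — the channel-frame and
  gain shift is large enough that pooling unaligned subjects (`tl-ass`)
  clearly degrades, yet small enough that whitening leaves a modest residual
  (whitening corrects gain and frame scale but not rotations).
* cluster kernel spans (peak 95–110 ms, undershoot weight 0.42/0.58, delay
  0–35 ms) — kernel shape is the one difference a linear alignment cannot
  undo, so it sets the residual bias of cross-cluster transfer. Moderate
  spans keep pooling beneficial on average while giving source selection
  something real to rank. (Absolute response delay, notably, is *not* a
  useful separator: a trial and its templates shift together, so the
  lag-correlation pattern is delay-invariant.)
* `snr_range = (0.35, 0.5)` with `noise_ar = 0.9` — AR(1) noise concentrates
  power in-band and has few effective degrees of freedom per trial, so
  single-trial covariances scatter realistically; the band keeps 5-trial
  subject-specific decoding well off ceiling (≈0.8) so that pooled, aligned
  transfer measurably helps.
* `trial_amp_jitter = 0.15`, `trial_latency_jitter_s = 0.004` — evoked
  responses vary across repetitions; without this, templates from 5 trials
  are unrealistically clean.

With these defaults, over seeds 0–9 (8 subjects, 2 clusters, 5 training
trials per class) the mean LOSO accuracies are ssl 0.796, tl-ass 0.714,
tl-leda-ass 0.829, tl-leda-tss 0.833, reproducing the expected ordering.

## 4. Numerical choices

* All SPD matrix functions (log, exp, square roots) use the symmetric
  eigendecomposition; eigenvalues below 1e−12 × (largest eigenvalue) are
  floored there before logs/inverse roots, and every flooring event is
  logged.
* The log-Euclidean mean is exp((1/N) Σ log P_i) — the actual minimizer of
  Σ d²_LE (the normalization matters).
* The affine-invariant mean uses the closed-form geodesic midpoint for N = 2
  and otherwise the fixed-point iteration
  M ← M^{1/2} exp(mean_i log(M^{−1/2} P_i M^{−1/2})) M^{1/2}, warm-started at
  the log-Euclidean mean, tolerance 1e−9 on the tangent-space gradient norm.
* The affine-invariant distance is computed from the generalized eigenvalues
  of the pencil (P₂, P₁) rather than explicit inverse square roots.
* `ledoit_wolf` shrinkage uses Γ = tr(P)·I (the convention stated with that
  name in the source literature for this pipeline), while `blankertz` is the
  usual average-variance target Γ = (tr P / n)·I; the hand-checkable example
  diag(1,3) → diag(1.5, 2.5) at λ = 0.5 applies to the latter.
* The analytic shrinkage intensity is a functional of the *samples*, not of
  P alone, so `shrink` takes an optional `data` matrix; λ may also be fixed.
  λ = 1 (pure target) is accepted so endpoint behavior is exactly testable.
* LOSO fold failures are caught, logged and reported per subject
  (`ExperimentResult.failures`) instead of aborting the whole evaluation;
  an evaluation where *every* fold fails raises.
* `compare_algorithms` shares per-subject source covariances across the four
  algorithms (aligned ones between the two LEDA variants, unaligned ones
  between `ssl`/`tl-ass`), roughly halving the comparison cost.

## 5. Limitations

* The generator's single neural source and linear mixing make alignment
  unrealistically effective; real-EEG gains from LEDA will be smaller.
* TSS inherits the bias of scoring on the training set; with very few
  training trials its pool-size estimate is noisy even with jackknife
  templates (ties between `tl-leda-tss` and `tl-leda-ass` are common when
  all sources genuinely help).
* The affine-invariant path (Karcher means) is O(iterations × N) eigensolves
  of 153×153 matrices per class and is noticeably slower than the
  log-Euclidean default at full problem size.
* Online (causal) filtering is available (`FilterSpec(zero_phase=False)`)
  but the evaluation harness models offline analysis only.
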