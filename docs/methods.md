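# Methods

`errp` implements a complete single-trial decoding pipeline for feedback
error-related potentials (ErrPs): a synthetic sham-feedback EEG generator, a
fixed preprocessing chain, two waveform-based classifiers — a multi-layer
perceptron trained by scaled conjugate gradient (SCG) and shrinkage linear
discriminant analysis (sLDA) — and three calibration-transfer evaluation
schemes.  This note records the model, its assumptions, the defaults and why
they were chosen, and what the simulation can and cannot say about real EEG.

## The experimental model

The simulated experiment is a sham brain–computer interface: on each trial
the participant is cued to attempt one of four movements (left/right hand,
left/right foot), and after a fixed delay receives "correct" or "error"
feedback that is predetermined rather than decoded.  A session comprises
4·n trials (default n = 100 per movement, 400 total) with feedback scheduled
at an exact 70/30 correct/error ratio; the trial timeline is idle (5 s),
preparation (3 s), cue plus attempted movement, feedback after a 3 s delay.
The scheduler enforces *exact* class counts (280/120 at defaults) rather than
i.i.d. draws, so class-balance arithmetic downstream is deterministic.

The feedback-locked response is modelled as two Gaussian-shaped bumps: a
negative deflection peaking 350 ms after feedback and a positive one at
450 ms.  Error feedback deepens the negative peak by `class_delta_uV`
(default −2.5 µV on a −4 µV NonErrP peak); this single amplitude difference
is the entire class signal.  Each bump is truncated to zero outside three
widths of its latency (widths 30/33 ms), which has a useful side effect:
each bump's support excludes the other's peak, so the waveform extrema sit
*exactly* at the configured latencies at any sampling rate.

The scalp topography is a Gaussian weight map centred on FCz (decay scale
2 electrode-grid steps), reflecting the fronto-central maximum of feedback
ErrPs.  No per-channel topography was available to fit, so this map is an
explicit assumption, not an estimate.

Background activity is 1/f-shaped Gaussian noise (flat below 1 Hz, no DC)
normalized per channel to `noise_rms_uV` (default 6 µV), plus an optional
10 Hz rhythm (default 1 µV RMS).  Two artifact mechanisms are simulated at
the amplitude level only: per-trial slow transients (rate 0.18, 300 µV,
60 ms Gaussian time course centred inside the analysis window, so they
survive the band-pass and trip the amplitude-rejection rule) and whole-
recording bad channels (per-channel probability 0.008, noise inflated 25×).
No ocular/EMG waveform morphology and no movement-related cortical
potentials are modelled.

### Cohort variability

Cohorts are built hierarchically.  Each participant draws one multiplicative
ERP amplitude factor (log-normal, σ = 0.5) shared across days and one trial
schedule; each (participant, day) draws an additional amplitude factor
(σ = 0.25) and a day-constant latency shift (Gaussian, σ = 30 ms); each
trial draws latency jitter (σ = 10 ms).  The jitter/shift ratio encodes the
regime the generator is meant to emulate: single-trial latency jitter of
feedback-locked potentials is modest, while session-to-session
nonstationarity (electrode placement, gel, vigilance, weeks between
sessions) is substantially larger.  It is this hierarchy that makes
within-day calibration the best scheme and cross-day transfer poor, which
is the structural phenomenon the evaluation module is designed to measure;
with trial jitter dominating the day shift the schemes become
indistinguishable.

## Preprocessing

Applied in order, per session:

1. **Band-pass 0.05–10 Hz.**  An order-8 Butterworth is designed and applied
   forward–backward (`sosfiltfilt`): zero phase, effective magnitude
   order 16.  The alternative reading (design order 4, doubled by the two
   passes) is available by setting `filter_order=4`.
2. **Bad-channel exclusion.**  Per channel, the statistic is the mean
   *absolute* amplitude over the whole recording (the signed mean of
   band-passed EEG is ≈0 and useless); channels above mean + 3 SD of the
   channel population are dropped.  Note a structural limit: among n
   channels a lone outlier's z-score cannot exceed (n−1)/√n, so the 3-SD
   rule can only ever fire with n ≥ 11 channels.  It is effective on the
   full 37-channel montage and intentionally inert on the 9-channel
   reduced montage used in fast tests.
3. **Epoching.**  One epoch per feedback event over the half-open window
   [100, 500) ms after feedback — 480 samples at 1200 Hz, 80 at 200 Hz.
   Events without room for the full window are dropped with a warning.
4. **Amplitude rejection.**  An epoch is rejected when its maximum absolute
   value across retained channels *strictly exceeds* 150 µV (an epoch
   peaking exactly at 150 µV is kept).  Applied before normalization, on
   the filtered signal.
5. **Normalization.**  Per epoch and channel, the within-epoch mean is
   subtracted (idempotent; channel means exactly zero afterwards).
6. **Class balancing.**  All ErrP epochs are kept and NonErrPs are
   subsampled without replacement to the ErrP count, once per session —
   before any cross-validation split, not per fold.

## Features

Two representations, both in raw microvolts (no standardization — none is
part of the modelled pipeline, and both classifiers must cope with µV
scales): the waveform downsampled to 50 Hz by plain decimation (keep every
(fs/50)-th sample from offset 0; the 10 Hz low-pass edge guarantees the
25 Hz Nyquist condition, verified by a spectral property test), and the
entire epoch flattened.  Columns are channel-major and every column carries
(channel, time-ms) provenance, so a feature vector can be mapped back onto
the scalp and epoch — the point of using waveform features at all.

## Classifiers

**MLP.**  Input layer sized to the feature vector, hidden layers 100-50-25
(tanh), one sigmoid output.  Training is full-batch minimization of the mean
binary cross-entropy by SCG with a maximum of 200 iterations and no early
stopping or validation split (`validation_checks = max_iterations`).  The
loss is computed from logits via log(1+e^z) − yz, so it stays finite under
saturation.  Weights are seeded Glorot-uniform; biases start at zero.  The
hidden activation is configurable (tanh default — the conventional choice
for pattern networks of this design; logistic available).

**SCG** follows Møller's 1993 algorithm: curvature along the search
direction from a finite difference of the gradient (σ₀ = 1e−5), a damping
parameter λ (initial 1e−7) raised on non-positive curvature or a failed
comparison ratio and lowered when the quadratic model is good, restarts to
steepest descent every n accepted steps, and acceptance only of steps that
decrease the loss — so the accepted-loss sequence is non-increasing by
construction.  No line search, no randomness: training is a pure function
of (data, architecture, seed).

**sLDA.**  Two-class LDA on the pooled within-class covariance shrunk toward
a scaled identity, Σ(γ) = (1−γ)S + γ(tr S/d)I, with γ from the analytic
Ledoit–Wolf formula clipped to [0, 1] (manually settable).  With balanced
classes the rule is sign(wᵀx − b), w = Σ⁻¹(μ₁−μ₀), b midway between the
projected means; exact ties go to NonErrP.  Degenerate corner: with two
samples per class, class-centering produces ± pairs for which the analytic
γ is exactly 0 and S is singular; the solver then falls back to the
minimum-norm (pseudo-inverse) solution rather than failing.

The classification threshold is 0.5 / equal priors throughout, justified by
the enforced class balance.

## Evaluation

*Within-day*: stratified 10-fold cross-validation inside one session (folds
are stratified to preserve the enforced 50/50 balance; the balancing
subsample is drawn once per session, not per fold).  *Between-day*: train
on one day's full session, test on the other, both directions reported
separately.  *Across-participant*: leave-one-participant-out; each training
participant contributes their balanced session unweighted, and channels are
restricted to the cohort-wide intersection (the resolution adopted for
mismatched bad-channel sets, logged when it triggers).

Accuracy is the trial-level fraction correct — no AUC/F1.  The chance level
for n test trials is the smallest k/n with P(Binomial(n, 1/2) ≥ k) ≤ 0.05;
it is reported next to every result.  Note it is only *approximately*
non-increasing in n: integer k makes it tick up by less than 1/n (e.g.
0.590 at n = 100, 0.591 at n = 110).  For a cross-validated session the
package reports the chance level at the total number of tested trials;
for leave-one-participant-out, at the mean per-participant test size.

Grand averages are means across participants' per-participant mean
waveforms, with the between-participant standard error.  Test–retest
reliability is the Pearson correlation of per-participant within-day
accuracies across the two days; accuracy–impairment association uses
Spearman (both via scipy, two-sided p, average ranks).  No multiple-testing
correction is applied to these correlations; omnibus ANOVA machinery is
out of scope — the results table is tidy CSV consumable by any stats
package.

## Reproducibility

Every stage seed is derived from one master seed as
sha256("master:stage-label") mod 2³¹, so a single integer reproduces an
entire experiment; the run manifest stores the config and master seed.
All generation, training, and evaluation is deterministic given seeds.

## Problem sizes

Design-parameter checks run at the full experimental scale (1200 Hz, 37
channels, 400 trials).  Scheme-level simulations in the test suite and the
acceptance script run at a reduced size chosen as this package's standard
small-cohort condition: 200 Hz (an integer multiple of the 50 Hz feature
rate, preserving the 80-sample window and 20 features per channel), the
9-channel fronto-central core of the montage, 2–4 participants × 2 days,
100–400 trials per session, and the sLDA classifier where only scheme
structure (not classifier family) is under test.  Bad-channel injection is
disabled in the 9-channel runs because the 3-SD rule cannot fire there (see
above); it is exercised on the full montage.

## Known limitations

- The class signal is a pure amplitude difference at a fixed latency;
  real ErrP/NonErrP pairs differ in shape, latency structure, and
  topography.  Passing structural tests shows the pipeline recovers what
  the generator injects, not that it would reach any particular accuracy
  on clinical EEG.
- Artifacts are amplitude transients only; rejection-rate statistics are
  meaningful, artifact *morphology* is not.
- The fronto-central weight map, noise spectrum, and variability sigmas are
  plausibility choices, stated above, not fitted quantities.
- The MLP is unregularized by design (no weight decay, no early stopping);
  with the full epoch as input at small n it overfits and its transfer
  accuracy degrades accordingly.  This mirrors the behaviour of the
  modelled pipeline rather than a defect to be fixed here.
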