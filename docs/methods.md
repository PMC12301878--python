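# Methods

This note documents the models and procedures implemented in `lespeech`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Listener effort and the measurement protocol

Listener effort (LE) is a perceptual rating, on a 0–100 visual-analogue
scale, of how much work a healthy listener needs to understand a speaker
(0 = easily understandable, 100 = unintelligible even with full effort).
The protocol modelled here: each session contains three sentence-reading
recordings; three SLP raters each score every recording, so a complete
session carries nine ratings, and the session LE is their plain mean.
Twenty percent of recordings are re-presented at random to the raters;
these repeat ratings exist solely to measure intra-rater reliability and
are excluded from all scoring and from inter-rater reliability (the
"first" repeat policy, the only one implemented).

Reliability is the two-way intraclass correlation from the mean-squares
decomposition. The default form is ICC(2,1) — random raters, absolute
agreement, single measurement — so systematic rater offsets count against
agreement; a consistency form, ICC(3,1), is available. The literature this
instrument comes from does not pin down the form, so it is a configuration
choice; ICC(2,1) is the conservative default because the raters in any
deployment are a sample from a larger pool. Interpretation bands: < 0.5
poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent. The ICC
implementation is cross-checked against pingouin's `intraclass_corr` in
the test suite to machine precision.

## Quality-assurance cascade

Three filters, applied in a fixed order (the per-stage counts are
order-dependent, so the order is part of the contract):

1. **Rater notes.** A recording is excluded if any rater's free-text note
   contains any keyword from the list {noise, volume, quality, recording,
   sample, error, nothing, no speech}. Matching is case-insensitive and
   substring-based over the union of all raters' notes for the recording —
   the conservative reading ("noisy" matches "noise"; any one rater's
   complaint suffices).
2. **Hallucination screen.** Automatic transcribers can fabricate content.
   A recording is kept only if its transcript reproduces at least 20%
   (inclusive) of the presented sentence's words, measured as word-multiset
   overlap relative to the reference. Overlap rather than edit distance:
   the filter's job is detecting fabricated content, and overlap is
   order-insensitive and cheap. A missing transcript is excluded under a
   distinct reason code.
3. **Minimum rated recordings.** Sessions reduced to a single surviving
   recording are dropped entirely, keeping session means comparable.

`run_qa` reports recording and session counts before QA and after each
stage, plus a per-recording exclusion reason; counts are conserved at every
stage (kept + excluded = input), and the cascade is idempotent on its own
output. A Mann–Whitney U comparison of excluded vs. retained LE scores is
provided for transparency about what a filter preferentially removed.

## Rate features

Word-level ASR timestamps are unreliable at recording edges, so both rates
drop the first and last word. **Speaking rate** = retained word count /
(offset of last retained word − onset of first retained word) × 60, in
words/min. The span convention (onset-to-offset of the retained window)
uses both boundary timestamps and is shift-invariant; the generator uses
the same convention, so generated transcripts invert exactly.
**Articulation rate** uses the same window but removes inter-word gaps of
at least the pause threshold (default 0.200 s, configurable — no standard
definition of "pause" exists at this granularity) from the denominator and
divides syllable count instead, in syllables/s.

Syllables come from a vowel-cluster heuristic: count maximal vowel
clusters, subtract one for a silent final 'e', add one back for a
consonant + 'le' ending, floor at one. 'y' counts as a vowel so words like
"rhythm" and "my" receive a cluster before the floor applies.

Recording-level ASR confidence is the geometric mean of per-word
probabilities when available, else the transcriber-reported segment
confidence.

## Acoustic features

Eleven features per recording, all gain-invariant:

* **Pitch** (mean, SD over voiced frames): frame-wise normalized,
  lag-unbiased autocorrelation; 40 ms frames, 10 ms hop (≥ 2 glottal
  periods at the 75 Hz floor); candidate lags between 1/500 and 1/75 s;
  parabolic lag interpolation; a frame is voiced when the peak reaches
  0.45. Among near-equal peaks the shortest lag wins, preventing octave
  errors (the peak at twice the true period is equally strong).
* **HNR**: per voiced frame, r = autocorrelation at the pitch lag, frame
  HNR = 10·log₁₀(r/(1−r)), clamped to [−20, 40] dB, averaged. For a
  periodic signal in additive white noise r ≈ P_h/(P_h+P_n), so HNR
  estimates the true SNR.
* **Jitter / shimmer** (local): mean absolute successive difference of
  cycle periods / peak amplitudes, divided by the respective mean. Cycles
  are found by pitch-guided peak picking with parabolic sub-sample
  refinement, skipping the first 100 ms (filter onset transient) and
  discarding periods outside 0.75–1.25× the median.
* **Formants** (F1/F2 mean, SD): linear-prediction root-solving on audio
  resampled to 10 kHz with 0.97 pre-emphasis; LP order 2 + rate/1000 = 12;
  roots with bandwidth under 400 Hz, sorted by frequency; voiced frames
  only.
* **Envelope SD**: coefficient of variation of 25 ms frame RMS (SD/mean,
  hence gain-invariant).
* **CPP**: per 40 ms frame, Hamming-windowed log-magnitude spectrum (dB) →
  real cepstrum; peak within the quefrency band [1/500, 1/75] s;
  prominence above the linear regression of cepstrum on quefrency fitted
  from 1 ms up; averaged over non-silent frames (plain CPP, not the
  smoothed CPPS variant).

Frame sizes, thresholds and LP settings mirror the documented defaults of
standard phonetics toolkits; none of them is sacred, and all live in
`AcousticConfig`. Missing values (silence, all-unvoiced audio, too few
cycles) propagate as NaN through `extract_features` rather than raising.

## Synthetic data: what it emulates and what it does not

`gen_voice` builds an impulse-train source: cycle periods jittered by
i.i.d. Gaussian noise (SD = jitter_pct/100 of the nominal period), cycle
amplitudes perturbed likewise (shimmer), filtered through a cascade of
two second-order resonators (the formants), plus white noise at a set SNR.
With zero jitter, periods are rounded to a whole number of samples so the
output is exactly periodic; with jitter, impulses are placed by two-point
linear fractional delay so sub-sample timing survives synthesis. The
returned object carries the exact per-cycle period/amplitude ledger — the
synthesis oracle that feature-recovery tests compare against. One bias is
inherent and documented: local jitter of i.i.d. Gaussian periods has
expectation 2σ/√π ≈ 1.13σ, so measured jitter runs ~13% above the set
percentage even with perfect cycle detection.

`gen_cohort` draws participants (PALS split into bulbar/non-bulbar onset,
plus controls) with linear true-LE trajectories clipped to [0, 100],
sessions at a fixed cadence, three recordings per session, and ratings =
clip(true LE + rater bias + Gaussian noise, 0, 100). Defaults mirror the
full-protocol conditions: 105 PALS / 20 controls, 22% bulbar onset, LE
slopes 1.66 (bulbar), 0.42 (non-bulbar) and 0.005 (control) points/month,
three raters with biases (−2, 0, +2) and 5-point within-rater noise
(within-rater noise is not reported anywhere; 5 LE points is a fixture
choice), sessions every 60 days, 20% repeats. Between-participant slope SD
is per-group — 1.0 for PALS, 0.03 for controls — because controls are
essentially stable; a large control slope scatter would contradict the
near-zero standard errors such cohorts show. A single master seed expands
into per-participant substreams, so enlarging the cohort never shifts an
existing participant's draws.

What the generator does **not** emulate: natural glottal waveforms
(impulse excitation, not a Rosenberg pulse — adequate because tests
compare against the cycle ledger, not against natural voice), coarticulation
and formant dynamics, ASR timing-error structure beyond uniform word
durations, rater drift and scale-use idiosyncrasies (e.g. a rater avoiding
a particular score), dropout and irregular session cadence. Passing tests
therefore demonstrate that the pipeline's machinery is correct and recovers
known ground truth — not that real recordings will yield the same feature
distributions or prediction accuracy.

## Longitudinal model

`ProgressionModel` fits value ~ time (months, days/30.4375) with a random
intercept and an *independent* random slope per participant (the slope
enters as a variance component), by REML; Wald tests on fixed effects; no
multiple-testing correction. With a two-level group factor the fixed
effects become time, group and time×group, and the interaction tests
whether slopes differ. If the random-slope fit fails to converge the model
falls back to a random-intercept-only fit and flags it in the results. The
time origin is selectable: months since symptom onset (PALS) or since
enrolment; controls, having no onset, always use enrolment.

Progression dichotomization: per participant, change = last − first
observation, sign-adjusted so positive always means decline (LE rises with
decline; speaking rate and function scores fall). The threshold is the
*maximum* sign-adjusted change among controls, and Progression requires
strictly more decline than that maximum. Endpoint-based change is the
default; per-participant OLS slopes are exported for slope-based analyses
and as the input surface for external trajectory-clustering methods.

Trial sample size per group uses the normal-approximation comparison of
slopes: n = (z₁₋α/₂ + z_power)²·σ²/(f·slope)², where f is the fractional
slowing attributed to treatment, σ the between-participant SD of the
slope, rounded up (ceiling; "nearest" is available — with inputs slope
2.71, σ 3.42, f 0.30, 90% power, α 0.05 the formula gives 185.95, so
ceiling yields 186 and published figures computed from unrounded inputs
can land one participant higher).

## Prediction model

`ListenerEffortModel` predicts session LE from 13 features: the 11
acoustic features plus speaking rate and ASR confidence, averaged over the
session's surviving recordings. The estimator is the Lasso, minimizing
(1/2n)·Σ(y − Xβ − β₀)² + λ·Σ|β|: the L1 penalty shrinks uninformative
coefficients exactly to zero, so the fitted model doubles as a feature
selector. Evaluation is participant-grouped nested cross-validation —
five outer folds for unbiased error, five inner folds within each outer
training set to pick λ — with every session of a participant confined to
one fold at both levels, because the deployment question is generalization
to unseen speakers. Fold-target uniformity is checked by a two-sample
Kolmogorov–Smirnov test (α = 0.05) of each fold against the pooled rest,
reshuffling up to 1000 times. Features are median-imputed and z-scored
using training-fold statistics only (a mutation test in the suite guards
the leakage boundary); the target stays on its 0–100 scale so RMSE is in
LE points. The penalty grid has 50 values log-spaced over four decades
down from λ_max = max|Xᵀ(y−ȳ)|/n (the analytic all-zero penalty);
selection is by minimum mean inner-validation MSE, with no one-standard-
error rule. Reported per fold: chosen λ, RMSE, R² (1 − SSE/SST about the
test-fold mean); aggregated: mean ± SD and the fold-averaged relative
coefficient weights |β_j|/Σ|β|.

Fold construction operates at session level. On synthetic cohorts a
per-recording layout makes the KS check unsatisfiable — each participant
contributes a cluster of near-identical targets, and at per-recording
sample sizes the test rejects every partition — and session level is also
how the rating protocol defines the target.

## Problem sizes used in tests and the acceptance script

Parameter-recovery suites run at the protocol's cohort scale (105 PALS /
20 controls) with 50 seeded replicates for slope recovery, 20 synthesized
voices per acoustic condition, and 150–200 synthetic sessions for the
nested-CV checks; the acceptance script synthesizes per-recording audio
for a 50-participant cohort before fitting the prediction model. These
sizes make the Monte-Carlo bands in the tests meaningful while keeping a
full run in the minutes range on one CPU.

## Known limitations

* The acoustic front end is a compact reimplementation of standard
  phonetics measures, not a bit-for-bit match to any specific toolkit;
  absolute CPP values in particular depend on windowing conventions and
  should be compared only within this implementation.
* The jitter estimator inherits the +13% folded-normal bias described
  above; comparisons against the set jitter percentage use a ±25% band.
* Whisper-style ASR is interfaced through its file output only; nothing
  here runs or models a transcriber.
* Trajectories are linear by construction; floor/ceiling saturation is the
  only nonlinearity the generator produces, and the mixed model does not
  model it.
* Only the sentence-reading task is modelled; passage reading, picture
  description and DDK tasks are out of scope, as are trajectory
  clustering (slopes are exported for it) and any rating UI.
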