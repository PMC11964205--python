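# Methods

## Task and measurement model

The task is paced sensorimotor synchronization: an isochronous stimulus
train at rate f (2.4 Hz auditory and visual; 2.6 Hz for the visual stream
of the asynchronous audio-visual condition) runs for 39.5 s, and the
participant taps once every second beat starting on beat 3, so the
instructed tap period is P = 2/f ≈ 833 ms.  Four conditions are scored
against a reference stream: auditory-only (A), visual-only (V), and the
two audio-visual conditions (AVsync, AVasync), which are referenced to
the visual stream because the multisensory questions are framed as
changes relative to the visual-only baseline.  This choice is a config
switch (`ConditionSpec.reference_stream`); the task instructions do not
single out a stream, so it is an interpretation, not a given.

Each tap time t is mapped to a phase θ = 2π·(t − nearest anchor)/P
wrapped to (−π, π], where the anchors are the odd- or even-indexed
stimuli (1-based) depending on which alternating subset the participant
locked to.  Negative phase = anticipation, the usual negative mean
asynchrony.  The equidistant point maps to +π by convention.  Trial
consistency is the mean resultant length R of the unit vectors e^{iθ},
accuracy the circular mean direction.  R is logit-transformed before
modelling (skew reduction), with R clamped to [ε, 1−ε], ε = 10⁻⁶, so
perfectly consistent trials stay finite (logit ≈ ±13.8).  Chance-level
tapping is identified by the Rayleigh test, Z = nR², with the standard
approximation p ≈ exp(√(1+4n+4(n²−nZ)) − (1+2n)); for n < 4 no p is
returned.

## Cleaning rules and their parameters

Applied in this order; each discards events with a recorded reason so
that kept + discarded always conserve the input:

1. **Post-dropout guard.** The recording emulated here loses the signal
   for 1.46 s once per trial; taps within 0.75 × (instructed inter-tap
   interval) after the dropout end are unreliable and are discarded —
   625 ms at 2.4 Hz tapping every 2nd beat.  The window is half-open
   [end, end + w): a tap exactly at end + w is kept.
2. **Refractory rule** (replaces manual double-tap inspection): within a
   run of events closer than 150 ms, only the first is kept.  150 ms is
   well below half the shortest plausible inter-tap interval
   (2/2.6 Hz ≈ 769 ms), so genuine taps are never merged.
3. **Tapping-interval detection.** The multiple m ∈ {1, 2, 3} of the
   stimulus interval nearest the trial's median inter-tap interval; ties
   break to the smaller m.  Trials with m = 1 or 3 (tapping every beat or
   every third beat) are excluded.
4. **Phase (parity) detection.** Odd-stimulus, even-stimulus and tap
   event trains are smoothed with a Gaussian kernel (sd 50 ms) on a 1 ms
   grid; the parity whose stimulus series has the larger Pearson
   correlation with the tap series wins; exact ties go to odd with a
   warning.  The kernel sd and grid are config values; parity recovery is
   insensitive to them at plausible jitter (tested at 30 ms).
5. **Initial trim.** The first 5 taps are discarded (synchronization
   warm-up).
6. **Pause pruning.** Inter-tap intervals above Q3 + 3 × IQR
   (linear-interpolation quartiles, the common "type 7" definition) mark
   pauses; the tap terminating each such interval is discarded.  Single
   pass — the threshold is not recomputed after removal.  A small epsilon
   (1 ns) guards the IQR = 0 edge case of perfectly regular tapping.
7. **Usability.** Trials with fewer than 8 scored taps are flagged
   unusable rather than scored.

## Inference

Trial-level logit R is modelled with a linear mixed model:
group × condition fixed effects under sum-to-zero coding, a random
intercept per participant and random condition slopes (unstructured 4×4
covariance).  REML fitting is delegated to statsmodels `MixedLM`; on
convergence failure the random-effect structure falls back to diagonal
slopes, then intercept-only, each downgrade logged.  An empty
group × condition cell makes the factorial rank-deficient; aliased
columns are then dropped (the R `NA`-coefficient convention), affected
omnibus terms are reported as undefined, and contrasts touching the
missing cell are returned as NaN.

Omnibus type-3 Wald F tests and the post-hoc contrasts use the
**Kenward-Roger** small-sample procedure by default: the fixed-effect
covariance Φ = (XᵀV⁻¹X)⁻¹ is inflated for the uncertainty of the
variance parameters, and the denominator df and an F scale factor are
obtained by moment matching.  Because V is linear in the variance
parameters (entries of G and σ²), all ingredients are closed-form; the
implementation follows the published procedure and reproduces R's
`pbkrtest`/`emmeans` to four significant digits in the test suite (on
balanced data it hits the same exact moment values).  Satterthwaite df
(numerical REML curvature; validated against `lmerTest`) and a
containment-style between-within rule are available as options.  In null
simulations at the study's size the KR interaction test rejects at the
nominal 5%; the asymptotic-covariance Satterthwaite version ran ~1 point
hot, which is why KR is the default.

Eleven pre-registered contrasts on the estimated marginal means compare
groups within conditions, the auditory advantage (A − V) within and
between groups, and the multisensory congruence (AVsync − V) and
interference (AVasync − V) effects within and between groups.  Bonferroni
correction uses the fixed printed family size of 11 (asserted against the
list length).  Clinical regressions are ordinary least squares of
per-participant mean outcomes (V, A, AVsync − V) on deafness onset age —
pre-linguistic onset entered as 2 years — or deafness duration, CI
participants only, df = n − 2.  Trial-level rows feed the mixed model;
participant means feed the regressions (the only sensible per-participant
summary given df = n − 2 reporting).

## Synthetic data generator

The generator is the test substrate standing in for undeposited raw
data.  Tap phases are von Mises around a participant-specific mean phase
(default −0.3 rad ≈ 40 ms anticipation, sd 0.15 across participants) —
the circular analogue of Gaussian jitter, chosen because its
concentration κ gives a closed-form expected consistency
A(κ) = I₁(κ)/I₀(κ).  Group × condition mean consistency defaults (logit
scale: HC 2.64/−1.22/1.71/−2.16, CI 1.38/−0.69/0.20/−1.72 for
A/V/AVsync/AVasync) are inverted through A(κ) to per-cell κ; participants
add a N(0, 1.0) intercept and N(0, 0.4) per-condition offsets on the
logit scale before inversion (clipped to R ∈ [0.01, 0.995]).  Artifact
rates: wrong-rate trial probabilities per cell matching the reported
exclusion tallies (e.g. HC visual 18/170); dropout in 90% of trials,
1.46 s long, uniformly placed after the first three beats, with
hold-last-sample fill; per-tap pause probability 0.02 with 3.5 s pauses
(≥ 4 tap periods, guaranteeing the Q3 + 3×IQR branch is exercised);
double-tap probability 0.02 (extra tap 50–120 ms later, inside the
refractory window); miss probability 0.03.  Force traces place one
fast-attack, sinusoidal-release pulse (30 ms, amplitude 1) per tap so a
mid-range threshold crossing is within one sample of the tap time.
Synthetic clinical tables draw ~15% pre-linguistic onsets and otherwise
uniform onset ages with exponential deafness durations, mirroring the
shape of the published clinical table.

What the generator does **not** emulate: force-amplitude variation,
sensor drift, tempo drift within a trial, serially correlated
(error-correcting) asynchronies, or any perceptual difference between
modalities beyond the planted consistency levels.  Passing tests
therefore demonstrate that the pipeline recovers known generative
parameters and keeps its error rates under the stated noise and artifact
model — not that it is robust to every property of real FSR recordings.

## Estimator calibration and the finite-sample bias of R

For any circular distribution with population resultant ρ,
E[R̂²] = 1/n + (1 − 1/n)ρ² exactly; hence R̂ itself is biased upward by
O(1/(nρ)) — at n ≈ 40 taps and κ = 0.5 the bias (~+0.03) is several
times the Monte-Carlo SE of a 500-trial ensemble.  Calibration checks
therefore compare √(mean[(nR̂² − 1)/(n − 1)]) — exactly unbiased for ρ²
before the square root — with A(κ), with a delta-method SE.  The same
identity gives E[nR̂²] = 1 under uniformity (κ = 0), the Rayleigh null
mean asserted in the tests.

## Problem sizes and numerics

Calibration experiments run at the study's own size (20 + 17 participants,
10 trials/condition): 500 null replicates for type-I rates and 200
planted-effect replicates (HC-only AVsync shift of 1.5 logit units) for
power, both in the test suite and in `scripts/acceptance.py`; estimator
calibration uses 500 trials per κ ∈ {0.5, 1, 2, 4}.  REML linear algebra
is blocked by participant and batched over participants sharing a
random-effect design block, so a full fit plus KR inference takes ~0.4 s.
Degenerate inputs are handled explicitly: boundary variance estimates use
pseudo-inverse information; df values are clamped to [1, N]; empty trials,
all-excluded participants and zero-variance predictors raise or flag with
explicit reasons rather than propagating NaNs.
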