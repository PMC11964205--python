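# tapsync

Analysis pipeline for paced finger-tapping (sensorimotor synchronization)
experiments comparing cochlear-implant (CI) users with hearing controls
(HC) across auditory, visual and audio-visual metronome conditions.

Participants tap once every two beats of an isochronous 2.4 Hz stimulus
train (2.6 Hz for the detuned visual stream of the asynchronous
audio-visual condition), 39.5 s per trial, 10 trials per condition.
`tapsync` covers the full path from raw force-sensor (FSR) traces — or
simulated tap-time tables — to group-level inference:

1. **Tap detection** — threshold crossings of the force trace, with a
   post-dropout guard (625 ms = 75% of the instructed inter-tap interval
   after a 1.46 s signal loss) and a refractory rule for double taps.
2. **Trial cleaning** — tapping-interval detection from the median
   inter-tap interval (trials at 1× or 3× the stimulus interval are
   excluded), odd/even phase assignment by Gaussian-smoothed event-train
   correlation, removal of the first five taps, and pruning of taps that
   end pause-like intervals (> Q3 + 3 × IQR).
3. **Circular scoring** — each tap becomes a phase on a circle whose full
   revolution is one beat (twice the inter-stimulus interval, anchored to
   the detected odd/even stimuli).  Consistency is the mean resultant
   vector length R = |n⁻¹ Σₖ e^{iθₖ}| ∈ [0, 1], logit-transformed for
   modelling; accuracy is the circular mean direction; chance-level
   tapping is flagged by a non-significant Rayleigh test (Z = nR²).
4. **Inference** — a linear mixed model of trial-level logit R with
   group × condition fixed effects (sum-to-zero coding), a participant
   random intercept and random condition slopes; type-3 Wald F tests with
   Kenward-Roger adjusted covariance and degrees of freedom (Satterthwaite
   and between-within available); 11 pre-registered contrasts on the
   estimated marginal means, Bonferroni-corrected; and OLS regressions of
   CI users' consistency on deafness onset age (pre-linguistic onset coded
   as 2 years) and deafness duration.
5. **Synthetic data** — a generator that emulates the study design
   (20 CI + 17 HC, 4 conditions × 10 trials) with von Mises phase noise
   whose concentration κ maps to expected consistency through the Bessel
   ratio A(κ) = I₁(κ)/I₀(κ), plus realistic artifacts: signal dropouts,
   wrong-rate trials, double taps, misses and mid-trial pauses.

The Kenward-Roger machinery is implemented in this package (statsmodels
provides the REML fit only) and is cross-checked in the test suite
against R's `pbkrtest`/`emmeans`/`lmerTest`.

## Worked example

```sh
tapsync run --seed 3 --out out/
```

simulates a full study, scores it, and writes `events.tsv`, `scores.tsv`,
`exclusions.tsv`, `report.json` and `summary.txt`.  The summary for seed 3:

```
Omnibus (type-3 Wald, kenward_roger df):
  group: F(1, 35.0) = 0.029, p = 0.8663
  condition: F(3, 32.9) = 324.362, p = 1.64e-24
  group:condition: F(3, 32.9) = 42.398, p = 2.065e-11
Post-hoc contrasts (Bonferroni x 11):
  V_CI - V_HC: est = 0.958, t(35.0) = 3.22, p = 0.03041
  A_CI - A_HC: est = -0.604, t(35.0) = -1.52, p = 1
  A_CI - V_CI: est = 1.982, t(35.3) = 15.29, p = 4.257e-16
  A_HC - V_HC: est = 3.544, t(34.6) = 25.33, p = 6.695e-23
  (A_CI - V_CI) - (A_HC - V_HC): est = -1.562, t(34.9) = -8.19, p = 1.323e-08
  ...
```

Reading this: both groups synchronize far better to the auditory than to
the visual metronome (the large positive `A − V` contrasts, in logit-R
units), and the group × condition interaction is driven by the auditory
and congruence advantages being larger in controls — the pattern the
generator's default consistency levels encode.  Exclusion counts per
group × condition (wrong-rate trials) are written alongside.

The stages are also available separately (`tapsync simulate`, `detect`,
`score`, `analyze`) and as library functions:

```python
from tapsync import CONDITIONS, TapperParams, simulate_tapper, score_trial

trial = simulate_tapper(CONDITIONS["A"], TapperParams(kappa=4.0), seed=1)
score = score_trial(trial)
print(score.vector_length, score.parity, score.rayleigh_p)
# 0.869...  odd  1.04e-12   (A(4) = I1(4)/I0(4) ≈ 0.864)
```

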