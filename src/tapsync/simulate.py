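"""Synthetic tapping data: stimulus-locked tappers, force traces, studies.

The generator emulates the study conditions: 20 cochlear-implant (CI)
users and 17 hearing controls (HC), 10 trials in each of four conditions
(auditory, visual, synchronous and asynchronous audio-visual), 39.5 s
trials, tapping every second beat from beat 3.  Tapper phase noise is von
Mises — the circular analogue of Gaussian jitter — whose concentration κ
maps to an expected mean resultant length through the Bessel ratio
A(κ) = I₁(κ)/I₀(κ), so planted consistency levels can be checked against
scored values.  Recording artifacts are reproduced: a single 1.46 s signal
dropout at a variable location in most trials, occasional wrong-rate
trials (every beat or every third beat), double taps, missed taps and
mid-trial pauses long enough to exercise the Q3 + 3×IQR pause rule.

Default per-cell consistency levels (group × condition, on the logit-R
scale) and wrong-rate trial probabilities follow the published group
summary table and exclusion counts, so a default synthetic study looks
like the real one at the summary level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, i0e, i1e

from .detect import FSRSignal, TapEventSeries
from .scoring import TapTrial, logit_transform, mean_resultant
from .stimuli import (
    CONDITION_NAMES,
    CONDITIONS,
    INSTRUCTED_MULTIPLIER,
    INSTRUCTED_START_BEAT,
    ConditionSpec,
)

__all__ = [
    "TapperParams",
    "ParticipantRecord",
    "StudyDesign",
    "StudyDataset",
    "bessel_ratio",
    "kappa_for_mean_r",
    "simulate_tapper",
    "simulate_fsr_signal",
    "generate_study",
    "simulate_score_table",
    "DEFAULT_CELL_LOGIT",
    "DEFAULT_WRONG_RATE_PROB",
    "DROPOUT_LENGTH_S",
]

#: duration of the recording-system signal dropout
DROPOUT_LENGTH_S = 1.46

#: group × condition mean logit consistency used as generator defaults
DEFAULT_CELL_LOGIT: dict[str, dict[str, float]] = {
    "HC": {"A": 2.64, "V": -1.22, "AVsync": 1.71, "AVasync": -2.16},
    "CI": {"A": 1.38, "V": -0.69, "AVsync": 0.20, "AVasync": -1.72},
}

#: per-trial probability of tapping at the wrong rate (1x or 3x), matching
#: the published exclusion counts over trials run (HC: 17×10, CI: 20×10)
DEFAULT_WRONG_RATE_PROB: dict[str, dict[str, float]] = {
    "HC": {"A": 6 / 170, "V": 18 / 170, "AVsync": 17 / 170, "AVasync": 4 / 170},
    "CI": {"A": 25 / 200, "V": 13 / 200, "AVsync": 33 / 200, "AVasync": 17 / 200},
}


def bessel_ratio(kappa: float) -> float:
    """Expected mean resultant length of a von Mises sample, A(κ) = I₁(κ)/I₀(κ)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if math.isinf(kappa):
        return 1.0
    return float(i1e(kappa) / i0e(kappa))


def kappa_for_mean_r(r: float) -> float:
    """Invert the Bessel ratio: concentration κ with A(κ) = r."""
    if not 0.0 <= r < 1.0:
        raise ValueError("r must be in [0, 1)")
    if r == 0.0:
        return 0.0
    return float(brentq(lambda k: bessel_ratio(k) - r, 1e-9, 1e4))


@dataclass(frozen=True)
class TapperParams:
    """Generative parameters of one simulated tapper/trial.

    kappa : von Mises concentration of the tap phase around ``mean_phase``
        (∞, via ``noise_free=True``, gives perfectly repeatable phase;
        0 gives uniform phase, i.e. chance tapping).
    mean_phase : preferred phase in radians; negative values model the
        anticipation (negative mean asynchrony) typical of paced tapping.
    period_multiplier : taps every m-th stimulus (instructed: 2).
    start_beat : 1-based stimulus index of the first tap (instructed: 3).
    """

    kappa: float = 8.0
    mean_phase: float = -0.3
    period_multiplier: int = INSTRUCTED_MULTIPLIER
    start_beat: int = INSTRUCTED_START_BEAT
    pause_prob: float = 0.0
    pause_length: float = 3.5
    double_tap_prob: float = 0.0
    miss_prob: float = 0.0
    noise_free: bool = False

    def __post_init__(self) -> None:
        if self.kappa < 0 and not self.noise_free:
            raise ValueError("kappa must be >= 0")
        for p in (self.pause_prob, self.double_tap_prob, self.miss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.period_multiplier not in (1, 2, 3):
            raise ValueError("period_multiplier must be 1, 2 or 3")
        if self.start_beat < 1:
            raise ValueError("start_beat must be >= 1")
        if self.pause_length <= 0:
            raise ValueError("pause_length must be positive")


def simulate_tapper(
    condition: ConditionSpec,
    params: TapperParams,
    seed: int | np.random.Generator = 0,
) -> TapTrial:
    """Simulate one trial of stochastic paced tapping.

    Tap times are the reference-stream beats (every ``period_multiplier``-th
    stimulus from ``start_beat``) perturbed by von Mises phase noise scaled
    to the tapper's own period, with pauses, misses and double taps
    injected at the configured probabilities.  Deterministic under a fixed
    seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stim = condition.reference_stimuli()
    beats = stim.onsets[params.start_beat - 1 :: params.period_multiplier]
    period = params.period_multiplier * stim.isi

    if params.noise_free:
        phases = np.full(len(beats), params.mean_phase)
    else:
        phases = rng.vonmises(params.mean_phase, params.kappa, size=len(beats))
    taps = beats + phases / (2 * np.pi) * period

    keep = np.ones(len(taps), dtype=bool)
    # mid-trial pauses: a pause starting at a tap swallows every scheduled
    # tap within pause_length
    if params.pause_prob > 0:
        pause_until = -np.inf
        for i, t in enumerate(beats):
            if t < pause_until:
                keep[i] = False
            elif rng.random() < params.pause_prob:
                pause_until = t + params.pause_length
                keep[i] = False
    if params.miss_prob > 0:
        keep &= rng.random(len(taps)) >= params.miss_prob
    taps = taps[keep]

    if params.double_tap_prob > 0 and len(taps):
        doubled = rng.random(len(taps)) < params.double_tap_prob
        extras = taps[doubled] + rng.uniform(0.05, 0.12, doubled.sum())
        taps = np.concatenate([taps, extras])

    taps = np.unique(taps[(taps >= 0) & (taps <= condition.duration)])
    return TapTrial(
        participant_id="sim",
        condition=condition,
        events=TapEventSeries(tap_times=taps, source="simulated"),
        reference_stimuli=stim,
        secondary_stimuli=condition.secondary_stimuli(),
        ground_truth=params,
    )


def simulate_fsr_signal(
    trial: TapTrial,
    sample_rate: float = 500.0,
    pulse_width_s: float = 0.030,
    pulse_amplitude: float = 1.0,
    noise_sd: float = 0.0,
    dropout: Optional[tuple[float, float]] = None,
    seed: int | np.random.Generator = 0,
) -> FSRSignal:
    """Render a force trace with one half-sine pulse per tap.

    ``dropout`` is (start, length) of a signal-loss window; the trace there
    holds the last pre-dropout sample (constant fill), and taps inside the
    window leave no pulse — emulating the recording malfunction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = trial.condition.duration
    if pulse_width_s * sample_rate < 2:
        raise ValueError("sample_rate too low for the pulse width")
    n = round(duration * sample_rate)
    samples = np.zeros(n)
    width = max(2, round(pulse_width_s * sample_rate))
    # fast attack, sinusoidal release: the onset sample is already at peak,
    # so a mid-range threshold crossing stays within one sample of the tap
    pulse = pulse_amplitude * np.cos(0.5 * np.pi * np.arange(width) / (width - 1))

    drop_lo = drop_hi = None
    if dropout is not None:
        drop_lo, length = dropout
        drop_hi = drop_lo + length
        if drop_lo < 0 or drop_hi > duration:
            raise ValueError("dropout window outside trial duration")

    for t in trial.events.tap_times:
        if drop_lo is not None and drop_lo <= t < drop_hi:
            continue  # signal lost: tap leaves no trace
        i0 = round(t * sample_rate)
        i1 = min(i0 + width, n)
        if i0 < n:
            samples[i0:i1] += pulse[: i1 - i0]

    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, n)

    interval = None
    if drop_lo is not None:
        a, b = round(drop_lo * sample_rate), min(round(drop_hi * sample_rate), n)
        fill = samples[a - 1] if a > 0 else 0.0
        samples[a:b] = fill
        interval = (drop_lo, drop_hi)
    return FSRSignal(samples=samples, sample_rate=sample_rate, dropout_interval=interval)


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's group membership and (for CI users) clinical history."""

    id: str
    group: str  # "CI" or "HC"
    age: float
    onset_age: Optional[float] = None
    pre_linguistic: bool = False
    deafness_duration: Optional[float] = None
    implantation_age: Optional[float] = None
    ci_use_years: Optional[float] = None

    def onset_age_coded(self) -> Optional[float]:
        """Onset age for regression; pre-linguistic onset is coded as 2 years."""
        if self.group != "CI":
            return None
        return 2.0 if self.pre_linguistic else self.onset_age


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of one synthetic study; identical seed ⇒ identical dataset."""

    n_ci: int = 20
    n_hc: int = 17
    trials_per_condition: int = 10
    cell_logit: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CELL_LOGIT.items()})
    wrong_rate_prob: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_WRONG_RATE_PROB.items()}
    )
    #: between-participant sd of consistency on the logit scale
    participant_sd: float = 1.0
    #: participant × condition sd (random-slope heterogeneity), logit scale
    slope_sd: float = 0.4
    mean_phase: float = -0.3
    mean_phase_sd: float = 0.15
    parity_even_prob: float = 0.3
    dropout_prob: float = 0.9
    dropout_length: float = DROPOUT_LENGTH_S
    pause_prob: float = 0.02
    double_tap_prob: float = 0.02
    miss_prob: float = 0.03
    #: additive logit shifts planted on specific cells, e.g.
    #: {("HC", "AVsync"): 1.5}; used for effect-recovery experiments
    planted_logit: dict = field(default_factory=dict)
    seed: int = 0

    def kappa_table(self) -> dict[tuple[str, str], float]:
        """Cell κ values implied by the cell logit means (plus planted shifts)."""
        out = {}
        for g, conds in self.cell_logit.items():
            for c, m in conds.items():
                m = m + self.planted_logit.get((g, c), 0.0)
                out[(g, c)] = kappa_for_mean_r(float(np.clip(expit(m), 0.01, 0.995)))
        return out


@dataclass
class StudyDataset:
    """Simulated participants and trials, with ground truth retained."""

    participants: list[ParticipantRecord]
    trials: list[TapTrial]
    design: StudyDesign

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append(
                {
                    "participant_id": p.id,
                    "group": p.group,
                    "age": p.age,
                    "onset_age": "pre_linguistic" if p.pre_linguistic else p.onset_age,
                    "deafness_duration": p.deafness_duration,
                    "implantation_age": p.implantation_age,
                    "ci_use_years": p.ci_use_years,
                }
            )
        return pd.DataFrame(rows)

    def events_frame(self) -> pd.DataFrame:
        """Long-format event table: one row per tap."""
        rows = []
        for tr in self.trials:
            for t in tr.events.tap_times:
                rows.append(
                    (tr.participant_id, tr.group, tr.condition.name, tr.trial_index, round(t, 6))
                )
        return pd.DataFrame(
            rows, columns=["participant_id", "group", "condition", "trial", "tap_time_s"]
        )


def _simulate_clinical(pid: str, group: str, rng: np.random.Generator) -> ParticipantRecord:
    if group == "HC":
        return ParticipantRecord(id=pid, group="HC", age=float(np.clip(rng.normal(41, 15), 18, 72)))
    pre = rng.random() < 0.15
    onset = float(rng.uniform(0.5, 2.0)) if pre else float(rng.uniform(1, 49))
    duration = float(np.clip(rng.exponential(12), 1, 35))
    implantation = onset + duration
    ci_use = float(rng.uniform(1, 18))
    return ParticipantRecord(
        id=pid,
        group="CI",
        age=implantation + ci_use,
        onset_age=None if pre else onset,
        pre_linguistic=pre,
        deafness_duration=duration,
        implantation_age=implantation,
        ci_use_years=ci_use,
    )


def generate_study(design: StudyDesign = StudyDesign()) -> StudyDataset:
    """Simulate a full study at the event level.

    Each participant gets a consistency offset and per-condition slope
    offsets on the logit scale around the group × condition cell means;
    the resulting target consistency is converted to a von Mises κ through
    the inverse Bessel ratio.  Trials add wrong-rate lapses, odd/even
    phase choice, signal dropouts, pauses, double taps and misses.
    """
    if design.n_ci <= 0 or design.n_hc <= 0 or design.trials_per_condition <= 0:
        raise ValueError("counts must be positive")
    for g in ("CI", "HC"):
        for c in CONDITION_NAMES:
            if c not in design.cell_logit.get(g, {}):
                raise ValueError(f"cell_logit missing entry for ({g}, {c})")
    rng = np.random.default_rng(design.seed)
    kappas = design.kappa_table()

    participants: list[ParticipantRecord] = []
    trials: list[TapTrial] = []
    groups = [("CI", design.n_ci), ("HC", design.n_hc)]
    for group, n in groups:
        for i in range(n):
            pid = f"{group}{i + 1:02d}"
            participants.append(_simulate_clinical(pid, group, rng))
            b0 = rng.normal(0.0, design.participant_sd)
            phase = rng.normal(design.mean_phase, design.mean_phase_sd)
            for cond_name in CONDITION_NAMES:
                cond = CONDITIONS[cond_name]
                b_c = rng.normal(0.0, design.slope_sd)
                cell = design.cell_logit[group][cond_name] + design.planted_logit.get(
                    (group, cond_name), 0.0
                )
                target_r = float(np.clip(expit(cell + b0 + b_c), 0.01, 0.995))
                kappa = kappa_for_mean_r(target_r)
                for j in range(design.trials_per_condition):
                    wrong = rng.random() < design.wrong_rate_prob[group][cond_name]
                    mult = int(rng.choice([1, 3])) if wrong else 2
                    start = 4 if rng.random() < design.parity_even_prob else 3
                    params = TapperParams(
                        kappa=kappa,
                        mean_phase=phase,
                        period_multiplier=mult,
                        start_beat=start,
                        pause_prob=design.pause_prob,
                        double_tap_prob=design.double_tap_prob,
                        miss_prob=design.miss_prob,
                    )
                    trial = simulate_tapper(cond, params, rng)
                    dropout = None
                    events = trial.events
                    if rng.random() < design.dropout_prob:
                        lo = rng.uniform(1.0, cond.duration - design.dropout_length - 0.5)
                        dropout = (lo, lo + design.dropout_length)
                        mask = (events.tap_times >= lo) & (events.tap_times < dropout[1])
                        events = TapEventSeries(
                            tap_times=events.tap_times[~mask], source="simulated"
                        )
                    trials.append(
                        replace(
                            trial,
                            participant_id=pid,
                            group=group,
                            trial_index=j,
                            events=events,
                            dropout_interval=dropout,
                        )
                    )
    return StudyDataset(participants=participants, trials=trials, design=design)


def simulate_score_table(
    design: StudyDesign = StudyDesign(),
    n_taps: int = 40,
    rng: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fast path: simulate trial-level logit consistency scores directly.

    Uses the same participant/condition hierarchy as :func:`generate_study`
    but skips event-level machinery: each trial draws ``n_taps`` von Mises
    phases and scores their mean resultant length.  Intended for model
    calibration studies (type-I error, power) where only the score table
    matters.  No artifact or exclusion modelling.
    """
    if rng is None:
        rng = design.seed
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    for group, n in (("CI", design.n_ci), ("HC", design.n_hc)):
        for i in range(n):
            pid = f"{group}{i + 1:02d}"
            b0 = rng.normal(0.0, design.participant_sd)
            for cond in CONDITION_NAMES:
                b_c = rng.normal(0.0, design.slope_sd)
                cell = design.cell_logit[group][cond] + design.planted_logit.get(
                    (group, cond), 0.0
                )
                target_r = float(np.clip(expit(cell + b0 + b_c), 0.01, 0.995))
                kappa = kappa_for_mean_r(target_r)
                phases = rng.vonmises(0.0, kappa, size=(design.trials_per_condition, n_taps))
                r_trial = np.abs(np.exp(1j * phases).mean(axis=1))
                for j, r in enumerate(r_trial):
                    rows.append((pid, group, cond, j, logit_transform(min(float(r), 1.0))))
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "condition", "trial", "logit_consistency"]
    )
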