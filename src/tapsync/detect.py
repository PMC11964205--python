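"""Tap-onset detection from force-sensor (FSR) traces and artifact guards.

Tap times are taken at upward threshold crossings of the force trace.  Two
countermeasures deal with recording artifacts:

* a post-dropout guard: the recording system lost the signal for a single
  1.46 s window in most trials, and taps detected shortly after the signal
  resumes are unreliable, so any tap within 75% of the instructed
  inter-tap interval after the dropout end is discarded
  (625 ms at 2.4 Hz when tapping every second beat);
* a refractory rule replacing manual double-tap removal: within any run of
  detected events closer than the refractory interval, only the first is
  kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FSRSignal",
    "TapEventSeries",
    "DISCARD_REASONS",
    "detect_taps",
    "auto_threshold",
    "dropout_guard_window",
    "apply_dropout_guard",
    "remove_double_taps",
    "DEFAULT_REFRACTORY_S",
]

#: default refractory interval for double-tap suppression, well below half
#: the shortest plausible inter-tap interval in this task (2/2.6 Hz ≈ 769 ms)
DEFAULT_REFRACTORY_S = 0.150

DISCARD_REASONS = ("post_dropout", "refractory", "pause_outlier", "initial_trim", "manual")


@dataclass(frozen=True)
class FSRSignal:
    """A sampled force trace for one trial.

    ``dropout_interval`` is the (start, end) of the signal-loss window in
    seconds, if one occurred; samples inside it hold a constant fill value.
    """

    samples: np.ndarray
    sample_rate: float
    dropout_interval: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


@dataclass(frozen=True)
class TapEventSeries:
    """Tap times for one trial, plus a log of discarded events.

    ``tap_times`` are strictly increasing times in seconds.  ``discarded``
    holds ``(time, reason)`` pairs with reasons from ``DISCARD_REASONS``;
    kept plus discarded events together conserve the input events.
    """

    tap_times: np.ndarray
    source: str = "detected"
    discarded: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.tap_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("tap_times must be strictly increasing")
        for _, reason in self.discarded:
            if reason not in DISCARD_REASONS:
                raise ValueError(f"unknown discard reason {reason!r}")
        object.__setattr__(self, "tap_times", t)

    def __len__(self) -> int:
        return len(self.tap_times)

    def discard(self, mask: np.ndarray, reason: str) -> "TapEventSeries":
        """Return a copy with ``mask``-selected taps moved to ``discarded``."""
        mask = np.asarray(mask, dtype=bool)
        removed = tuple((float(t), reason) for t in self.tap_times[mask])
        return replace(
            self,
            tap_times=self.tap_times[~mask],
            discarded=self.discarded + removed,
        )


def auto_threshold(samples: np.ndarray) -> float:
    """Midpoint between the baseline median and the median pulse peak.

    The trace baseline is the overall median (tap pulses are sparse); pulse
    peaks are local maxima with at least half the baseline-to-maximum range
    of prominence.
    """
    from scipy.signal import find_peaks

    samples = np.asarray(samples, dtype=float)
    baseline = float(np.median(samples))
    span = float(samples.max() - baseline)
    if span <= 0:
        return baseline + 0.5  # flat trace: any positive offset, no crossings
    peaks, _ = find_peaks(samples, prominence=span / 2)
    peak_level = float(np.median(samples[peaks])) if len(peaks) else float(samples.max())
    return 0.5 * (baseline + peak_level)


def detect_taps(signal: FSRSignal, threshold: Optional[float] = None) -> TapEventSeries:
    """Detect tap onsets as upward threshold crossings of the force trace.

    The event time is the time of the first suprathreshold sample of each
    crossing (no sub-sample interpolation).  Crossings inside the signal
    dropout window, if any, are suppressed.

    Parameters
    ----------
    signal : FSRSignal
    threshold : float, optional
        Force threshold; defaults to :func:`auto_threshold` of the trace.
    """
    samples = np.asarray(signal.samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty signal")
    if not np.all(np.isfinite(samples)):
        raise ValueError("signal contains non-finite samples")
    if threshold is None:
        threshold = auto_threshold(samples)
    above = samples > threshold
    # upward crossings: first sample of each suprathreshold run
    onset_idx = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    times = onset_idx / signal.sample_rate
    if signal.dropout_interval is not None:
        lo, hi = signal.dropout_interval
        times = times[(times < lo) | (times >= hi)]
    return TapEventSeries(tap_times=times, source="detected")


def dropout_guard_window(stimulus_rate: float, period_multiplier: int = 2) -> float:
    """Guard window after a signal dropout: 75% of the instructed inter-tap
    interval, i.e. ``0.75 * period_multiplier / stimulus_rate`` seconds
    (625 ms for tapping every 2nd beat of a 2.4 Hz metronome)."""
    if stimulus_rate <= 0:
        raise ValueError("stimulus_rate must be positive")
    if period_multiplier < 1:
        raise ValueError("period_multiplier must be >= 1")
    return 0.75 * period_multiplier / stimulus_rate


def apply_dropout_guard(
    events: TapEventSeries, dropout_end: Optional[float], window: float
) -> TapEventSeries:
    """Discard taps in the half-open window ``[dropout_end, dropout_end + window)``.

    Identity when ``dropout_end`` is None (trial without dropout).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if dropout_end is None:
        return events
    t = events.tap_times
    mask = (t >= dropout_end) & (t < dropout_end + window)
    if not mask.any():
        return events
    return events.discard(mask, "post_dropout")


def remove_double_taps(
    events: TapEventSeries, refractory: float = DEFAULT_REFRACTORY_S
) -> TapEventSeries:
    """Suppress double taps: within any run of taps spaced closer than
    ``refractory`` seconds, keep only the first (applied left to right)."""
    if refractory <= 0:
        raise ValueError("refractory must be positive")
    t = events.tap_times
    if len(t) < 2:
        return events
    keep = np.ones(len(t), dtype=bool)
    last_kept = t[0]
    for i in range(1, len(t)):
        if t[i] - last_kept < refractory:
            keep[i] = False
        else:
            last_kept = t[i]
    if keep.all():
        return events
    return events.discard(~keep, "refractory")
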