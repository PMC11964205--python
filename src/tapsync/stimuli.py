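"""Isochronous metronome streams and the four synchronization conditions.

The task presents isochronous pulse trains at 2.4 Hz (auditory and visual)
or 2.6 Hz (the detuned visual stream of the asynchronous audio-visual
condition) for 39.5 s.  Participants tap once every two beats, starting on
beat 3, so the instructed tap period is twice the inter-stimulus interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "StimulusSequence",
    "ConditionSpec",
    "CONDITIONS",
    "CONDITION_NAMES",
    "generate_stimulus_train",
    "AUDITORY_RATE_HZ",
    "VISUAL_RATE_HZ",
    "ASYNC_VISUAL_RATE_HZ",
    "TRIAL_DURATION_S",
    "INSTRUCTED_MULTIPLIER",
    "INSTRUCTED_START_BEAT",
]

AUDITORY_RATE_HZ = 2.4
VISUAL_RATE_HZ = 2.4
#: rate of the visual stream when it is deliberately detuned from the
#: 2.4 Hz auditory stream (asynchronous audio-visual condition)
ASYNC_VISUAL_RATE_HZ = 2.6
TRIAL_DURATION_S = 39.5
INSTRUCTED_MULTIPLIER = 2
INSTRUCTED_START_BEAT = 3


@dataclass(frozen=True)
class StimulusSequence:
    """Onset times of one isochronous metronome stream.

    Attributes
    ----------
    onsets : np.ndarray
        Strictly increasing onset times in seconds, starting at 0.
    rate : float
        Pulse rate in Hz; the inter-stimulus interval is ``1 / rate``.
    duration : float
        Total sequence duration in seconds.
    modality : str
        ``"auditory"`` or ``"visual"``.
    """

    onsets: np.ndarray
    rate: float
    duration: float
    modality: str

    @property
    def isi(self) -> float:
        """Inter-stimulus interval in seconds (1/rate)."""
        return 1.0 / self.rate

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.onsets)


def generate_stimulus_train(
    rate: float, duration: float, modality: str = "auditory"
) -> StimulusSequence:
    """Generate an isochronous onset train ``{k/rate : k = 0..floor(duration*rate)}``.

    Parameters
    ----------
    rate : float
        Metronome rate in Hz (must be > 0).
    duration : float
        Sequence duration in seconds (must be > 0); the last onset is the
        largest multiple of the interval not exceeding ``duration``.
    modality : str
        ``"auditory"`` or ``"visual"``.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if modality not in ("auditory", "visual"):
        raise ValueError(f"unknown modality {modality!r}")
    n = math.floor(duration * rate) + 1
    onsets = np.arange(n, dtype=float) / rate
    return StimulusSequence(onsets=onsets, rate=rate, duration=duration, modality=modality)


@dataclass(frozen=True)
class ConditionSpec:
    """One of the four task conditions: A, V, AVsync, AVasync.

    ``reference_stream`` names the stream against which tapping is scored.
    In the multisensory conditions this defaults to the visual stream,
    matching the framing of the multisensory contrasts against the
    visual-only baseline; it is configurable because the instructions to
    participants did not single out a stream.
    """

    name: str
    auditory_rate: Optional[float] = None
    visual_rate: Optional[float] = None
    reference_stream: str = "auditory"
    duration: float = TRIAL_DURATION_S

    def __post_init__(self) -> None:
        if self.name not in ("A", "V", "AVsync", "AVasync"):
            raise ValueError(f"unknown condition name {self.name!r}")
        if self.reference_stream == "auditory" and self.auditory_rate is None:
            raise ValueError("reference_stream is auditory but no auditory_rate")
        if self.reference_stream == "visual" and self.visual_rate is None:
            raise ValueError("reference_stream is visual but no visual_rate")

    @property
    def reference_rate(self) -> float:
        if self.reference_stream == "auditory":
            return float(self.auditory_rate)
        return float(self.visual_rate)

    def reference_stimuli(self) -> StimulusSequence:
        return generate_stimulus_train(self.reference_rate, self.duration, self.reference_stream)

    def secondary_stimuli(self) -> Optional[StimulusSequence]:
        if self.auditory_rate is not None and self.visual_rate is not None:
            if self.reference_stream == "visual":
                return generate_stimulus_train(self.auditory_rate, self.duration, "auditory")
            return generate_stimulus_train(self.visual_rate, self.duration, "visual")
        return None


#: The four study conditions.  AVsync pairs both streams at 2.4 Hz; AVasync
#: detunes the visual stream to 2.6 Hz.  Scoring in the multisensory
#: conditions references the visual stream.
CONDITIONS: dict[str, ConditionSpec] = {
    "A": ConditionSpec("A", auditory_rate=AUDITORY_RATE_HZ, reference_stream="auditory"),
    "V": ConditionSpec("V", visual_rate=VISUAL_RATE_HZ, reference_stream="visual"),
    "AVsync": ConditionSpec(
        "AVsync",
        auditory_rate=AUDITORY_RATE_HZ,
        visual_rate=VISUAL_RATE_HZ,
        reference_stream="visual",
    ),
    "AVasync": ConditionSpec(
        "AVasync",
        auditory_rate=AUDITORY_RATE_HZ,
        visual_rate=ASYNC_VISUAL_RATE_HZ,
        reference_stream="visual",
    ),
}

CONDITION_NAMES = tuple(CONDITIONS)
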