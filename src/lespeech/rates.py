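"""Speaking rate and articulation rate from timestamped ASR transcripts.

Both rates drop the first and last word of the transcript: word-level
timestamps at the edges of a recording suffer border effects and are
unreliable. Speaking rate (SR, words/min) divides the retained word count by
the span from the onset of the first retained word to the offset of the last
retained word. Articulation rate (AR, syllables/s) uses the same window but
removes inter-word gaps at or above a pause threshold from the denominator
and divides syllables instead of words.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .text import count_syllables_text, normalize_token

__all__ = [
    "WordToken",
    "Transcript",
    "RateConfig",
    "speaking_rate",
    "articulation_rate",
    "recording_rates",
]

DEFAULT_PAUSE_THRESHOLD_S = 0.200


@dataclass(frozen=True)
class WordToken:
    """One ASR word with its time interval and recognition probability."""

    text: str
    start_s: float
    end_s: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"word {self.text!r}: end {self.end_s} not after start {self.start_s}"
            )


@dataclass
class Transcript:
    """Timestamped ASR output for one recording.

    ``asr_confidence`` is the recording-level transcriber confidence
    (geometric mean of word probabilities when available).
    """

    recording_id: str
    reference_text: str
    tokens: list[WordToken] = field(default_factory=list)
    asr_confidence: float = float("nan")

    def __post_init__(self) -> None:
        for a, b in zip(self.tokens, self.tokens[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(
                    f"transcript {self.recording_id}: overlapping tokens "
                    f"{a.text!r} and {b.text!r}"
                )

    @property
    def asr_text(self) -> str:
        return " ".join(t.text for t in self.tokens)


@dataclass(frozen=True)
class RateConfig:
    pause_threshold_s: float = DEFAULT_PAUSE_THRESHOLD_S


class UndefinedRateError(ValueError):
    """Raised when a rate is undefined for a transcript (too few words, zero span)."""


def _retained(t: Transcript) -> list[WordToken]:
    if len(t.tokens) < 3:
        raise UndefinedRateError(
            f"transcript {t.recording_id}: need >= 3 words, got {len(t.tokens)}"
        )
    return t.tokens[1:-1]


def speaking_rate(t: Transcript) -> float:
    """Words per minute over the retained window (pauses included)."""
    kept = _retained(t)
    span = kept[-1].end_s - kept[0].start_s
    if span <= 0:
        raise UndefinedRateError(f"transcript {t.recording_id}: zero time span")
    return len(kept) / span * 60.0


def articulation_rate(
    t: Transcript, pause_threshold_s: float = DEFAULT_PAUSE_THRESHOLD_S
) -> float:
    """Syllables per second over the retained window with pauses removed.

    A pause is an inter-word gap of at least ``pause_threshold_s`` seconds;
    such gaps are subtracted from the speech time before dividing.
    """
    kept = _retained(t)
    span = kept[-1].end_s - kept[0].start_s
    pause_time = sum(
        gap
        for a, b in zip(kept, kept[1:])
        if (gap := b.start_s - a.end_s) >= pause_threshold_s
    )
    artic_time = span - pause_time
    if artic_time <= 0:
        raise UndefinedRateError(
            f"transcript {t.recording_id}: non-positive articulation time"
        )
    words = [w for w in (normalize_token(k.text) for k in kept) if w]
    return count_syllables_text(words) / artic_time


def recording_rates(
    t: Transcript, config: RateConfig | None = None
) -> tuple[float, float, float]:
    """(SR, AR, asr_confidence) with NaN for undefined rates instead of raising."""
    config = config or RateConfig()
    try:
        sr = speaking_rate(t)
    except (UndefinedRateError, ValueError):
        sr = math.nan
    try:
        ar = articulation_rate(t, config.pause_threshold_s)
    except (UndefinedRateError, ValueError):
        ar = math.nan
    return sr, ar, t.asr_confidence
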