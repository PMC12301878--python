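"""Three-stage quality-assurance cascade for rated speech recordings.

Applied in fixed order (order matters for the per-stage counts, so it is
part of the contract):

1. **Rater notes** — drop recordings whose rater notes mention recording
   trouble (case-insensitive substring match on a keyword list: 'noise',
   'volume', 'quality', 'recording', 'sample', 'error', 'nothing',
   'no speech'). Such recordings were typically rated only to advance the
   rating platform, not as genuine assessments.
2. **Hallucination screen** — keep only recordings whose ASR transcript
   reproduces at least 20% (inclusive) of the presented sentence's words;
   automatic transcribers can fabricate content, which corrupts the speaking
   rate and confidence features.
3. **Minimum rated recordings** — drop sessions left with a single
   surviving recording, so session-level LE means stay comparable.

`run_qa` returns the surviving records plus a `QAReport` of per-stage
recording/session counts and per-recording exclusion reasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from scipy.stats import mannwhitneyu

from .rates import Transcript
from .synth import QA_KEYWORDS
from .text import match_fraction

__all__ = [
    "RecordingRecord",
    "QAReport",
    "filter_notes",
    "filter_hallucination",
    "filter_min_rated",
    "run_qa",
    "compare_excluded_distribution",
]

DEFAULT_MIN_MATCH = 0.20


@dataclass
class RecordingRecord:
    """One recording with its session linkage, rater notes and transcript."""

    recording_id: str
    session_id: str
    participant_id: str
    notes: list[str] = field(default_factory=list)
    transcript: Transcript | None = None
    le_scores: list[float] = field(default_factory=list)


@dataclass
class QAReport:
    """Per-stage accounting of the cascade."""

    stages: list[str] = field(default_factory=list)
    recordings: list[int] = field(default_factory=list)
    sessions: list[int] = field(default_factory=list)
    exclusion_reason: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, records: list[RecordingRecord]) -> None:
        self.stages.append(stage)
        self.recordings.append(len(records))
        self.sessions.append(len({r.session_id for r in records}))

    def as_dict(self) -> dict:
        return {
            "stages": self.stages,
            "recordings": self.recordings,
            "sessions": self.sessions,
            "exclusion_reason": self.exclusion_reason,
        }


def _note_flagged(record: RecordingRecord, keywords: Iterable[str]) -> bool:
    blob = " ".join(record.notes).lower()
    return any(k.lower() in blob for k in keywords)


def filter_notes(
    records: list[RecordingRecord], keywords: Iterable[str] = tuple(QA_KEYWORDS)
) -> tuple[list[RecordingRecord], list[RecordingRecord]]:
    """Split records on the keyword note screen (kept, excluded)."""
    keywords = list(keywords)
    if not keywords:
        raise ValueError("keyword list is empty")
    kept = [r for r in records if not _note_flagged(r, keywords)]
    excluded = [r for r in records if _note_flagged(r, keywords)]
    return kept, excluded


def filter_hallucination(
    records: list[RecordingRecord], min_match: float = DEFAULT_MIN_MATCH
) -> tuple[list[RecordingRecord], list[RecordingRecord], dict[str, str]]:
    """Split records on the transcript-match screen; the bound is inclusive."""
    kept, excluded, reasons = [], [], {}
    for r in records:
        if r.transcript is None:
            excluded.append(r)
            reasons[r.recording_id] = "missing_transcript"
        elif (
            match_fraction(r.transcript.reference_text, r.transcript.asr_text)
            >= min_match
        ):
            kept.append(r)
        else:
            excluded.append(r)
            reasons[r.recording_id] = "hallucinated_transcript"
    return kept, excluded, reasons


def filter_min_rated(
    records: list[RecordingRecord],
) -> tuple[list[RecordingRecord], list[RecordingRecord]]:
    """Drop whole sessions reduced to a single surviving recording."""
    per_session: dict[str, int] = {}
    for r in records:
        per_session[r.session_id] = per_session.get(r.session_id, 0) + 1
    kept = [r for r in records if per_session[r.session_id] >= 2]
    excluded = [r for r in records if per_session[r.session_id] < 2]
    return kept, excluded


def run_qa(
    records: list[RecordingRecord],
    keywords: Iterable[str] = tuple(QA_KEYWORDS),
    min_match: float = DEFAULT_MIN_MATCH,
) -> tuple[list[RecordingRecord], QAReport]:
    """Apply the full cascade in order, with exact per-stage accounting."""
    report = QAReport()
    report.record("input", records)

    kept, excl = filter_notes(records, keywords)
    for r in excl:
        report.exclusion_reason[r.recording_id] = "note_keyword"
    report.record("notes", kept)

    kept, excl, reasons = filter_hallucination(kept, min_match)
    report.exclusion_reason.update(reasons)
    report.record("hallucination", kept)

    kept, excl = filter_min_rated(kept)
    for r in excl:
        report.exclusion_reason[r.recording_id] = "session_min_recordings"
    report.record("min_rated", kept)
    return kept, report


def compare_excluded_distribution(
    excluded_scores: list[float], full_scores: list[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of excluded-vs-full LE scores (U, p).

    Reported for QA transparency: a significant shift means a filter
    preferentially removed one end of the severity range.
    """
    if not excluded_scores or not full_scores:
        raise ValueError("both samples must be non-empty")
    res = mannwhitneyu(excluded_scores, full_scores, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
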