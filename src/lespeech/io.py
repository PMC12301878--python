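"""Readers and writers for the on-disk formats plus pipeline configuration.

Formats
-------
* WAV: uncompressed PCM (what the study platform records); read to mono
  float samples in [-1, 1].
* Transcript JSON: ``{recording_id, reference_text, asr_text,
  words: [{w, start_s, end_s, prob}], segment_confidence}`` — a superset of
  common ASR word-timestamp outputs.
* CSV tables (UTF-8, comma, header row, ISO-8601 dates): ratings, sessions,
  participants, features, scores. Times in seconds, rates in wpm and
  syllables/s, LE on 0-100.
* Config: YAML mapping onto `PipelineConfig`; unknown keys are rejected.

Validation collects row-level violations and reports them instead of
silently dropping rows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .acoustics import Waveform
from .rates import Transcript, WordToken
from .synth import QA_KEYWORDS

__all__ = [
    "PipelineConfig",
    "load_config",
    "config_hash",
    "read_wav",
    "write_wav",
    "read_transcript",
    "write_transcript",
    "read_ratings",
    "read_sessions",
    "read_participants",
    "TableValidationError",
]


class TableValidationError(ValueError):
    """A table failed schema validation; the message lists the offenders."""


@dataclass
class PipelineConfig:
    """Every tunable the pipeline exposes, with study-default values."""

    pause_threshold_s: float = 0.200
    pitch_floor_hz: float = 75.0
    pitch_ceiling_hz: float = 500.0
    qa_keywords: list[str] = field(default_factory=lambda: list(QA_KEYWORDS))
    min_match_fraction: float = 0.20
    repeat_policy: str = "first"
    icc_form: str = "agreement"
    random_slope: bool = True
    time_origin: str = "onset"
    cv_outer_folds: int = 5
    cv_inner_folds: int = 5
    cv_grid_size: int = 50
    cv_ks_alpha: float = 0.05
    cv_max_retries: int = 1000
    master_seed: int = 0

    def validate(self) -> None:
        if self.pause_threshold_s < 0:
            raise ValueError("pause_threshold_s must be >= 0")
        if not 0 < self.pitch_floor_hz < self.pitch_ceiling_hz:
            raise ValueError("need 0 < pitch_floor_hz < pitch_ceiling_hz")
        if not 0 <= self.min_match_fraction <= 1:
            raise ValueError("min_match_fraction must lie in [0, 1]")
        if self.repeat_policy != "first":
            raise ValueError("repeat_policy must be 'first'")
        if self.icc_form not in ("agreement", "consistency"):
            raise ValueError("icc_form must be 'agreement' or 'consistency'")
        if self.time_origin not in ("onset", "enrolment"):
            raise ValueError("time_origin must be 'onset' or 'enrolment'")


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; missing file or None gives the defaults."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise TableValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM WAV to mono float samples in [-1, 1] (stereo averaged)."""
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise TableValidationError(f"cannot read WAV {path}: {exc}") from exc
    if data.size == 0:
        raise TableValidationError(f"WAV {path} contains no samples")
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min < 0:
            data = data.astype(np.float64) / max(abs(info.min), info.max)
        else:  # unsigned PCM is offset-binary
            data = (data.astype(np.float64) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(np.float64)
    return Waveform(np.clip(data, -1.0, 1.0), int(rate))


def write_wav(path: str | Path, w: Waveform) -> None:
    samples = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, w.sample_rate_hz, (samples * 32767).astype(np.int16))


def write_transcript(path: str | Path, t: Transcript) -> None:
    payload = {
        "recording_id": t.recording_id,
        "reference_text": t.reference_text,
        "asr_text": t.asr_text,
        "words": [
            {"w": w.text, "start_s": w.start_s, "end_s": w.end_s, "prob": w.confidence}
            for w in t.tokens
        ],
        "segment_confidence": t.asr_confidence,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_transcript(path: str | Path) -> Transcript:
    raw = json.loads(Path(path).read_text())
    try:
        tokens = [
            WordToken(w["w"], float(w["start_s"]), float(w["end_s"]), float(w.get("prob", 1.0)))
            for w in raw["words"]
        ]
        return Transcript(
            recording_id=raw["recording_id"],
            reference_text=raw["reference_text"],
            tokens=tokens,
            asr_confidence=float(raw.get("segment_confidence", float("nan"))),
        )
    except (KeyError, ValueError) as exc:
        raise TableValidationError(f"invalid transcript {path}: {exc}") from exc


def _read_csv_checked(
    path: str | Path, required: list[str]
) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing columns {missing}")
    return df


def read_ratings(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a ratings CSV; returns (valid rows, rejected rows).

    Required columns: rater_id, recording_id, le_score, is_repeat; ``note``
    is optional. Rows with LE outside [0, 100] or non-numeric are rejected
    and returned, never silently dropped.
    """
    df = _read_csv_checked(path, ["rater_id", "recording_id", "le_score", "is_repeat"])
    if "note" not in df.columns:
        df["note"] = ""
    df["note"] = df["note"].fillna("")
    score = pd.to_numeric(df["le_score"], errors="coerce")
    bad = score.isna() | (score < 0) | (score > 100)
    rejected = df.loc[bad].copy()
    valid = df.loc[~bad].copy()
    valid["le_score"] = score[~bad]
    valid["is_repeat"] = valid["is_repeat"].astype(bool)
    return valid, rejected


def read_sessions(path: str | Path) -> pd.DataFrame:
    return _read_csv_checked(
        path, ["session_id", "participant_id", "months_since_enrolment"]
    )


def read_participants(path: str | Path) -> pd.DataFrame:
    df = _read_csv_checked(path, ["participant_id", "group"])
    for col in ("onset_date", "enrolment_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], errors="coerce")
    return df
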