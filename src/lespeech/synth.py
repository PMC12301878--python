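"""Synthetic voices, transcripts and rated cohorts with known ground truth.

Everything downstream — feature extraction, QA, scoring, longitudinal
modelling, the prediction model — is testable against the ground truth this
module carries along:

* `gen_voice` builds a glottal-pulse-train voice with controllable F0,
  jitter, shimmer, two formants and additive-noise SNR, and returns the
  exact per-cycle period/amplitude ledger used during synthesis.
* `gen_transcript` emits timestamped word tokens whose implied speaking
  rate equals the request, with optional pauses and ASR-style corruption.
* `gen_cohort` builds a rated longitudinal cohort: PALS (bulbar and
  non-bulbar onset) and controls with linear true listener-effort (LE)
  trajectories clipped to the 0-100 visual-analogue scale, three raters
  with additive bias and Gaussian noise, a configurable fraction of
  re-presented recordings for intra-rater reliability, and QA contamination
  (keyword notes, corrupted transcripts).

A single master seed expands into per-participant substreams, so adding a
participant never shifts another participant's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .acoustics import Waveform
from .rates import Transcript, WordToken

__all__ = [
    "VoiceSpec",
    "SynthVoice",
    "CohortSpec",
    "CohortData",
    "QA_KEYWORDS",
    "SENTENCE_POOL",
    "gen_voice",
    "gen_transcript",
    "gen_cohort",
    "voice_spec_for_le",
]

# Keyword list searched by the QA note filter.
QA_KEYWORDS = [
    "noise",
    "volume",
    "quality",
    "recording",
    "sample",
    "error",
    "nothing",
    "no speech",
]

# Reading-task sentence pool (11, 13 and 15 words), synthetic stand-ins for
# the study's sentence pools.
SENTENCE_POOL = {
    11: [
        "the quiet river moves past the old stone bridge every single morning",
        "my brother walks his small brown dog around the park before work",
        "she placed the warm bread on the table next to the butter",
    ],
    13: [
        "the children played a long game of cards on the porch after dinner tonight",
        "a gentle rain fell over the green valley while the farmers gathered their tools",
        "he read the morning paper slowly while his coffee cooled on the kitchen table",
    ],
    15: [
        "the old clock in the hallway strikes nine times as the family sits down to eat",
        "every summer the whole town gathers by the lake to watch the boats race at noon",
        "my grandmother keeps a small garden of herbs and roses behind the white fence near the gate",
    ],
}


@dataclass(frozen=True)
class VoiceSpec:
    """Ground-truth parameters for one synthetic voice."""

    f0_hz: float = 120.0
    jitter_pct: float = 1.0
    shimmer_pct: float = 3.0
    formants_hz: tuple[tuple[float, float], ...] = ((500.0, 80.0), (1500.0, 120.0))
    snr_db: float | None = 25.0
    duration_s: float = 2.0
    sample_rate_hz: int = 16000

    def validate(self) -> None:
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise ValueError("jitter/shimmer percentages must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_hz < 8000:
            raise ValueError("sample_rate_hz must be >= 8000")
        for f, _bw in self.formants_hz:
            if f >= self.sample_rate_hz / 2:
                raise ValueError(f"formant {f} Hz at or above Nyquist")


@dataclass
class SynthVoice:
    """A synthesized voice plus its exact cycle ledger (the synthesis oracle)."""

    waveform: Waveform
    spec: VoiceSpec
    pulse_times_s: np.ndarray
    periods_s: np.ndarray
    amplitudes: np.ndarray

    @property
    def true_jitter(self) -> float:
        p = self.periods_s
        return float(np.mean(np.abs(np.diff(p))) / np.mean(p))

    @property
    def true_shimmer(self) -> float:
        a = self.amplitudes
        return float(np.mean(np.abs(np.diff(a))) / np.mean(a))


def gen_voice(spec: VoiceSpec, seed: int | np.random.SeedSequence = 0) -> SynthVoice:
    """Synthesize a voiced pulse-train signal from a `VoiceSpec`.

    Source: an impulse train whose cycle periods are jittered by Gaussian
    noise (SD = jitter_pct/100 of the nominal period) and whose cycle
    amplitudes are perturbed likewise (SD = shimmer_pct/100). With zero
    jitter, periods are rounded to a whole number of samples so the output
    is exactly periodic; with jitter, impulses are placed with two-point
    linear fractional delay so sub-sample timing survives synthesis. The
    train is filtered through a cascade of second-order resonators (one per
    formant), then white noise is added at `snr_db` relative to the
    harmonic power. Deterministic given (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    t0 = 1.0 / spec.f0_hz
    if spec.jitter_pct == 0:
        t0 = round(t0 * fs) / fs  # exact sample-grid periodicity

    # cycle ledger
    times = [0.05 * t0 + t0]  # leave room for the resonator onset
    while times[-1] + 1.5 * t0 < spec.duration_s:
        dt = t0 * (1.0 + spec.jitter_pct / 100.0 * rng.standard_normal())
        times.append(times[-1] + max(dt, 0.2 * t0))
    times = np.asarray(times)
    amps = 1.0 + spec.shimmer_pct / 100.0 * rng.standard_normal(len(times))
    amps = np.maximum(amps, 0.05)

    src = np.zeros(n)
    pos = times * fs
    if spec.jitter_pct == 0:
        idx = np.round(pos).astype(int)
        np.add.at(src, idx[idx < n], amps[idx < n])
    else:
        base = np.floor(pos).astype(int)
        frac = pos - base
        ok = base < n - 1
        np.add.at(src, base[ok], amps[ok] * (1 - frac[ok]))
        np.add.at(src, base[ok] + 1, amps[ok] * frac[ok])

    x = src
    for f, bw in spec.formants_hz:
        r = math.exp(-math.pi * bw / fs)
        theta = 2 * math.pi * f / fs
        x = sps.lfilter([1.0], [1.0, -2 * r * math.cos(theta), r * r], x)

    if spec.snr_db is not None and math.isfinite(spec.snr_db):
        p_harm = float(np.mean(x**2))
        sigma = math.sqrt(p_harm / (10.0 ** (spec.snr_db / 10.0)))
        x = x + sigma * rng.standard_normal(n)

    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    wf = Waveform(x, fs)
    quantized = np.round(pos).astype(int) / fs if spec.jitter_pct == 0 else times
    return SynthVoice(
        waveform=wf,
        spec=spec,
        pulse_times_s=quantized,
        periods_s=np.diff(quantized),
        amplitudes=amps,
    )


_CONSONANTS = "bcdfghjklmnpqrstvwxz"


def _nonsense_word(rng: np.random.Generator, forbidden: set[str]) -> str:
    while True:
        w = "".join(rng.choice(list(_CONSONANTS), size=5))
        if w not in forbidden:
            return w


def gen_transcript(
    sentence: str,
    speaking_rate_wpm: float = 150.0,
    pause_spec: dict[int, float] | None = None,
    corruption_frac: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    recording_id: str = "synthetic",
) -> Transcript:
    """Timestamped transcript whose implied speaking rate equals the request.

    Each word occupies 60/speaking_rate_wpm seconds with no inter-word gap,
    so the retained-window rate convention recovers the requested rate
    exactly (pauses, when requested via ``pause_spec`` = {after-word index:
    gap seconds}, lower it as they would in real speech). A fraction
    ``corruption_frac`` of words is corrupted — replaced by out-of-vocabulary
    strings or deleted — emulating ASR hallucination; corrupted words get
    depressed per-word confidences.
    """
    words = sentence.split()
    if not words:
        raise ValueError("sentence is empty")
    if speaking_rate_wpm <= 0:
        raise ValueError("speaking_rate_wpm must be positive")
    if not 0.0 <= corruption_frac <= 1.0:
        raise ValueError("corruption_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pause_spec = pause_spec or {}
    dur = 60.0 / speaking_rate_wpm
    n = len(words)
    n_corrupt = int(round(corruption_frac * n))
    corrupt_idx = set(rng.choice(n, size=n_corrupt, replace=False).tolist())
    vocab = set(words)

    tokens: list[WordToken] = []
    t = 0.0
    logps = []
    for i, word in enumerate(words):
        action = "keep"
        if i in corrupt_idx:
            action = "replace" if rng.random() < 0.7 else "delete"
        if action != "delete":
            text = word if action == "keep" else _nonsense_word(rng, vocab)
            conf = (
                float(np.clip(rng.normal(0.97, 0.02), 0.5, 1.0))
                if action == "keep"
                else float(np.clip(rng.normal(0.55, 0.10), 0.05, 0.9))
            )
            tokens.append(WordToken(text, t, t + dur, conf))
            logps.append(math.log(conf))
        t += dur
        t += pause_spec.get(i, 0.0)
    conf_overall = math.exp(float(np.mean(logps))) if logps else 0.0
    return Transcript(
        recording_id=recording_id,
        reference_text=sentence,
        tokens=tokens,
        asr_confidence=conf_overall,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic rated cohort.

    Defaults mirror the full sub-study conditions: 105 PALS (22% bulbar
    onset) and 20 controls, LE slopes in points/month by group, three raters
    with small additive biases and 5-point within-rater noise, 20% of
    recordings re-presented for intra-rater reliability, sessions roughly
    every two months.
    """

    n_pals: int = 105
    n_controls: int = 20
    frac_bulbar_onset: float = 0.22
    slope_by_group: dict = field(
        default_factory=lambda: {
            "pals_bulbar": 1.66,
            "pals_nonbulbar": 0.42,
            "control": 0.005,
        }
    )
    # between-participant slope SD; PALS progress at very heterogeneous
    # rates while controls are essentially stable
    slope_sd: dict | float = field(
        default_factory=lambda: {"pals": 1.0, "control": 0.03}
    )
    baseline_le_dist: dict = field(
        default_factory=lambda: {
            "pals_bulbar": (30.0, 18.0),
            "pals_nonbulbar": (12.0, 12.0),
            "control": (3.0, 2.5),
        }
    )
    rater_bias: tuple[float, ...] = (-2.0, 0.0, 2.0)
    rater_sd: float = 5.0
    session_interval_days: float = 60.0
    n_sessions_range: tuple[int, int] = (4, 8)
    repeat_fraction: float = 0.20
    note_contamination_frac: float = 0.0
    transcript_corruption_frac: float = 0.0
    onset_years_range: tuple[float, float] = (0.5, 6.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pals < 0 or self.n_controls < 0:
            raise ValueError("participant counts must be >= 0")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction must lie in [0, 1]")
        slope_sds = (
            self.slope_sd.values() if isinstance(self.slope_sd, dict) else [self.slope_sd]
        )
        if self.rater_sd < 0 or any(s < 0 for s in slope_sds):
            raise ValueError("SDs must be >= 0")
        if not 0.0 <= self.frac_bulbar_onset <= 1.0:
            raise ValueError("frac_bulbar_onset must lie in [0, 1]")


@dataclass
class CohortData:
    """Generated cohort tables plus ground truth and transcripts."""

    participants: pd.DataFrame
    sessions: pd.DataFrame
    recordings: pd.DataFrame
    ratings: pd.DataFrame
    transcripts: dict[str, Transcript]
    spec: CohortSpec


DAYS_PER_MONTH = 30.4375


def _group_param(d: dict, gkey: str):
    """Look up a per-group parameter, letting a plain 'pals' key cover both onset types."""
    if gkey in d:
        return d[gkey]
    if gkey.startswith("pals_") and "pals" in d:
        return d["pals"]
    raise KeyError(f"no parameter for group {gkey!r}")


def voice_spec_for_le(le: float, f0_hz: float = 120.0) -> VoiceSpec:
    """Map a true LE score to plausible voice-degradation parameters.

    Higher listener effort comes with more perturbed phonation: jitter and
    shimmer grow and the harmonics-to-noise ratio falls roughly linearly
    with LE. Used when synthesizing audio for cohort recordings.
    """
    le = float(np.clip(le, 0.0, 100.0))
    return VoiceSpec(
        f0_hz=f0_hz,
        jitter_pct=0.5 + 3.5 * le / 100.0,
        shimmer_pct=2.0 + 8.0 * le / 100.0,
        snr_db=30.0 - 25.0 * le / 100.0,
        duration_s=2.0,
    )


def gen_cohort(spec: CohortSpec | None = None, with_transcripts: bool = True) -> CohortData:
    """Generate a full rated cohort with known ground truth.

    Per participant: group (PALS bulbar/non-bulbar onset, or control), onset
    and enrolment dates, a linear true-LE trajectory clipped to [0, 100].
    Per session: three sentence recordings. Per recording: one score per
    rater = clip(true LE + rater bias + noise, 0, 100); a `repeat_fraction`
    of recordings is re-presented to every rater with fresh noise and
    flagged `is_repeat`. QA contamination injects keyword notes and
    corrupted transcripts at the configured rates. Deterministic given
    `spec.seed`.
    """
    spec = spec or CohortSpec()
    spec.validate()
    master = np.random.SeedSequence(spec.seed)
    n_total = spec.n_pals + spec.n_controls
    streams = master.spawn(n_total + 1)
    tail_rng = np.random.default_rng(streams[-1])

    sentences = [s for pool in SENTENCE_POOL.values() for s in pool]
    n_bulbar = int(round(spec.frac_bulbar_onset * spec.n_pals))

    p_rows, s_rows, r_rows, rating_rows = [], [], [], []
    transcripts: dict[str, Transcript] = {}
    enrol = pd.Timestamp("2021-01-04")

    for i in range(n_total):
        rng = np.random.default_rng(streams[i])
        pid = f"P{i:03d}"
        if i < spec.n_pals:
            group = "pals"
            onset_type = "bulbar" if i < n_bulbar else "non-bulbar"
            gkey = "pals_bulbar" if onset_type == "bulbar" else "pals_nonbulbar"
            onset_years = rng.uniform(*spec.onset_years_range)
            onset_date = enrol - pd.Timedelta(days=onset_years * 365.25)
        else:
            group = "control"
            onset_type = "none"
            gkey = "control"
            onset_date = pd.NaT
        mu, sd = _group_param(spec.baseline_le_dist, gkey)
        baseline = float(np.clip(rng.normal(mu, sd), 0.0, 100.0))
        slope_sd = (
            _group_param(spec.slope_sd, gkey)
            if isinstance(spec.slope_sd, dict)
            else spec.slope_sd
        )
        slope = rng.normal(_group_param(spec.slope_by_group, gkey), slope_sd)
        n_sessions = int(rng.integers(spec.n_sessions_range[0], spec.n_sessions_range[1] + 1))
        p_rows.append(
            dict(
                participant_id=pid,
                group=group,
                onset_type=onset_type,
                onset_date=onset_date,
                enrolment_date=enrol,
                true_baseline_le=baseline,
                true_slope=slope,
            )
        )
        for k in range(n_sessions):
            days = k * spec.session_interval_days
            m_enrol = days / DAYS_PER_MONTH
            m_onset = (
                ((enrol + pd.Timedelta(days=days)) - onset_date).days / DAYS_PER_MONTH
                if onset_date is not pd.NaT
                else math.nan
            )
            true_le = float(np.clip(baseline + slope * m_enrol, 0.0, 100.0))
            sid = f"{pid}-S{k:02d}"
            s_rows.append(
                dict(
                    session_id=sid,
                    participant_id=pid,
                    session_date=enrol + pd.Timedelta(days=days),
                    months_since_enrolment=m_enrol,
                    months_since_onset=m_onset,
                    true_le=true_le,
                )
            )
            for j in range(3):
                rid = f"{sid}-R{j}"
                sentence = sentences[int(rng.integers(len(sentences)))]
                wpm = float(np.clip(190.0 - 1.2 * true_le + rng.normal(0, 8), 40.0, 260.0))
                r_rows.append(
                    dict(
                        recording_id=rid,
                        session_id=sid,
                        participant_id=pid,
                        sentence_text=sentence,
                        true_le=true_le,
                        true_wpm=wpm,
                        corrupted_transcript=False,
                    )
                )
                if with_transcripts:
                    transcripts[rid] = gen_transcript(
                        sentence,
                        speaking_rate_wpm=wpm,
                        corruption_frac=0.0,
                        seed=rng.integers(2**31),
                        recording_id=rid,
                    )
                for r_idx, bias in enumerate(spec.rater_bias):
                    score = float(np.clip(true_le + bias + rng.normal(0, spec.rater_sd), 0, 100))
                    rating_rows.append(
                        dict(
                            rater_id=f"SLP{r_idx + 1}",
                            recording_id=rid,
                            le_score=score,
                            is_repeat=False,
                            note="",
                        )
                    )

    recordings = pd.DataFrame(r_rows)
    ratings = pd.DataFrame(rating_rows)

    # re-present a fraction of recordings to every rater with fresh noise
    n_rec = len(recordings)
    n_repeat = int(round(spec.repeat_fraction * n_rec))
    repeat_ids = tail_rng.choice(recordings["recording_id"], size=n_repeat, replace=False)
    rep_rows = []
    true_le_map = recordings.set_index("recording_id")["true_le"]
    for rid in repeat_ids:
        for r_idx, bias in enumerate(spec.rater_bias):
            score = float(
                np.clip(true_le_map[rid] + bias + tail_rng.normal(0, spec.rater_sd), 0, 100)
            )
            rep_rows.append(
                dict(
                    rater_id=f"SLP{r_idx + 1}",
                    recording_id=rid,
                    le_score=score,
                    is_repeat=True,
                    note="",
                )
            )
    if rep_rows:
        ratings = pd.concat([ratings, pd.DataFrame(rep_rows)], ignore_index=True)

    # QA contamination: keyword notes on some recordings
    if spec.note_contamination_frac > 0:
        n_notes = int(round(spec.note_contamination_frac * n_rec))
        note_ids = tail_rng.choice(recordings["recording_id"], size=n_notes, replace=False)
        for rid in note_ids:
            kw = QA_KEYWORDS[int(tail_rng.integers(len(QA_KEYWORDS)))]
            mask = (ratings["recording_id"] == rid) & (ratings["rater_id"] == "SLP1")
            idx = ratings.index[mask][0]
            ratings.loc[idx, "note"] = f"poor {kw} today"

    # QA contamination: hallucinated transcripts
    if spec.transcript_corruption_frac > 0 and with_transcripts:
        n_bad = int(round(spec.transcript_corruption_frac * n_rec))
        bad_ids = tail_rng.choice(recordings["recording_id"], size=n_bad, replace=False)
        for rid in bad_ids:
            row = recordings.loc[recordings["recording_id"] == rid].iloc[0]
            transcripts[rid] = gen_transcript(
                row["sentence_text"],
                speaking_rate_wpm=row["true_wpm"],
                corruption_frac=1.0,
                seed=int(tail_rng.integers(2**31)),
                recording_id=rid,
            )
            recordings.loc[recordings["recording_id"] == rid, "corrupted_transcript"] = True

    ratings["presented_order"] = np.arange(len(ratings))
    return CohortData(
        participants=pd.DataFrame(p_rows),
        sessions=pd.DataFrame(s_rows),
        recordings=recordings,
        ratings=ratings,
        transcripts=transcripts,
        spec=spec,
    )
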