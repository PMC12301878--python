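"""End-to-end glue: cohort tables -> QA -> session scores -> model inputs.

These helpers connect the module surfaces: they reshape the generator's (or
an imported study export's) tables into QA records, aggregate surviving
ratings into session LE scores, and assemble the long-format series the
longitudinal models and the prediction model consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acoustics import extract_features
from .qa import RecordingRecord
from .scoring import session_le
from .synth import CohortData, gen_voice, voice_spec_for_le

__all__ = [
    "records_from_cohort",
    "score_sessions",
    "longitudinal_series",
    "feature_table",
]


def records_from_cohort(cohort: CohortData) -> list[RecordingRecord]:
    """One QA record per recording: session linkage, rater notes, transcript."""
    notes = (
        cohort.ratings.groupby("recording_id")["note"]
        .apply(lambda s: [n for n in s if n])
        .to_dict()
    )
    firsts = cohort.ratings[~cohort.ratings["is_repeat"].astype(bool)]
    scores = firsts.groupby("recording_id")["le_score"].apply(list).to_dict()
    return [
        RecordingRecord(
            recording_id=row.recording_id,
            session_id=row.session_id,
            participant_id=row.participant_id,
            notes=notes.get(row.recording_id, []),
            transcript=cohort.transcripts.get(row.recording_id),
            le_scores=scores.get(row.recording_id, []),
        )
        for row in cohort.recordings.itertuples()
    ]


def score_sessions(
    cohort: CohortData, kept_records: list[RecordingRecord] | None = None
) -> pd.DataFrame:
    """Session LE table (mean of first-presentation ratings of kept recordings).

    When ``kept_records`` is None all recordings count (no QA applied).
    """
    if kept_records is None:
        kept_ids = set(cohort.recordings["recording_id"])
    else:
        kept_ids = {r.recording_id for r in kept_records}
    ratings = cohort.ratings[cohort.ratings["recording_id"].isin(kept_ids)]
    rec2sess = cohort.recordings.set_index("recording_id")["session_id"]
    ratings = ratings.assign(session_id=ratings["recording_id"].map(rec2sess))
    sess_meta = cohort.sessions.set_index("session_id")

    rows = []
    for sid, grp in ratings.groupby("session_id"):
        meta = sess_meta.loc[sid]
        score = session_le(grp, session_id=sid, participant_id=meta["participant_id"])
        rows.append(
            dict(
                session_id=sid,
                participant_id=meta["participant_id"],
                le_mean=score.le_mean,
                n_ratings=score.n_ratings,
                months_since_enrolment=meta["months_since_enrolment"],
                months_since_onset=meta["months_since_onset"],
            )
        )
    return pd.DataFrame(rows)


def longitudinal_series(
    scores: pd.DataFrame,
    participants: pd.DataFrame,
    time_origin: str = "onset",
) -> pd.DataFrame:
    """Long-format series for `ProgressionModel`.

    ``time_origin`` "onset" uses months since symptom onset for PALS and
    months since enrolment for controls (who have no onset date);
    "enrolment" uses enrolment time for everyone.
    """
    meta = participants.set_index("participant_id")
    df = scores.copy()
    df["group"] = df["participant_id"].map(meta["group"])
    df["onset_type"] = df["participant_id"].map(meta["onset_type"])
    if time_origin == "enrolment":
        df["time_months"] = df["months_since_enrolment"]
    elif time_origin == "onset":
        df["time_months"] = np.where(
            df["group"].eq("control") | df["months_since_onset"].isna(),
            df["months_since_enrolment"],
            df["months_since_onset"],
        )
    else:
        raise ValueError("time_origin must be 'onset' or 'enrolment'")
    return df.rename(columns={"le_mean": "value"})[
        ["participant_id", "group", "onset_type", "time_months", "value", "session_id"]
    ]


def feature_table(
    cohort: CohortData,
    kept_records: list[RecordingRecord] | None = None,
    with_audio: bool = False,
    seed: int = 0,
    level: str = "session",
) -> pd.DataFrame:
    """Feature rows plus target LE for the prediction model.

    Features are extracted per recording; at the default ``level="session"``
    they are averaged over the session's surviving recordings — the
    prediction target is the session LE (mean of its first-presentation
    ratings), mirroring how sessions are scored. ``level="recording"``
    returns the raw per-recording rows.

    With ``with_audio`` the acoustic features come from voices synthesized
    at each recording's degradation level (slow: seconds per recording);
    without it only speaking rate and ASR confidence are populated and the
    acoustic columns stay NaN for the training-time imputation to handle.
    """
    if level not in ("session", "recording"):
        raise ValueError("level must be 'session' or 'recording'")
    recs = kept_records if kept_records is not None else records_from_cohort(cohort)
    rec_meta = cohort.recordings.set_index("recording_id")
    rows = []
    for i, r in enumerate(recs):
        meta = rec_meta.loc[r.recording_id]
        wf = None
        if with_audio:
            spec = voice_spec_for_le(meta["true_le"])
            wf = gen_voice(spec, seed=np.random.SeedSequence([seed, i])).waveform
        fv = extract_features(wf, r.transcript)
        row = fv.as_dict()
        row.update(
            recording_id=r.recording_id,
            session_id=r.session_id,
            participant_id=r.participant_id,
            target_le=float(np.mean(r.le_scores)) if r.le_scores else np.nan,
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    if level == "recording" or df.empty:
        return df
    feature_cols = [c for c in df.columns if c not in
                    ("recording_id", "session_id", "participant_id")]
    agg = df.groupby("session_id", as_index=False).agg(
        {**{c: "mean" for c in feature_cols}, "participant_id": "first"}
    )
    return agg
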