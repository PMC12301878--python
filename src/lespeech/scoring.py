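"""Session-level listener-effort scores and rater reliability.

A complete session is three sentences rated by three SLPs — nine ratings —
and the session LE is their plain mean. Recordings re-presented to measure
intra-rater reliability contribute only their first rating to scores and to
inter-rater reliability ("first" repeat policy).

Reliability uses the intraclass correlation coefficient computed from the
two-way mean-squares decomposition, absolute-agreement, single-measurement
form (ICC(2,1)): raters are treated as a random sample of possible raters
and systematic rater offsets count against agreement. Intra-rater ICC uses
the (first, repeat) pair per recording within one rater; inter-rater ICC
uses first ratings across raters. Bands: < 0.5 poor, 0.5-0.75 moderate,
0.75-0.9 good, > 0.9 excellent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SessionScore",
    "session_le",
    "icc",
    "interpret_icc",
    "reliability_report",
]


@dataclass
class SessionScore:
    session_id: str
    participant_id: str
    le_mean: float
    n_ratings: int


def session_le(
    ratings: pd.DataFrame,
    session_id: str = "",
    participant_id: str = "",
    repeat_policy: str = "first",
) -> SessionScore:
    """Mean LE over a session's first-presentation ratings.

    ``ratings`` holds one session's rows with columns ``le_score`` and
    ``is_repeat``. Only the "first" repeat policy is implemented: repeats
    are measurement-reliability probes, not additional observations.
    """
    if repeat_policy != "first":
        raise ValueError(f"unknown repeat policy: {repeat_policy!r}")
    firsts = ratings.loc[~ratings["is_repeat"].astype(bool), "le_score"]
    if firsts.empty:
        raise ValueError("no usable (first-presentation) ratings in session")
    return SessionScore(
        session_id=session_id,
        participant_id=participant_id,
        le_mean=float(firsts.mean()),
        n_ratings=int(firsts.size),
    )


def icc(matrix: np.ndarray, form: str = "agreement") -> float:
    """Two-way single-measurement ICC from the mean-squares decomposition.

    ``matrix`` is targets x raters with no missing cells. With rows MSR,
    columns MSC and error MSE from the two-way ANOVA, the default
    "agreement" form (ICC(2,1), random raters, systematic offsets count
    against agreement) is

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    and "consistency" (ICC(3,1)) drops the rater-variance term. A matrix
    with zero total variance is perfect agreement (1.0).
    """
    if form not in ("agreement", "consistency"):
        raise ValueError(f"unknown ICC form: {form!r}")
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if np.isnan(y).any():
        raise ValueError("missing cells: pair ratings before computing ICC")
    n, k = y.shape
    if np.ptp(y) == 0:
        return 1.0
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate ICC: zero denominator with unequal values")
    # roundoff can push a near-perfect matrix a hair past 1
    return float(min((msr - mse) / denom, 1.0))


def interpret_icc(value: float) -> str:
    """Reliability band for an ICC value."""
    if value > 1:
        raise ValueError("ICC cannot exceed 1")
    if value > 0.90:
        return "excellent"
    if value >= 0.75:
        return "good"
    if value >= 0.5:
        return "moderate"
    return "poor"


def _first_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    return ratings.loc[~ratings["is_repeat"].astype(bool)]


def reliability_report(ratings: pd.DataFrame) -> dict:
    """Intra-rater, pairwise inter-rater and overall inter-rater ICCs.

    ``ratings`` has columns rater_id, recording_id, le_score, is_repeat.
    Intra-rater ICC pairs each rater's first and repeat rating of the
    re-presented recordings; when no repeats exist that section is marked
    unavailable. Inter-rater ICCs use first ratings on recordings scored by
    every rater.
    """
    out: dict = {"intra": {}, "inter_pairwise": {}, "inter_overall": None}
    raters = sorted(ratings["rater_id"].unique())

    for rater in raters:
        sub = ratings.loc[ratings["rater_id"] == rater]
        firsts = sub.loc[~sub["is_repeat"].astype(bool)].set_index("recording_id")[
            "le_score"
        ]
        repeats = sub.loc[sub["is_repeat"].astype(bool)].set_index("recording_id")[
            "le_score"
        ]
        repeats = repeats[~repeats.index.duplicated()]
        common = firsts.index.intersection(repeats.index)
        if len(common) < 2:
            out["intra"][rater] = {"available": False}
            continue
        mat = np.column_stack([firsts.loc[common].values, repeats.loc[common].values])
        val = icc(mat)
        out["intra"][rater] = {
            "available": True,
            "icc": val,
            "interpretation": interpret_icc(val),
            "n": int(len(common)),
        }

    wide = (
        _first_ratings(ratings)
        .pivot_table(index="recording_id", columns="rater_id", values="le_score")
        .dropna()
    )
    for a, b in itertools.combinations(raters, 2):
        if a in wide.columns and b in wide.columns and len(wide) >= 2:
            val = icc(wide[[a, b]].values)
            out["inter_pairwise"][f"{a}|{b}"] = {
                "icc": val,
                "interpretation": interpret_icc(val),
                "n": int(len(wide)),
            }
    if len(raters) >= 3 and len(wide) >= 2 and all(r in wide.columns for r in raters):
        val = icc(wide[raters].values)
        out["inter_overall"] = {
            "icc": val,
            "interpretation": interpret_icc(val),
            "n": int(len(wide)),
        }
    return out
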