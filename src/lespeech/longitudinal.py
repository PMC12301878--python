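"""Longitudinal progression analysis of listener effort and related measures.

The central object is `ProgressionModel`, a linear mixed model of a measure
on time (months) with participant as a random effect — random intercept plus
an independent random slope, estimated by REML. `fit()` returns a
`ProgressionResults` carrying the fixed slope, its standard error, the Wald
p-value, the group-difference (time x group interaction) when two groups are
compared, and a `summary()` table. If the random-slope model fails to
converge the model falls back to a random-intercept-only fit and flags it.

Around the model: cohort filters on baseline LE and time since onset,
the slope coefficient of variation (CoV = SE/|slope|; closer to 0 means
less residual variability per unit change), progression dichotomization
against the control range, 2x2 progression contingency tables, and the
normal-approximation trial sample size for a given slowing of the slope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm

__all__ = [
    "ProgressionModel",
    "ProgressionResults",
    "ProgressionFlag",
    "DAYS_PER_MONTH",
    "filter_cohort",
    "fit_slopes",
    "cov_of_slope",
    "participant_ols_slopes",
    "progression_flags",
    "contingency",
    "sample_size",
]

DAYS_PER_MONTH = 30.4375


@dataclass
class ProgressionResults:
    """Fixed-effect slope estimates from a mixed-model fit."""

    measure: str
    slope: float
    se: float
    p_value: float
    n_participants: int
    n_observations: int
    random_slope: bool
    group_term: str | None = None
    group_slope_diff: float | None = None
    group_diff_se: float | None = None
    group_diff_p: float | None = None
    slopes_by_group: dict = field(default_factory=dict)
    _sm_results: object | None = None

    @property
    def conf_int(self) -> tuple[float, float]:
        """95% Wald confidence interval for the slope."""
        z = norm.ppf(0.975)
        return self.slope - z * self.se, self.slope + z * self.se

    @property
    def cov(self) -> float:
        return cov_of_slope(self)

    def summary(self) -> str:
        lines = [
            f"Mixed-model progression fit: {self.measure}",
            f"  participants: {self.n_participants}   observations: {self.n_observations}",
            f"  random effects: intercept{' + slope' if self.random_slope else ' only (fallback)'}",
            f"  slope: {self.slope:+.4f} /month   SE {self.se:.4f}   "
            f"95% CI [{self.conf_int[0]:+.4f}, {self.conf_int[1]:+.4f}]   P {self.p_value:.3g}",
        ]
        if not math.isnan(self.cov):
            lines.append(f"  CoV (SE/|slope|): {self.cov:.3f}")
        if self.group_term is not None:
            lines.append(
                f"  group contrast ({self.group_term}): slope difference "
                f"{self.group_slope_diff:+.4f} SE {self.group_diff_se:.4f} "
                f"P {self.group_diff_p:.3g}"
            )
            for g, s in self.slopes_by_group.items():
                lines.append(f"    slope[{g}]: {s:+.4f} /month")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        d = {
            "measure": self.measure,
            "slope": self.slope,
            "se": self.se,
            "p_value": self.p_value,
            "conf_int": list(self.conf_int),
            "n_participants": self.n_participants,
            "n_observations": self.n_observations,
            "random_slope": self.random_slope,
        }
        if self.group_term is not None:
            d.update(
                group_term=self.group_term,
                group_slope_diff=self.group_slope_diff,
                group_diff_se=self.group_diff_se,
                group_diff_p=self.group_diff_p,
                slopes_by_group=self.slopes_by_group,
            )
        return d


class ProgressionModel:
    """Linear mixed model of a longitudinal measure on time.

    Parameters
    ----------
    data : DataFrame
        Long format, one row per session.
    value_col, time_col, participant_col : str
        Column names; time is in months from the chosen origin.
    group_col : str, optional
        Two-level factor; adds fixed effects for group and time x group,
        so the interaction tests whether slopes differ between groups.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        value_col: str = "value",
        time_col: str = "time_months",
        participant_col: str = "participant_id",
        group_col: str | None = None,
        measure: str | None = None,
    ) -> None:
        cols = [participant_col, time_col, value_col] + ([group_col] if group_col else [])
        d = data[cols].dropna().copy()
        d = d.rename(
            columns={value_col: "value", time_col: "time", participant_col: "pid"}
        )
        if group_col:
            d = d.rename(columns={group_col: "grp"})
            levels = sorted(d["grp"].unique())
            if len(levels) != 2:
                raise ValueError(f"group column must have 2 levels, got {levels}")
            self.group_levels = levels
        else:
            self.group_levels = None
        n_per = d.groupby("pid").size()
        if (n_per >= 2).sum() < 2:
            raise ValueError("need >= 2 participants with >= 2 observations")
        self.data = d
        self.group_col = group_col
        self.measure = measure or value_col

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "ProgressionModel":
        return cls(data, **kwargs)

    def _fit_once(self, random_slope: bool):
        formula = "value ~ time * grp" if self.group_col else "value ~ time"
        kwargs = dict(groups=self.data["pid"], re_formula="1")
        if random_slope:
            kwargs["vc_formula"] = {"slope": "0 + time"}
        model = smf.mixedlm(formula, self.data, **kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=True, method=["lbfgs", "powell"])

    def fit(self) -> ProgressionResults:
        random_slope = True
        try:
            res = self._fit_once(random_slope=True)
            ok = bool(res.converged) and np.isfinite(res.bse.get("time", np.nan))
        except (np.linalg.LinAlgError, ValueError):
            ok = False
        if not ok:
            random_slope = False
            res = self._fit_once(random_slope=False)

        out = ProgressionResults(
            measure=self.measure,
            slope=float(res.params["time"]),
            se=float(res.bse["time"]),
            p_value=float(res.pvalues["time"]),
            n_participants=int(self.data["pid"].nunique()),
            n_observations=int(len(self.data)),
            random_slope=random_slope,
            _sm_results=res,
        )
        if self.group_col:
            ref, other = self.group_levels
            inter = f"time:grp[T.{other}]"
            out.group_term = f"{other} vs {ref}"
            out.group_slope_diff = float(res.params[inter])
            out.group_diff_se = float(res.bse[inter])
            out.group_diff_p = float(res.pvalues[inter])
            out.slopes_by_group = {
                ref: float(res.params["time"]),
                other: float(res.params["time"] + res.params[inter]),
            }
        return out


def fit_slopes(
    data: pd.DataFrame,
    value_col: str = "value",
    time_col: str = "time_months",
    participant_col: str = "participant_id",
    group_col: str | None = None,
    measure: str | None = None,
) -> ProgressionResults:
    """Functional wrapper: build a `ProgressionModel` and fit it."""
    return ProgressionModel(
        data,
        value_col=value_col,
        time_col=time_col,
        participant_col=participant_col,
        group_col=group_col,
        measure=measure,
    ).fit()


def cov_of_slope(fit: ProgressionResults) -> float:
    """Slope coefficient of variation: SE / |slope|; NaN for a zero slope."""
    if fit.slope == 0:
        return math.nan
    return fit.se / abs(fit.slope)


def filter_cohort(
    participants: pd.DataFrame,
    onset_within_years: float | None = None,
    baseline_le_range: tuple[float, float] | None = None,
    baseline_le_above: float | None = None,
    baseline_col: str = "baseline_le",
    onset_years_col: str = "onset_years_before_entry",
) -> pd.DataFrame:
    """Subset participants by baseline LE and time since onset.

    ``baseline_le_range`` is inclusive at both ends (the normal range is
    0-10 *including* 10); ``baseline_le_above`` is strict (bulbar
    involvement is LE > 10, excluding 10); ``onset_within_years`` is strict
    (onset < y years before study entry).
    """
    mask = pd.Series(True, index=participants.index)
    if onset_within_years is not None:
        mask &= participants[onset_years_col] < onset_within_years
    if baseline_le_range is not None:
        lo, hi = baseline_le_range
        mask &= participants[baseline_col].between(lo, hi, inclusive="both")
    if baseline_le_above is not None:
        mask &= participants[baseline_col] > baseline_le_above
    return participants.loc[mask]


def participant_ols_slopes(
    data: pd.DataFrame,
    value_col: str = "value",
    time_col: str = "time_months",
    participant_col: str = "participant_id",
) -> pd.DataFrame:
    """Per-participant ordinary least-squares slopes (input surface for
    trajectory-clustering methods); NaN slope with fewer than 2 sessions."""
    rows = []
    for pid, g in data.groupby(participant_col):
        g = g.dropna(subset=[value_col, time_col])
        if len(g) >= 2 and g[time_col].nunique() >= 2:
            slope = float(np.polyfit(g[time_col], g[value_col], 1)[0])
        else:
            slope = math.nan
        rows.append({participant_col: pid, "ols_slope": slope, "n_sessions": len(g)})
    return pd.DataFrame(rows)


@dataclass
class ProgressionFlag:
    participant_id: str
    measure: str
    change: float
    threshold: float
    flag: str  # "Progression" | "NoProgression"


def _endpoint_changes(
    data: pd.DataFrame, value_col: str, time_col: str, participant_col: str, decline_sign: float
) -> pd.Series:
    changes = {}
    for pid, g in data.dropna(subset=[value_col]).groupby(participant_col):
        g = g.sort_values(time_col)
        if len(g) < 2:
            continue
        changes[pid] = decline_sign * (g[value_col].iloc[-1] - g[value_col].iloc[0])
    return pd.Series(changes, dtype=float)


def progression_flags(
    pals_data: pd.DataFrame,
    control_data: pd.DataFrame,
    measure: str = "LE",
    decline_sign: float = 1.0,
    value_col: str = "value",
    time_col: str = "time_months",
    participant_col: str = "participant_id",
) -> list[ProgressionFlag]:
    """Dichotomize each PALS as Progression / NoProgression.

    Change is last-minus-first observation, multiplied by ``decline_sign``
    so that positive always means decline (+1 for LE where an increase is
    worse, -1 for speaking rate or ALSFRS where a decrease is worse). The
    threshold is the maximum sign-adjusted change in the control set;
    Progression requires strictly *more* decline than that maximum.
    """
    ctrl = _endpoint_changes(control_data, value_col, time_col, participant_col, decline_sign)
    if ctrl.empty:
        raise ValueError("control set has no participant with >= 2 observations")
    threshold = float(ctrl.max())
    pals = _endpoint_changes(pals_data, value_col, time_col, participant_col, decline_sign)
    return [
        ProgressionFlag(
            participant_id=str(pid),
            measure=measure,
            change=float(chg),
            threshold=threshold,
            flag="Progression" if chg > threshold else "NoProgression",
        )
        for pid, chg in pals.items()
    ]


def contingency(
    flags_a: list[ProgressionFlag], flags_b: list[ProgressionFlag]
) -> pd.DataFrame:
    """2x2 table of Progression flags on the same participants.

    Rows = measure A, columns = measure B, ordered NoProgression then
    Progression; cell counts sum to the shared participant count.
    """
    a = {f.participant_id: f.flag for f in flags_a}
    b = {f.participant_id: f.flag for f in flags_b}
    if set(a) != set(b):
        raise ValueError("flag sets cover different participants")
    levels = ["NoProgression", "Progression"]
    table = pd.DataFrame(0, index=levels, columns=levels)
    for pid in a:
        table.loc[a[pid], b[pid]] += 1
    return table


def sample_size(
    slope: float,
    sd: float,
    effect_fraction: float = 0.30,
    power: float = 0.90,
    alpha: float = 0.05,
    rounding: str = "ceil",
) -> int:
    """Participants per group to detect a fractional slowing of the slope.

    Normal-approximation two-sample formula: with Delta = effect_fraction x
    |slope| and between-participant SD ``sd``,

        n = (z_{1-alpha/2} + z_{power})^2 * sd^2 / Delta^2

    rounded up to a whole participant (``rounding`` may also be "nearest"),
    with a floor of one participant per group.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    if not 0 < effect_fraction < 1:
        raise ValueError("effect_fraction must lie in (0, 1)")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must lie in (0, 1)")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    z = norm.ppf(1 - alpha / 2) + norm.ppf(power)
    delta = effect_fraction * abs(slope)
    n = (z * sd / delta) ** 2
    if rounding == "ceil":
        n_int = math.ceil(n)
    elif rounding == "nearest":
        n_int = round(n)
    else:
        raise ValueError(f"unknown rounding convention: {rounding!r}")
    return max(1, int(n_int))
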