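"""Mixed-model slopes, cohort filters, progression dichotomization, trial sizing."""

import math

import numpy as np
import pandas as pd
import pytest

from lespeech.longitudinal import (
    ProgressionModel,
    contingency,
    cov_of_slope,
    filter_cohort,
    fit_slopes,
    participant_ols_slopes,
    progression_flags,
    sample_size,
)


def make_series(slopes, intercepts=None, noise_sd=0.0, n_obs=5, seed=0, group=None):
    rng = np.random.default_rng(seed)
    rows = []
    for i, s in enumerate(slopes):
        b0 = (intercepts or {}).get(i, 20.0)
        for k in range(n_obs):
            t = 2.0 * k
            rows.append(
                dict(
                    participant_id=f"P{i}",
                    time_months=t,
                    value=b0 + s * t + rng.normal(0, noise_sd),
                    group=(group or {}).get(i, "a"),
                )
            )
    return pd.DataFrame(rows)


class TestProgressionModel:
    def test_noiseless_common_slope(self):
        df = make_series([-0.2] * 6)
        fit = fit_slopes(df)
        assert fit.slope == pytest.approx(-0.2, abs=1e-6)
        assert fit.se == pytest.approx(0.0, abs=1e-4)

    def test_group_interaction_detected(self):
        slopes = [2.0] * 10 + [0.0] * 10
        groups = {i: ("fast" if i < 10 else "slow") for i in range(20)}
        df = make_series(slopes, noise_sd=1.0, group=groups, seed=1)
        fit = fit_slopes(df, group_col="group")
        assert fit.group_diff_p < 0.05
        assert fit.slopes_by_group["fast"] == pytest.approx(2.0, abs=0.5)
        assert fit.slopes_by_group["slow"] == pytest.approx(0.0, abs=0.5)

    def test_summary_mentions_key_quantities(self):
        fit = fit_slopes(make_series([0.5] * 5, noise_sd=0.5, seed=2))
        text = fit.summary()
        assert "slope" in text and "SE" in text and "CI" in text

    def test_too_few_participants_rejected(self):
        df = make_series([0.1])
        with pytest.raises(ValueError):
            ProgressionModel(df)


class TestCoV:
    def test_printed_formula(self):
        fit = fit_slopes(make_series([0.5] * 5, noise_sd=0.5, seed=3))
        fit.slope, fit.se = 2.0, 0.4
        assert cov_of_slope(fit) == pytest.approx(0.2)

    def test_absolute_value_convention(self):
        fit = fit_slopes(make_series([0.5] * 5, noise_sd=0.5, seed=3))
        fit.slope, fit.se = -2.0, 0.4
        assert cov_of_slope(fit) == pytest.approx(0.2)

    def test_zero_se(self):
        fit = fit_slopes(make_series([0.5] * 5, noise_sd=0.5, seed=3))
        fit.slope, fit.se = 1.0, 0.0
        assert cov_of_slope(fit) == 0.0

    def test_zero_slope_undefined(self):
        fit = fit_slopes(make_series([0.5] * 5, noise_sd=0.5, seed=3))
        fit.slope = 0.0
        assert math.isnan(cov_of_slope(fit))


class TestFilterCohort:
    def participants(self):
        return pd.DataFrame(
            dict(
                participant_id=["A", "B", "C", "D"],
                baseline_le=[10.0, 10.5, 3.0, 45.0],
                onset_years_before_entry=[1.0, 3.5, 2.9, 0.5],
            )
        )

    def test_normal_range_includes_boundary(self):
        kept = filter_cohort(self.participants(), baseline_le_range=(0, 10))
        assert set(kept["participant_id"]) == {"A", "C"}

    def test_bulbar_involvement_strict(self):
        kept = filter_cohort(self.participants(), baseline_le_above=10.0)
        assert set(kept["participant_id"]) == {"B", "D"}

    def test_onset_window_strict(self):
        kept = filter_cohort(self.participants(), onset_within_years=3.0)
        assert set(kept["participant_id"]) == {"A", "C", "D"}


class TestProgressionFlags:
    def control_data(self):
        # control changes: max sign-adjusted LE increase = +2.0
        return make_series([0.0, 0.25], intercepts={0: 10, 1: 10}, n_obs=5)

    def pals(self, delta):
        return pd.DataFrame(
            dict(
                participant_id=["X"] * 2,
                time_months=[0.0, 10.0],
                value=[20.0, 20.0 + delta],
            )
        )

    @pytest.mark.parametrize(
        "delta, flag",
        [(5.0, "Progression"), (1.0, "NoProgression"), (2.0, "NoProgression")],
    )
    def test_threshold_strict(self, delta, flag):
        flags = progression_flags(self.pals(delta), self.control_data())
        assert flags[0].flag == flag
        assert flags[0].threshold == pytest.approx(2.0)

    def test_decline_sign_for_rate_like_measures(self):
        # speaking rate: decrease is decline
        ctrl = make_series([-0.1], intercepts={0: 180}, n_obs=5)  # max decline 0.8
        pals = pd.DataFrame(
            dict(participant_id=["X"] * 2, time_months=[0, 10], value=[150.0, 100.0])
        )
        flags = progression_flags(pals, ctrl, measure="SR", decline_sign=-1.0)
        assert flags[0].flag == "Progression"

    def test_intermediate_observations_irrelevant(self):
        base = self.pals(5.0)
        with_mid = pd.concat(
            [base, pd.DataFrame(dict(participant_id=["X"], time_months=[5.0], value=[90.0]))]
        ).sort_values("time_months")
        a = progression_flags(base, self.control_data())[0]
        b = progression_flags(with_mid, self.control_data())[0]
        assert (a.flag, a.change) == (b.flag, b.change)

    def test_single_observation_skipped(self):
        pals = pd.DataFrame(dict(participant_id=["X"], time_months=[0.0], value=[5.0]))
        assert progression_flags(pals, self.control_data()) == []


class TestContingency:
    def flags(self, mapping, measure="m"):
        from lespeech.longitudinal import ProgressionFlag

        return [
            ProgressionFlag(pid, measure, 0.0, 0.0, flag) for pid, flag in mapping.items()
        ]

    def test_identical_flags_diagonal(self):
        f = self.flags({"a": "Progression", "b": "NoProgression", "c": "Progression"})
        table = contingency(f, f)
        assert table.loc["Progression", "NoProgression"] == 0
        assert table.loc["NoProgression", "Progression"] == 0
        assert table.to_numpy().sum() == 3

    def test_complementary_flags_off_diagonal(self):
        fa = self.flags({"a": "Progression", "b": "NoProgression"})
        fb = self.flags({"a": "NoProgression", "b": "Progression"})
        table = contingency(fa, fb)
        assert table.loc["Progression", "Progression"] == 0
        assert table.loc["NoProgression", "NoProgression"] == 0

    def test_hand_counted_fixture(self):
        a_flags = dict(
            p0="Progression", p1="Progression", p2="Progression", p3="Progression",
            p4="NoProgression", p5="NoProgression", p6="Progression", p7="Progression",
            p8="NoProgression", p9="Progression",
        )
        b_flags = dict(
            p0="Progression", p1="NoProgression", p2="Progression", p3="NoProgression",
            p4="NoProgression", p5="Progression", p6="Progression", p7="Progression",
            p8="NoProgression", p9="NoProgression",
        )
        table = contingency(self.flags(a_flags), self.flags(b_flags))
        assert table.loc["Progression", "Progression"] == 4
        assert table.loc["Progression", "NoProgression"] == 3
        assert table.loc["NoProgression", "Progression"] == 1
        assert table.loc["NoProgression", "NoProgression"] == 2

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            contingency(self.flags({"a": "Progression"}), self.flags({"b": "Progression"}))


class TestSampleSize:
    def test_trial_inputs(self):
        n = sample_size(2.71, 3.42, 0.30, 0.90, 0.05)
        assert abs(n - 187) <= 1

    def test_zero_sd_floor(self):
        assert sample_size(2.0, 0.0, 0.30, 0.90, 0.05) == 1

    def test_quadratic_in_sd(self):
        n1 = sample_size(2.0, 10.0, 0.30, 0.90, 0.05)
        n2 = sample_size(2.0, 20.0, 0.30, 0.90, 0.05)
        assert n2 == pytest.approx(4 * n1, rel=0.01)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            sample_size(0.0, 3.42)
        with pytest.raises(ValueError):
            sample_size(2.0, 3.0, effect_fraction=1.5)
        with pytest.raises(ValueError):
            sample_size(2.0, 3.0, power=1.2)


def test_participant_ols_slopes():
    df = make_series([0.5, -1.0], intercepts={0: 10, 1: 50})
    out = participant_ols_slopes(df).set_index("participant_id")
    assert out.loc["P0", "ols_slope"] == pytest.approx(0.5)
    assert out.loc["P1", "ols_slope"] == pytest.approx(-1.0)
    single = pd.DataFrame(dict(participant_id=["Q"], time_months=[0.0], value=[1.0]))
    out2 = participant_ols_slopes(single)
    assert math.isnan(out2["ols_slope"].iloc[0])
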