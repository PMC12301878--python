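"""Lasso LE prediction with participant-grouped nested cross-validation."""

import numpy as np
import pandas as pd
import pytest

from lespeech.acoustics import FEATURE_NAMES
from lespeech.lepm import (
    ListenerEffortModel,
    evaluate,
    fit_l1,
    lambda_max,
    make_group_folds,
    nested_cv,
    penalty_grid,
)


def feature_frame(n_participants=125, sessions_each=3, seed=0, target_fn=None, noise_sd=0.0):
    """Synthetic feature table: 13 standardized-ish features per session."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for s in range(sessions_each):
            x = rng.standard_normal(len(FEATURE_NAMES))
            rows.append(
                dict(
                    zip(FEATURE_NAMES, x),
                    participant_id=f"P{p:03d}",
                    session_id=f"P{p:03d}-S{s}",
                )
            )
    df = pd.DataFrame(rows)
    if target_fn is None:
        target_fn = lambda X: 50 + 10 * X[:, 0]
    X = df[FEATURE_NAMES].to_numpy()
    df["target_le"] = target_fn(X) + rng.normal(0, noise_sd, len(df))
    return df


class TestGroupFolds:
    def test_125_participants_five_folds(self):
        df = feature_frame()
        folds = make_group_folds(
            df["participant_id"].to_numpy(), df["target_le"].to_numpy(), 5, rng=0
        )
        by_pid = pd.DataFrame(
            {"pid": df["participant_id"], "fold": folds}
        ).groupby("pid")["fold"]
        assert (by_pid.nunique() == 1).all()  # grouping contract
        pids_per_fold = (
            pd.DataFrame({"pid": df["participant_id"], "fold": folds})
            .groupby("fold")["pid"]
            .nunique()
        )
        assert (pids_per_fold == 25).all()

    def test_iid_targets_pass_quickly(self):
        df = feature_frame(n_participants=50, seed=1)
        folds = make_group_folds(
            df["participant_id"].to_numpy(),
            df["target_le"].to_numpy(),
            5,
            max_retries=50,
            rng=1,
        )
        assert len(np.unique(folds)) == 5

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            make_group_folds(np.array(["a", "b"]), np.zeros(2), 5)


class TestFitL1:
    def test_lambda_max_kills_all_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 8))
        X = (X - X.mean(0)) / X.std(0)
        y = 3 * X[:, 0] + rng.standard_normal(100)
        lam = lambda_max(X, y)
        coef, _ = fit_l1(X, y, lam * 1.0001)
        assert np.allclose(coef, 0.0)
        coef_below, _ = fit_l1(X, y, lam * 0.9)
        assert not np.allclose(coef_below, 0.0)

    def test_zero_penalty_is_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 3.0
        coef, b0 = fit_l1(X, y, 0.0)
        assert coef == pytest.approx([1.0, -2.0, 0.5, 0.0], abs=1e-8)
        assert b0 == pytest.approx(3.0, abs=1e-8)

    def test_orthonormal_soft_threshold(self):
        # columns orthonormal in the (1/n) X^T X = I sense
        rng = np.random.default_rng(2)
        n, p = 400, 5
        A = rng.standard_normal((n, p))
        A -= A.mean(axis=0)  # zero-mean columns stay zero-mean through QR
        Q, _ = np.linalg.qr(A)
        X = Q * np.sqrt(n)  # (1/n) X^T X = I
        beta = np.array([2.0, -1.0, 0.5, 0.05, 0.0])
        y = X @ beta
        pen = 0.3
        ols = X.T @ (y - y.mean()) / n
        expected = np.sign(ols) * np.maximum(np.abs(ols) - pen, 0.0)
        coef, _ = fit_l1(X, y, pen)
        assert coef == pytest.approx(expected, abs=1e-6)

    def test_sparsity_monotone_in_penalty(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((120, 10))
        y = X[:, 0] - 2 * X[:, 1] + 0.5 * rng.standard_normal(120)
        grid = penalty_grid(lambda_max((X - X.mean(0)) / X.std(0), y), 20)
        nnz = [np.count_nonzero(fit_l1(X, y, p)[0]) for p in grid]
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))  # grid descends

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fit_l1(np.array([[np.nan, 1.0]]), np.array([1.0]), 0.1)


class TestEvaluate:
    def test_perfect(self):
        rmse, r2 = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rmse == 0.0 and r2 == 1.0

    def test_mean_predictor_zero_r2(self):
        truth = np.array([1.0, 2.0, 3.0, 6.0])
        rmse, r2 = evaluate(np.full(4, truth.mean()), truth)
        assert r2 == pytest.approx(0.0)

    def test_hand_example(self):
        rmse, r2 = evaluate([0.0, 0.0], [0.0, 10.0])
        assert rmse == pytest.approx(np.sqrt(50.0))
        assert r2 == pytest.approx(-1.0)

    def test_zero_variance_truth(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [5.0, 5.0])


class TestNestedCV:
    def test_noiseless_linear_target_recovered(self):
        df = feature_frame(
            n_participants=60,
            sessions_each=3,
            seed=4,
            target_fn=lambda X: 40 + 8 * X[:, 0] - 5 * X[:, 4] + 3 * X[:, 9],
        )
        res = nested_cv(df, seed=0, grid_size=25)
        assert res.r2_mean >= 0.99
        assert res.rmse_mean <= 0.5

    def test_informative_features_carry_top_weights(self):
        def target(X):
            sr = X[:, FEATURE_NAMES.index("speaking_rate_wpm")]
            conf = X[:, FEATURE_NAMES.index("asr_confidence")]
            return 50 - 8 * sr - 6 * conf

        df = feature_frame(n_participants=60, seed=5, target_fn=target, noise_sd=1.0)
        res = nested_cv(df, seed=1, grid_size=25)
        top2 = set(res.relative_weights.index[:2])
        assert top2 == {"speaking_rate_wpm", "asr_confidence"}

    def test_pure_noise_near_null(self):
        rng = np.random.default_rng(6)
        df = feature_frame(n_participants=60, seed=6, target_fn=lambda X: np.zeros(len(X)))
        df["target_le"] = rng.normal(50, 10, len(df))
        res = nested_cv(df, seed=2, grid_size=25)
        assert res.r2_mean <= 0.05
        mean_nnz = np.mean([np.count_nonzero(c) for c in res.fold_coefs])
        assert mean_nnz <= 4  # sparse: most of the 13 coefficients shrunk to zero

    def test_participants_partition_outer_folds(self):
        df = feature_frame(n_participants=50, seed=7, noise_sd=2.0)
        res = ListenerEffortModel(df, grid_size=15).fit(seed=3)
        pred = res.predictions
        fold_of = pred.groupby("participant_id")["fold"].nunique()
        assert (fold_of == 1).all()
        assert set(pred["fold"].unique()) == set(range(5))
        # every session predicted exactly once
        assert pred["session_id"].is_unique and len(pred) == len(df)

    def test_training_statistics_only_leakage_guard(self):
        """Standardizing with full-data statistics would change held-out
        predictions; verify the pipeline's scaler is fit on training folds by
        checking that a test-fold outlier does not shift its own scaling."""
        from lespeech.lepm import _Scaler

        rng = np.random.default_rng(8)
        X_tr = rng.standard_normal((50, 3))
        sc = _Scaler.fit(X_tr)
        X_te = np.array([[100.0, 100.0, 100.0]])  # extreme held-out point
        before = sc.transform(X_te).copy()
        _ = _Scaler.fit(np.vstack([X_tr, X_te]))  # a leaky refit...
        after = sc.transform(X_te)
        np.testing.assert_array_equal(before, after)
        leaky = _Scaler.fit(np.vstack([X_tr, X_te])).transform(X_te)
        assert not np.allclose(leaky, before)
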