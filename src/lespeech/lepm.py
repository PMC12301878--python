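"""Listener-effort prediction model (LEPM).

An L1-penalized (Lasso) linear regression predicting the session LE score
(0-100) from the 13 recording features (11 acoustic + speaking rate + ASR
confidence), evaluated with participant-grouped nested cross-validation:
five outer folds for unbiased performance estimates, five inner folds
within each outer training set to pick the penalty. All sessions of a
participant stay in one fold at both levels — the model must generalize to
unseen speakers, not memorize voices. Uniformity of the target distribution
across folds is checked with a two-sample Kolmogorov-Smirnov test, and the
partition is reshuffled until every fold passes.

Features are z-scored and median-imputed using *training-fold statistics
only*; the target stays on its 0-100 scale so RMSE is in LE points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.linear_model import Lasso

from .acoustics import FEATURE_NAMES

__all__ = [
    "FoldConstructionError",
    "make_group_folds",
    "lambda_max",
    "fit_l1",
    "evaluate",
    "penalty_grid",
    "ListenerEffortModel",
    "LEPMResults",
    "nested_cv",
]


class FoldConstructionError(RuntimeError):
    """Raised when no fold assignment passes the target-uniformity check."""


def make_group_folds(
    groups: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    uniformity_alpha: float = 0.05,
    max_retries: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Participant-grouped fold assignment with a KS uniformity check.

    Participants are shuffled and split into ``n_folds`` near-equal blocks;
    every sample inherits its participant's fold. A candidate partition is
    accepted only if, for each fold, the two-sample KS test of its targets
    against the pooled targets of the other folds gives p >=
    ``uniformity_alpha``. Reshuffles up to ``max_retries`` times, then
    raises `FoldConstructionError` naming the failing fold.
    """
    rng = np.random.default_rng(rng)
    groups = np.asarray(groups)
    y = np.asarray(y, dtype=float)
    uniq = np.unique(groups)
    if len(uniq) < n_folds:
        raise ValueError(f"{len(uniq)} participants cannot fill {n_folds} folds")
    worst = (None, 1.0)
    for _ in range(max_retries):
        perm = rng.permutation(uniq)
        blocks = np.array_split(perm, n_folds)
        fold_of = {g: i for i, blk in enumerate(blocks) for g in blk}
        assignment = np.array([fold_of[g] for g in groups])
        ok = True
        for i in range(n_folds):
            in_fold = y[assignment == i]
            rest = y[assignment != i]
            p = ks_2samp(in_fold, rest).pvalue
            if p < uniformity_alpha:
                ok = False
                if p < worst[1]:
                    worst = (i, p)
                break
        if ok:
            return assignment
    raise FoldConstructionError(
        f"no uniform partition in {max_retries} tries "
        f"(last failing fold {worst[0]}, KS p={worst[1]:.3g})"
    )


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every Lasso coefficient is exactly zero.

    For the objective (1/2n)||y - Xb - b0||^2 + penalty * ||b||_1 with an
    unpenalized intercept: max_j |X_j^T (y - mean(y))| / n.
    """
    n = len(y)
    yc = y - y.mean()
    return float(np.max(np.abs(X.T @ yc)) / n)


def fit_l1(X: np.ndarray, y: np.ndarray, penalty: float) -> tuple[np.ndarray, float]:
    """Lasso fit minimizing (1/2n)*RSS + penalty*sum|beta|; returns (coef, intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or target")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    if penalty == 0:
        Xa = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
        return beta[1:], float(beta[0])
    model = Lasso(alpha=penalty, fit_intercept=True, max_iter=100000, tol=1e-8)
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(RMSE, R^2) with R^2 = 1 - SSE/SST about the test-set mean."""
    pred = np.asarray(predictions, dtype=float)
    t = np.asarray(truth, dtype=float)
    if len(pred) != len(t) or len(t) < 2:
        raise ValueError("need equal-length arrays with >= 2 values")
    sst = float(np.sum((t - t.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined: zero-variance truth")
    sse = float(np.sum((t - pred) ** 2))
    return math.sqrt(sse / len(t)), 1.0 - sse / sst


def penalty_grid(lam_max: float, n_values: int = 50, decades: float = 4.0) -> np.ndarray:
    """Log-spaced penalties from the all-zero penalty down ``decades`` decades."""
    return np.logspace(math.log10(lam_max), math.log10(lam_max) - decades, n_values)


@dataclass
class _Scaler:
    """Median imputation + z-scoring frozen from training data only."""

    medians: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        med = np.nanmedian(X, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        Xi = np.where(np.isnan(X), med, X)
        sds = Xi.std(axis=0)
        return cls(medians=med, means=Xi.mean(axis=0), sds=np.where(sds > 0, sds, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xi = np.where(np.isnan(X), self.medians, X)
        return (Xi - self.means) / self.sds


@dataclass
class LEPMResults:
    """Nested-CV evaluation of the listener-effort prediction model."""

    fold_penalty: list[float]
    fold_rmse: list[float]
    fold_r2: list[float]
    fold_coefs: list[np.ndarray]
    feature_names: list[str]
    predictions: pd.DataFrame  # session_id, participant_id, fold, y_true, y_pred

    @property
    def rmse_mean(self) -> float:
        return float(np.mean(self.fold_rmse))

    @property
    def rmse_sd(self) -> float:
        return float(np.std(self.fold_rmse, ddof=1))

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def r2_sd(self) -> float:
        return float(np.std(self.fold_r2, ddof=1))

    @property
    def relative_weights(self) -> pd.Series:
        """|coefficient| / sum|coefficients| per fold, averaged across folds."""
        rows = []
        for c in self.fold_coefs:
            tot = np.sum(np.abs(c))
            rows.append(np.abs(c) / tot if tot > 0 else np.zeros_like(c))
        return pd.Series(
            np.mean(rows, axis=0), index=self.feature_names
        ).sort_values(ascending=False)

    def summary(self) -> str:
        lines = [
            "Listener-effort prediction model — nested CV "
            f"({len(self.fold_rmse)} outer folds)",
            f"  RMSE: {self.rmse_mean:.2f} ± {self.rmse_sd:.2f} LE points",
            f"  R²:   {self.r2_mean:.3f} ± {self.r2_sd:.3f}",
            "  average relative feature weights:",
        ]
        for name, wgt in self.relative_weights.items():
            if wgt > 0:
                lines.append(f"    {name:<18s} {wgt:.3f}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "rmse_mean": self.rmse_mean,
            "rmse_sd": self.rmse_sd,
            "r2_mean": self.r2_mean,
            "r2_sd": self.r2_sd,
            "fold_penalty": list(map(float, self.fold_penalty)),
            "fold_rmse": list(map(float, self.fold_rmse)),
            "fold_r2": list(map(float, self.fold_r2)),
            "relative_weights": self.relative_weights.to_dict(),
        }


class ListenerEffortModel:
    """Lasso LE predictor with participant-grouped nested cross-validation.

    Parameters
    ----------
    data : DataFrame
        One row per session with the 13 feature columns, ``target_le`` in
        [0, 100], ``participant_id`` and optionally ``session_id``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_cols: list[str] | None = None,
        target_col: str = "target_le",
        participant_col: str = "participant_id",
        n_outer: int = 5,
        n_inner: int = 5,
        grid_size: int = 50,
        grid_decades: float = 4.0,
        uniformity_alpha: float = 0.05,
        max_retries: int = 1000,
    ) -> None:
        self.feature_cols = feature_cols or list(FEATURE_NAMES)
        missing = [c for c in self.feature_cols + [target_col, participant_col] if c not in data]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.data = data.reset_index(drop=True)
        self.target_col = target_col
        self.participant_col = participant_col
        self.n_outer = n_outer
        self.n_inner = n_inner
        self.grid_size = grid_size
        self.grid_decades = grid_decades
        self.uniformity_alpha = uniformity_alpha
        self.max_retries = max_retries

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "ListenerEffortModel":
        return cls(data, **kwargs)

    def fit(self, seed: int | np.random.Generator = 0) -> LEPMResults:
        rng = np.random.default_rng(seed)
        X_all = self.data[self.feature_cols].to_numpy(dtype=float)
        y_all = self.data[self.target_col].to_numpy(dtype=float)
        groups = self.data[self.participant_col].to_numpy()
        sess = (
            self.data["session_id"].astype(str).to_numpy()
            if "session_id" in self.data
            else self.data.index.astype(str).to_numpy()
        )

        outer = make_group_folds(
            groups, y_all, self.n_outer, self.uniformity_alpha, self.max_retries, rng
        )
        fold_penalty, fold_rmse, fold_r2, fold_coefs = [], [], [], []
        pred_rows = []
        for k in range(self.n_outer):
            tr, te = outer != k, outer == k
            X_tr, y_tr, g_tr = X_all[tr], y_all[tr], groups[tr]

            # inner grouped CV on the outer training set picks the penalty
            inner = make_group_folds(
                g_tr, y_tr, self.n_inner, self.uniformity_alpha, self.max_retries, rng
            )
            scaler_probe = _Scaler.fit(X_tr)
            grid = penalty_grid(
                lambda_max(scaler_probe.transform(X_tr), y_tr),
                self.grid_size,
                self.grid_decades,
            )
            val_mse = np.zeros(len(grid))
            for j in range(self.n_inner):
                itr, iva = inner != j, inner == j
                sc = _Scaler.fit(X_tr[itr])
                Xi, Xv = sc.transform(X_tr[itr]), sc.transform(X_tr[iva])
                for gi, pen in enumerate(grid):
                    coef, b0 = fit_l1(Xi, y_tr[itr], pen)
                    resid = y_tr[iva] - (Xv @ coef + b0)
                    val_mse[gi] += float(np.mean(resid**2))
            best = grid[int(np.argmin(val_mse))]

            # refit on the four training outer folds, test on the held-out fold
            sc = _Scaler.fit(X_tr)
            coef, b0 = fit_l1(sc.transform(X_tr), y_tr, best)
            y_hat = sc.transform(X_all[te]) @ coef + b0
            rmse, r2 = evaluate(y_hat, y_all[te])
            fold_penalty.append(float(best))
            fold_rmse.append(rmse)
            fold_r2.append(r2)
            fold_coefs.append(coef)
            for s, p_, yt, yp in zip(sess[te], groups[te], y_all[te], y_hat):
                pred_rows.append(
                    dict(session_id=s, participant_id=p_, fold=k, y_true=yt, y_pred=yp)
                )
        # grouping integrity: every participant in exactly one outer test fold
        by_pid = pd.DataFrame({"pid": groups, "fold": outer}).groupby("pid")["fold"].nunique()
        assert (by_pid == 1).all(), "participant straddles an outer fold boundary"

        return LEPMResults(
            fold_penalty=fold_penalty,
            fold_rmse=fold_rmse,
            fold_r2=fold_r2,
            fold_coefs=fold_coefs,
            feature_names=list(self.feature_cols),
            predictions=pd.DataFrame(pred_rows),
        )


def nested_cv(
    data: pd.DataFrame, seed: int | np.random.Generator = 0, **kwargs
) -> LEPMResults:
    """Functional wrapper around `ListenerEffortModel(...).fit(seed)`."""
    return ListenerEffortModel(data, **kwargs).fit(seed)
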