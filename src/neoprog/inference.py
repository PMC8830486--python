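"""Correlation screening and leave-one-subject-out ensemble regression.

Features are screened against outcome scores with the Pearson coefficient;
significance comes from t = r sqrt(n-2) / sqrt(1-r^2) referred to a
t-distribution with n-2 degrees of freedom (two-tailed), with an inclusive
threshold p <= alpha.  No multiple-testing correction is applied across the
feature set; interpret screen hits on real data accordingly.

Prediction uses tree ensembles -- bootstrap-aggregated (bagged) regression
trees and least-squares gradient-boosted shallow trees -- evaluated by
leave-one-subject-out cross-validation (LOSOCV): each subject is predicted
by a model trained on the remaining n-1, and RMSE / MAE / R-squared are
pooled over the held-out predictions (fold-averaged metrics are logged
alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import BaggingRegressor, GradientBoostingRegressor
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "CorrelationResult",
    "ModelSpec",
    "PredictionReport",
    "pearson_r",
    "p_from_r",
    "screen_features",
    "fit_ensemble",
    "losocv",
    "regression_metrics",
]


@dataclass(frozen=True)
class ModelSpec:
    """Tree-ensemble hyperparameters.

    Defaults mirror common regression-learner presets: 30 learners,
    boosted learning rate 0.1, minimum leaf size 8, unconstrained depth.
    """

    kind: str = "bagged"
    n_learners: int = 30
    learning_rate: float = 0.1
    min_leaf: int = 8
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"bagged", "boosted"}:
            raise ValueError(f"kind must be 'bagged' or 'boosted', got {self.kind!r}")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")


@dataclass
class CorrelationResult:
    feature_id: str
    r: float
    t_statistic: float
    p_value: float
    n: int
    significant: bool


@dataclass
class PredictionReport:
    model_spec: ModelSpec
    subjects: list[str]
    actual: np.ndarray
    predicted: np.ndarray
    rmse: float
    mae: float
    r_squared: float
    fold_log: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subjects, "actual": self.actual, "predicted": self.predicted}
        )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation, clamped to [-1, 1] against rounding."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def p_from_r(r: float, n: int) -> float:
    """Two-tailed p-value of a Pearson coefficient via the t-transform.

    t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom; |r| = 1 gives
    p = 0 exactly.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| cannot exceed 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def screen_features(
    features: pd.DataFrame, scores: pd.Series | np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson screen of every feature column against the outcome scores.

    Returns a frame (feature, r, t, p_value, n, significant) sorted by
    p-value; significance is inclusive (p <= alpha).  Constant feature
    columns are reported with r = 0 and p = 1 rather than raising, since
    degenerate features routinely occur in screened tables.
    """
    y = np.asarray(scores, dtype=float)
    if len(y) != len(features):
        raise ValueError(
            f"{len(y)} scores for {len(features)} subjects in the feature table"
        )
    n = len(y)
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            r, t, p = 0.0, 0.0, 1.0
        else:
            r = pearson_r(x, y)
            t = float(r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r * r, np.finfo(float).tiny)))
            p = p_from_r(r, n)
        rows.append(
            {
                "feature": name,
                "r": r,
                "t": t,
                "p_value": p,
                "n": n,
                "significant": p <= alpha,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    )


def fit_ensemble(features: np.ndarray, scores: np.ndarray, spec: ModelSpec):
    """Fit a bagged or boosted regression-tree ensemble.

    Bagged: bootstrap-resampled trees whose predictions are averaged.
    Boosted: least-squares gradient boosting of depth-limited trees at the
    configured learning rate.  Deterministic given ``spec.seed``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite value in features or scores")
    if len(x) < 2:
        raise ValueError("need at least 2 training subjects")
    if spec.kind == "bagged":
        model = BaggingRegressor(
            estimator=DecisionTreeRegressor(
                min_samples_leaf=spec.min_leaf, max_depth=spec.max_depth
            ),
            n_estimators=spec.n_learners,
            random_state=spec.seed,
        )
    else:
        model = GradientBoostingRegressor(
            n_estimators=spec.n_learners,
            learning_rate=spec.learning_rate,
            min_samples_leaf=min(spec.min_leaf, max(1, len(x) // 2)),
            max_depth=spec.max_depth if spec.max_depth is not None else 3,
            random_state=spec.seed,
        )
    model.fit(x, y)
    return model


def regression_metrics(
    actual: np.ndarray, predicted: np.ndarray
) -> tuple[float, float, float]:
    """(RMSE, MAE, R-squared) of predictions against actual scores.

    R-squared compares against the constant baseline at the mean of the
    actual scores: 1 - SSE / SS_total.  Zero-variance actuals make
    R-squared undefined and raise.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length and non-empty")
    err = p - a
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ss_total = float(np.sum((a - a.mean()) ** 2))
    if ss_total == 0:
        raise ValueError("R-squared undefined: actual scores have zero variance")
    r_squared = 1.0 - float(np.sum(err**2)) / ss_total
    return rmse, mae, r_squared


def losocv(
    features: pd.DataFrame | np.ndarray,
    scores: pd.Series | np.ndarray,
    spec: ModelSpec = ModelSpec(),
) -> PredictionReport:
    """Leave-one-subject-out cross-validated prediction of the scores.

    Each of the n subjects is predicted once by an ensemble trained on the
    other n-1; RMSE, MAE and R-squared are pooled over the n held-out
    predictions, and per-fold absolute errors are kept in ``fold_log``
    (with fold-averaged metrics in the last entry).
    """
    if isinstance(features, pd.DataFrame):
        subjects = [str(s) for s in features.index]
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        subjects = [str(i) for i in range(len(x))]
    y = np.asarray(scores, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOSOCV needs at least 3 subjects")
    if x.shape[0] != n:
        raise ValueError("feature rows and scores differ in length")

    predicted = np.empty(n)
    fold_log: list[dict] = []
    for i in range(n):
        mask = np.arange(n) != i
        model = fit_ensemble(x[mask], y[mask], spec)
        predicted[i] = float(model.predict(x[i : i + 1])[0])
        fold_log.append(
            {"fold": i, "subject": subjects[i], "abs_error": abs(predicted[i] - y[i])}
        )

    err = predicted - y
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(err**2)) / ss_total if ss_total > 0 else float("nan")
    fold_log.append(
        {
            "fold": "averaged",
            "rmse_fold_mean": float(np.mean(np.abs(err))),
            "note": "per-fold (single-subject) metrics averaged; pooled values are headline",
        }
    )
    return PredictionReport(
        model_spec=spec,
        subjects=subjects,
        actual=y,
        predicted=predicted,
        rmse=rmse,
        mae=mae,
        r_squared=r_squared,
        fold_log=fold_log,
    )
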