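"""Regression performance metrics and the standardized 17-value record.

Conventions:

* CV and test R² use the squared-Pearson-correlation form (affine
  invariant, bounded in [0, 1]); the training *fit* R² uses the
  coefficient-of-determination form 1 − RSS/TSS.  Both appear in the
  record.
* "Standardized RMSE" is RMSE divided by the sample standard deviation
  (n−1 denominator) of the observed values — dimensionless, comparable
  across endpoints.
* Undefined quantities (zero-variance inputs, n ≤ p+1) are recorded as NaN
  with a warning, never silently fabricated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np


class MetricError(ValueError):
    pass


def _check_pair(obs, pred):
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise MetricError("obs and pred must be 1-d vectors of equal length")
    if len(obs) == 0:
        raise MetricError("empty vectors")
    return obs, pred


def rmse(obs, pred) -> float:
    """Root mean squared error, sqrt(mean((obs − pred)²))."""
    obs, pred = _check_pair(obs, pred)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def pearson_correlation(obs, pred) -> float:
    """Pearson r; NaN (with warning) if either vector has zero variance."""
    obs, pred = _check_pair(obs, pred)
    if np.std(obs) == 0 or np.std(pred) == 0:
        warnings.warn("zero-variance input: correlation undefined, recorded as NaN")
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def r_squared(obs, pred) -> float:
    """Squared Pearson correlation between observed and predicted values.

    This is the resampling/test-set convention: bounded in [0, 1] and
    invariant to affine transformation of the predictions.
    """
    r = pearson_correlation(obs, pred)
    return r * r if not math.isnan(r) else float("nan")


def r_squared_fit(obs, pred) -> float:
    """Coefficient of determination 1 − RSS/TSS (training-fit convention)."""
    obs, pred = _check_pair(obs, pred)
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0:
        warnings.warn("zero-variance obs: fit R² undefined, recorded as NaN")
        return float("nan")
    rss = float(np.sum((obs - pred) ** 2))
    return 1.0 - rss / tss


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """1 − (1 − R²)(n − 1)/(n − p − 1); NaN with warning when n ≤ p + 1."""
    if math.isnan(r2):
        return float("nan")
    if n <= p + 1:
        warnings.warn(f"adjusted R² undefined for n={n}, p={p}; recorded as NaN")
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def standardized_rmse(obs, pred) -> float:
    """RMSE divided by the sample sd (n−1) of the observed values."""
    obs, pred = _check_pair(obs, pred)
    sd = float(np.std(obs, ddof=1)) if len(obs) > 1 else 0.0
    if sd == 0:
        warnings.warn("zero sd of obs: standardized RMSE undefined, recorded as NaN")
        return float("nan")
    return rmse(obs, pred) / sd


@dataclass
class CVMetrics:
    """Held-out metrics of the winning hyperparameters across resamples.

    For repeated k-fold each resample contributes one (RMSE, R²) pair.
    For LOO the singleton residuals are pooled: per-singleton R² is
    undefined, so RMSE comes from the pooled residual vector and R² from
    the pooled observed/predicted pairs.
    """

    kind: str  # repeated_kfold | loo
    per_resample_rmse: list
    per_resample_r2: list
    pooled_obs: np.ndarray | None = None
    pooled_pred: np.ndarray | None = None


def cv_statistics(metrics: CVMetrics) -> tuple[float, float]:
    """(rmse_cv, r2_cv): resample means, or pooled values for LOO."""
    if metrics.kind == "loo":
        if metrics.pooled_obs is None or len(metrics.pooled_obs) == 0:
            raise MetricError("LOO metrics require pooled obs/pred")
        return (
            rmse(metrics.pooled_obs, metrics.pooled_pred),
            r_squared(metrics.pooled_obs, metrics.pooled_pred),
        )
    if not metrics.per_resample_rmse:
        raise MetricError("empty resample metric list")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rmse_cv = float(np.nanmean(metrics.per_resample_rmse))
        r2_cv = float(np.nanmean(metrics.per_resample_r2))
    return rmse_cv, r2_cv


#: Fixed column order of the standardized statistics record.
STAT_COLUMNS = (
    "method",
    "split_index",
    "cv_type",
    "n_features",
    "feature_names",
    "train_adj_r2",
    "rmse_cv",
    "r2_cv",
    "std_rmse_train",
    "test_adj_r2",
    "rmse_test",
    "r2_test",
    "test_correlation",
    "train_rmse_fit",
    "train_r2_fit",
    "train_correlation",
    "std_rmse_test",
)


@dataclass
class StatRecord:
    """The standardized 17-value statistics row for one method × split × CV type."""

    method: str
    split_index: int
    cv_type: str
    n_features: int
    feature_names: list[str]
    train_adj_r2: float
    rmse_cv: float
    r2_cv: float
    std_rmse_train: float
    test_adj_r2: float
    rmse_test: float
    r2_test: float
    test_correlation: float
    train_rmse_fit: float
    train_r2_fit: float
    train_correlation: float
    std_rmse_test: float

    NUMERIC_FIELDS = STAT_COLUMNS[5:]

    def as_row(self) -> dict:
        row = {f.name: getattr(self, f.name) for f in fields(self)}
        row["feature_names"] = ";".join(row["feature_names"])
        return row


def evaluate_split(model, ds_train, ds_test, cv_metrics: CVMetrics,
                   split_index: int, cv_type: str) -> StatRecord:
    """Assemble the full record for a fitted model on one split.

    Train-side statistics come from refit predictions on the training
    partition; test-side from the untouched test partition; CV columns from
    the held-out resample metrics of the winning hyperparameters.
    """
    yhat_train = model.predict(ds_train.X)
    yhat_test = model.predict(ds_test.X)
    p = model.n_features
    rmse_cv_v, r2_cv_v = cv_statistics(cv_metrics)
    train_r2_fit = r_squared_fit(ds_train.y, yhat_train)
    r2_test = r_squared(ds_test.y, yhat_test)
    return StatRecord(
        method=model.method,
        split_index=split_index,
        cv_type=cv_type,
        n_features=p,
        feature_names=list(model.selected_features),
        train_adj_r2=adjusted_r_squared(train_r2_fit, ds_train.n_cases, p),
        rmse_cv=rmse_cv_v,
        r2_cv=r2_cv_v,
        std_rmse_train=standardized_rmse(ds_train.y, yhat_train),
        test_adj_r2=adjusted_r_squared(r2_test, ds_test.n_cases, p),
        rmse_test=rmse(ds_test.y, yhat_test),
        r2_test=r2_test,
        test_correlation=pearson_correlation(ds_test.y, yhat_test),
        train_rmse_fit=rmse(ds_train.y, yhat_train),
        train_r2_fit=train_r2_fit,
        train_correlation=pearson_correlation(ds_train.y, yhat_train),
        std_rmse_test=standardized_rmse(ds_test.y, yhat_test),
    )
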