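"""Accuracy metrics and error-heterogeneity analysis on held-out predictions.

Metrics per parameter and method: RMSE, MAE with its standard error
(sd of the absolute errors / sqrt(n)), and NMAE — the MAE normalized by the
prior range of the parameter, which makes errors comparable across
parameters with very different scales.  The error-surface analysis explains
|standardized error| = |(y_hat - y)| / (prior range) by the true parameter
values through a random-forest regression, ranks parameters by permutation
importance, and bins the errors over the two most explanatory parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .demography import PriorSpec

__all__ = [
    "EvalReport",
    "ErrorSurface",
    "compute_metrics",
    "standardized_errors",
    "error_surface",
    "evaluate_predictions",
]


def compute_metrics(y_true, y_pred, prior: PriorSpec) -> dict[str, float]:
    """RMSE, MAE, se(MAE) and NMAE = MAE / (prior.high - prior.low)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.shape[0] < 2:
        raise ValueError("y_true and y_pred must be equal-length with n >= 2")
    err = y_pred - y_true
    abs_err = np.abs(err)
    mae = float(abs_err.mean())
    se_mae = float(abs_err.std(ddof=1) / np.sqrt(abs_err.shape[0]))
    rng = prior.width
    return {
        "RMSE": float(np.sqrt((err**2).mean())),
        "MAE": mae,
        "se_MAE": se_mae,
        "NMAE": mae / rng if rng > 0 else np.nan,
    }


def standardized_errors(y_true, y_pred, prior: PriorSpec) -> np.ndarray:
    """Signed per-row errors scaled by the prior range, (y_hat - y)/(high - low)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return (y_pred - y_true) / prior.width


@dataclass
class EvalReport:
    """Per (parameter, method) metric table plus prediction/target pairs."""

    metrics: pd.DataFrame  # index (parameter, method); columns RMSE, MAE, se_MAE, NMAE
    predictions: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    targets: dict[str, np.ndarray] = field(default_factory=dict)

    def summary(self) -> str:
        return self.metrics.to_string(float_format=lambda v: f"{v:.4g}")


def evaluate_predictions(
    targets: dict[str, np.ndarray],
    predictions: dict[tuple[str, str], np.ndarray],
    priors: dict[str, PriorSpec],
) -> EvalReport:
    """Build the metric table from {(parameter, method): y_hat} predictions."""
    rows = []
    for (param, method), y_pred in predictions.items():
        m = compute_metrics(targets[param], y_pred, priors[param])
        rows.append({"parameter": param, "method": method, **m})
    metrics = pd.DataFrame(rows).set_index(["parameter", "method"]).sort_index()
    return EvalReport(metrics=metrics, predictions=dict(predictions), targets=dict(targets))


@dataclass
class ErrorSurface:
    """Binned mean |standardized error| over the two most explanatory parameters."""

    std_errors: np.ndarray
    param_names: list[str]
    importance: np.ndarray  # permutation importance of each parameter
    top_params: list[str]
    grid: np.ndarray  # (n_bins, n_bins) mean |standardized error|, NaN = empty
    edges_x: np.ndarray
    edges_y: np.ndarray


def error_surface(
    std_errors: np.ndarray,
    true_params: np.ndarray,
    param_names: list[str],
    n_top: int = 2,
    grid: int = 20,
    seed: int = 0,
) -> ErrorSurface:
    """Identify which parameters drive prediction error, and map the error.

    Fits a random forest of |standardized error| on the true parameter
    values, ranks parameters by permutation importance, and averages the
    absolute errors over a ``grid`` x ``grid`` binning of the top two.
    """
    std_errors = np.asarray(std_errors, dtype=float)
    true_params = np.asarray(true_params, dtype=float)
    if std_errors.shape[0] < 50:
        raise ValueError("need at least 50 rows for the error-surface analysis")
    abs_err = np.abs(std_errors)
    rf = RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1)
    rf.fit(true_params, abs_err)
    imp = _sk_permutation_importance(
        rf, true_params, abs_err, n_repeats=5, random_state=seed, n_jobs=1
    ).importances_mean
    order = np.argsort(-imp, kind="stable")[:n_top]
    xi, yi = int(order[0]), int(order[1])
    x, y = true_params[:, xi], true_params[:, yi]
    ex = np.linspace(x.min(), x.max(), grid + 1)
    ey = np.linspace(y.min(), y.max(), grid + 1)
    bx = np.clip(np.digitize(x, ex) - 1, 0, grid - 1)
    by = np.clip(np.digitize(y, ey) - 1, 0, grid - 1)
    sums = np.zeros((grid, grid))
    counts = np.zeros((grid, grid))
    np.add.at(sums, (bx, by), abs_err)
    np.add.at(counts, (bx, by), 1.0)
    with np.errstate(invalid="ignore"):
        surface = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ErrorSurface(
        std_errors=std_errors,
        param_names=list(param_names),
        importance=imp,
        top_params=[param_names[xi], param_names[yi]],
        grid=surface,
        edges_x=ex,
        edges_y=ey,
    )
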