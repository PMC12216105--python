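"""Per-parameter regression of demographic parameters on summary statistics.

One single-output model is trained per demographic parameter, on
standardized feature tables, with the mean squared error loss: a random
forest (RF, 300 trees of depth 20 by default, within the tuned 200-300 /
15-20 ranges), gradient-boosted trees (XGB, 100 trees of depth 7), or a
multilayer perceptron (MLP, six or seven fully connected ReLU layers).
The validation set is used only to stop MLP training early; it never enters
the gradient or tree-fitting data.  MLP predictions falling outside the
parameter's prior interval are clipped to the violated bound; the tree
ensembles cannot extrapolate beyond their training targets and are returned
as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

from .demography import PriorSpec

__all__ = [
    "Standardizer",
    "RegressorConfig",
    "TrainedRegressor",
    "fit_standardizer",
    "apply_standardizer",
    "train_regressor",
    "predict",
]

Method = Literal["RF", "XGB", "MLP"]


@dataclass
class Standardizer:
    """Column-wise (x - mean) / sd transform fitted on training rows only.

    The population-sd convention (denominator n) is used; zero-variance
    columns are centred but not scaled, so they transform to all zeros.
    """

    mean: np.ndarray
    scale: np.ndarray  # 1.0 where the training sd is 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale + self.mean


def fit_standardizer(train_features: np.ndarray) -> Standardizer:
    X = np.asarray(train_features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two training rows")
    scaler = StandardScaler().fit(X)
    return Standardizer(mean=scaler.mean_.copy(), scale=scaler.scale_.copy())


def apply_standardizer(std: Standardizer, features: np.ndarray) -> np.ndarray:
    return std.transform(features)


@dataclass(frozen=True)
class RegressorConfig:
    """Hyperparameters of one per-parameter regressor.

    Tree settings default to the tuned values (RF: 300 trees, depth 20;
    XGB: 100 trees, depth 7).  The MLP depth is six or seven hidden
    layers; widths, optimizer and epoch budget are this package's choices:
    layer widths (512, 256, 128, 64, 32, 16), Adam, early stopping on the
    validation MSE with patience 20 within a 500-epoch budget.
    """

    method: Method = "RF"
    seed: int = 0
    rf_n_trees: int = 300
    rf_max_depth: int = 20
    rf_max_features: float = 1 / 3  # classic regression-forest mtry = p/3
    xgb_n_trees: int = 100
    xgb_max_depth: int = 7
    mlp_hidden: tuple[int, ...] = (512, 256, 128, 64, 32, 16)
    mlp_max_epochs: int = 500
    mlp_patience: int = 20
    mlp_batch_size: int = 200
    mlp_learning_rate: float = 1e-3
    mlp_l1_penalty: float = 0.0  # optional L1 flag; off by default and untuned

    def __post_init__(self) -> None:
        if self.method not in ("RF", "XGB", "MLP"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "RF" and not (200 <= self.rf_n_trees <= 300 and 15 <= self.rf_max_depth <= 20):
            raise ValueError("RF settings outside the tuned ranges (override explicitly)")
        if self.method == "MLP" and len(self.mlp_hidden) not in (6, 7):
            raise ValueError("MLP depth must be six or seven hidden layers")


@dataclass
class TrainedRegressor:
    """A fitted per-parameter model with its standardizer and clipping bounds."""

    model: object
    standardizer: Standardizer
    target: str
    prior: PriorSpec
    config: RegressorConfig
    feature_names: tuple[str, ...] | None = None
    n_epochs: int | None = None  # MLP only

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


class _ScaledMLP:
    """An MLP trained on a standardized target, with the inverse transform
    applied at prediction time (the MSE loss is ill-conditioned for targets
    spanning thousands of generations otherwise)."""

    def __init__(self, mlp: MLPRegressor, y_mean: float, y_scale: float):
        self.mlp = mlp
        self.y_mean = y_mean
        self.y_scale = y_scale

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return self.mlp.predict(Z) * self.y_scale + self.y_mean


def _fit_mlp(
    config: RegressorConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> tuple[_ScaledMLP, int]:
    """Epoch loop with early stopping monitored on the held-out validation
    rows (sklearn's built-in early stopping would instead split the training
    rows, which would leak the epoch choice into the fitting data)."""
    if config.mlp_l1_penalty:
        raise NotImplementedError(
            "the L1-penalty option is exposed but not implemented; the "
            "L1-regularization analysis is outside this package's tested surface"
        )
    y_mean = float(np.mean(y_train))
    y_scale = float(np.std(y_train))
    if y_scale == 0:
        y_scale = 1.0
    t_train = (y_train - y_mean) / y_scale
    t_val = (y_val - y_mean) / y_scale
    mlp = MLPRegressor(
        hidden_layer_sizes=config.mlp_hidden,
        activation="relu",
        solver="adam",
        alpha=0.0,
        batch_size=min(config.mlp_batch_size, X_train.shape[0]),
        learning_rate_init=config.mlp_learning_rate,
        max_iter=1,
        warm_start=False,
        random_state=config.seed,
    )
    best_val = np.inf
    best_weights = None
    since_best = 0
    n_epochs = 0
    for epoch in range(config.mlp_max_epochs):
        mlp.partial_fit(X_train, t_train)
        n_epochs = epoch + 1
        val_mse = float(np.mean((mlp.predict(X_val) - t_val) ** 2))
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_weights = (
                [w.copy() for w in mlp.coefs_],
                [b.copy() for b in mlp.intercepts_],
            )
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.mlp_patience:
                break
    if best_weights is not None:
        mlp.coefs_, mlp.intercepts_ = best_weights
    return _ScaledMLP(mlp, y_mean, y_scale), n_epochs


def train_regressor(
    config: RegressorConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    target: str,
    prior: PriorSpec,
    feature_names: Sequence[str] | None = None,
    standardizer: Standardizer | None = None,
) -> TrainedRegressor:
    """Fit one regressor for one demographic parameter.

    Features are standardized uniformly for all methods (fitted on the
    training rows; pass ``standardizer`` to reuse one across methods).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if not np.isfinite(X_train).all() or not np.isfinite(y_train).all():
        raise ValueError("non-finite values in the training data")
    std = standardizer or fit_standardizer(X_train)
    Z_train = std.transform(X_train)
    n_epochs = None
    if config.method == "RF":
        model = RandomForestRegressor(
            n_estimators=config.rf_n_trees,
            max_depth=config.rf_max_depth,
            max_features=config.rf_max_features,
            random_state=config.seed,
            n_jobs=1,
        )
        model.fit(Z_train, y_train)
    elif config.method == "XGB":
        model = XGBRegressor(
            n_estimators=config.xgb_n_trees,
            max_depth=config.xgb_max_depth,
            objective="reg:squarederror",
            random_state=config.seed,
            n_jobs=1,
        )
        model.fit(Z_train, y_train)
    else:
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        if not np.isfinite(X_val).all() or not np.isfinite(y_val).all():
            raise ValueError("non-finite values in the validation data")
        model, n_epochs = _fit_mlp(config, Z_train, y_train, std.transform(X_val), y_val)
    return TrainedRegressor(
        model=model,
        standardizer=std,
        target=target,
        prior=prior,
        config=config,
        feature_names=tuple(feature_names) if feature_names is not None else None,
        n_epochs=n_epochs,
    )


def predict(trained: TrainedRegressor, X: np.ndarray, feature_names=None) -> np.ndarray:
    """Predict the target parameter; MLP outputs are clipped to the prior."""
    X = np.asarray(X, dtype=float)
    if feature_names is not None and trained.feature_names is not None:
        got, want = list(feature_names), list(trained.feature_names)
        if got != want:
            missing = sorted(set(want) - set(got))
            extra = sorted(set(got) - set(want))
            raise ValueError(
                f"feature schema mismatch: missing={missing[:5]} extra={extra[:5]} "
                "(column order must match training)"
            )
    if X.shape[1] != trained.standardizer.mean.shape[0]:
        raise ValueError(
            f"expected {trained.standardizer.mean.shape[0]} features, got {X.shape[1]}"
        )
    yhat = np.asarray(trained.model.predict(trained.standardizer.transform(X)), dtype=float)
    if trained.config.method == "MLP":
        yhat = np.clip(yhat, trained.prior.low, trained.prior.high)
    return yhat
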