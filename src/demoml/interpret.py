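"""Feature-contribution analysis: permutation importance and Shapley values.

Permutation feature importance (PFI) measures the degradation of held-out
R^2 when one feature column is shuffled (5 repeats by default); class-level
importance sums member features within each of the eleven statistic classes
(negative per-feature values floored at 0) and normalizes to fractions of
the total, for Fig-4-style comparison across methods and parameters.

Shapley values quantify each statistic's signed per-prediction contribution
with the local-accuracy guarantee base + sum(phi) = prediction.  Gradient-
boosted models use XGBoost's built-in exact TreeSHAP (``pred_contribs``),
random forests the exact path-dependent TreeSHAP implemented in this
package, and the MLP a seeded permutation-sampling estimator whose sampled
contributions telescope so that local accuracy holds against the
background-mean base value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_pfi
from xgboost import XGBRegressor

from ._treeshap import forest_shap_values
from .inference import TrainedRegressor
from .sumstats import FeatureSchema

__all__ = [
    "ImportanceReport",
    "ShapleyReport",
    "permutation_importance",
    "class_importance",
    "shapley_values",
]


@dataclass
class ImportanceReport:
    """Per-feature permutation importance (mean +/- sd over repeats)."""

    feature_names: tuple[str, ...]
    importances_mean: np.ndarray
    importances_sd: np.ndarray
    metric: str
    n_repeats: int
    seed: int

    def top(self, k: int = 20) -> pd.DataFrame:
        order = np.argsort(-self.importances_mean, kind="stable")[:k]
        return pd.DataFrame(
            {
                "feature": [self.feature_names[i] for i in order],
                "importance": self.importances_mean[order],
                "sd": self.importances_sd[order],
            }
        )


def permutation_importance(
    trained: TrainedRegressor,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
    metric: str = "r2",
    feature_names=None,
) -> ImportanceReport:
    """Held-out R^2 degradation per feature under within-column shuffles."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    class _Wrapper:
        # present the TrainedRegressor (with its standardizer and clipping)
        # as an sklearn estimator for the shuffling machinery
        def fit(self, *a, **k):  # pragma: no cover - never called
            return self

        def predict(self, Xq):
            return trained.predict(Xq)

        def score(self, Xq, yq):
            yhat = trained.predict(Xq)
            ss_res = ((yq - yhat) ** 2).sum()
            ss_tot = ((yq - yq.mean()) ** 2).sum()
            return 1.0 - ss_res / ss_tot

    res = _sk_pfi(
        _Wrapper(), X, y, n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    names = tuple(
        feature_names
        if feature_names is not None
        else (trained.feature_names or [f"x{i}" for i in range(X.shape[1])])
    )
    return ImportanceReport(
        feature_names=names,
        importances_mean=res.importances_mean,
        importances_sd=res.importances_std,
        metric=metric,
        n_repeats=n_repeats,
        seed=seed,
    )


def class_importance(report: ImportanceReport, schema: FeatureSchema) -> dict[str, float]:
    """Summed per-class importances as fractions of the total.

    Negative per-feature values are floored at 0 before aggregation, so the
    fractions are non-negative and sum to 1 (given any positive total).
    """
    totals: dict[str, float] = {}
    for name, imp in zip(report.feature_names, report.importances_mean):
        cls = schema.class_of(name)  # raises KeyError for unmapped features
        totals[cls] = totals.get(cls, 0.0) + max(imp, 0.0)
    grand = sum(totals.values())
    if grand <= 0:
        return {cls: 0.0 for cls in totals}
    return {cls: v / grand for cls, v in totals.items()}


@dataclass
class ShapleyReport:
    """Per-instance per-feature Shapley values with their base value."""

    feature_names: tuple[str, ...]
    shap_values: np.ndarray  # (n_explain, n_features)
    base_value: float
    predictions: np.ndarray
    feature_values: np.ndarray  # raw (unstandardized) explained instances

    def mean_abs(self) -> pd.Series:
        return pd.Series(
            np.abs(self.shap_values).mean(axis=0), index=list(self.feature_names)
        ).sort_values(ascending=False)

    def dependence(self, feature: str) -> pd.DataFrame:
        j = self.feature_names.index(feature)
        return pd.DataFrame(
            {"value": self.feature_values[:, j], "shap": self.shap_values[:, j]}
        )

    def local_accuracy_residuals(self) -> np.ndarray:
        return self.predictions - (self.base_value + self.shap_values.sum(axis=1))


def _sampling_shap(predict, X_background, X_explain, seed, n_permutations=64):
    """Monte-Carlo permutation Shapley estimator.

    For each sampled (permutation, background row) pair the marginal
    contributions telescope from f(background) to f(x), so the estimates sum
    exactly to prediction minus the mean background prediction.
    """
    rng = np.random.default_rng(seed)
    nb, m = X_background.shape
    phi = np.zeros((X_explain.shape[0], m))
    for r, x in enumerate(X_explain):
        acc = np.zeros(m)
        for _ in range(n_permutations):
            order = rng.permutation(m)
            b = X_background[rng.integers(nb)]
            cur = b.copy()
            prev = float(predict(cur[None])[0])
            # evaluate the telescoping chain in one batched call
            states = np.empty((m, m))
            for k, j in enumerate(order):
                cur[j] = x[j]
                states[k] = cur
            preds = predict(states)
            vals = np.concatenate([[prev], preds])
            acc[order] += np.diff(vals)
        phi[r] = acc / n_permutations
    return phi


def shapley_values(
    trained: TrainedRegressor,
    X_background: np.ndarray,
    X_explain: np.ndarray,
    seed: int = 0,
    n_permutations: int = 64,
) -> ShapleyReport:
    """Shapley values of a trained regressor on the explained instances.

    Tree ensembles use exact TreeSHAP (path-dependent, so the base value is
    the cover-weighted training mean and ``X_background`` is unused); the
    MLP uses the sampling estimator with ``X_background`` as the reference
    distribution.  Clipping of MLP outputs is part of the explained model.
    """
    Xb = np.asarray(X_background, dtype=float)
    Xe = np.asarray(X_explain, dtype=float)
    model = trained.model
    Zb = trained.standardizer.transform(Xb)
    Ze = trained.standardizer.transform(Xe)
    preds = trained.predict(Xe)
    if isinstance(model, XGBRegressor):
        booster = model.get_booster()
        import xgboost as xgb

        contrib = booster.predict(xgb.DMatrix(Ze), pred_contribs=True)
        phi, base = contrib[:, :-1], float(contrib[0, -1])
    elif isinstance(model, RandomForestRegressor):
        phi, base = forest_shap_values(model, Ze)
    else:
        phi = _sampling_shap(lambda Z: trained.predict(
            trained.standardizer.inverse_transform(Z)), Zb, Ze, seed, n_permutations)
        base = float(np.mean(trained.predict(Xb)))
    names = trained.feature_names or tuple(f"x{i}" for i in range(Xe.shape[1]))
    return ShapleyReport(
        feature_names=tuple(names),
        shap_values=np.asarray(phi, dtype=float),
        base_value=base,
        predictions=preds,
        feature_values=Xe,
    )
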