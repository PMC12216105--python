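"""Approximate Bayesian computation baselines.

Three classical algorithms against which the regression methods are
benchmarked: plain rejection, rejection followed by a distance-kernel-
weighted local-linear regression adjustment (Beaumont-style
``theta* = theta - b (s - s_obs)``), and rejection followed by the analogous
adjustment from a small single-hidden-layer (three neurons) network fitted
with the same kernel weights.

Distances are Euclidean on per-statistic scaled features (median absolute
deviation over the reference table; zero-MAD statistics are dropped from
the distance).  The tolerance is the proportion of reference simulations
accepted.  For the adjustment methods, up to ``max_stats`` statistics with
the highest absolute correlation with the target parameter are retained
first, following the classical package's limitation on the statistic count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "ABCResult",
    "abc_rejection",
    "abc_loclinear",
    "abc_neuralnet",
    "point_estimate",
    "select_correlated_stats",
]


@dataclass
class ABCResult:
    """Accepted draws (raw and, for the regression methods, adjusted)."""

    accepted_params: np.ndarray  # (n_acc,) raw parameter draws
    adjusted_params: np.ndarray | None  # None for rejection
    accepted_idx: np.ndarray
    distances: np.ndarray  # distances of the accepted rows, ascending
    tolerance: float
    warning: str | None = None

    @property
    def posterior(self) -> np.ndarray:
        return self.adjusted_params if self.adjusted_params is not None else self.accepted_params

    @property
    def n_accepted(self) -> int:
        return self.accepted_idx.shape[0]


def _mad_scale(ref_stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-statistic median absolute deviation; keep mask for MAD > 0."""
    med = np.median(ref_stats, axis=0)
    mad = np.median(np.abs(ref_stats - med), axis=0)
    keep = mad > 0
    return mad, keep


def _n_accept(tolerance: float, n_ref: int) -> int:
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    n_acc = int(round(tolerance * n_ref))
    if n_acc < 1:
        raise ValueError(
            f"tolerance {tolerance} accepts no simulation out of {n_ref}; "
            "increase the tolerance or the reference table"
        )
    return n_acc


def _reject(target_stats, ref_stats, tolerance):
    target = np.asarray(target_stats, dtype=float).ravel()
    ref = np.asarray(ref_stats, dtype=float)
    mad, keep = _mad_scale(ref)
    if not keep.any():
        raise ValueError("all statistics have zero median absolute deviation")
    d = np.sqrt((((ref[:, keep] - target[keep]) / mad[keep]) ** 2).sum(axis=1))
    n_acc = _n_accept(tolerance, ref.shape[0])
    order = np.argsort(d, kind="stable")  # ties broken by row index
    idx = order[:n_acc]
    return idx, d[idx]


def abc_rejection(target_stats, ref_stats, ref_params, tolerance) -> ABCResult:
    """Accept the round(tolerance * n) reference rows nearest to the target."""
    ref_params = np.asarray(ref_params, dtype=float).ravel()
    idx, dist = _reject(target_stats, ref_stats, tolerance)
    return ABCResult(
        accepted_params=ref_params[idx],
        adjusted_params=None,
        accepted_idx=idx,
        distances=dist,
        tolerance=tolerance,
    )


def select_correlated_stats(ref_stats, ref_params, max_stats: int = 300) -> np.ndarray:
    """Indices of up to ``max_stats`` statistics with the highest absolute
    Pearson correlation with the parameter over the reference table."""
    ref = np.asarray(ref_stats, dtype=float)
    y = np.asarray(ref_params, dtype=float).ravel()
    sd = ref.std(axis=0)
    ysd = y.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = ((ref - ref.mean(axis=0)) * (y - y.mean())[:, None]).mean(axis=0) / (sd * ysd)
    corr = np.where(np.isfinite(corr), np.abs(corr), -1.0)
    k = min(max_stats, ref.shape[1])
    top = np.argsort(-corr, kind="stable")[:k]
    return np.sort(top)


def _epanechnikov(dist: np.ndarray) -> np.ndarray:
    dmax = dist.max()
    if dmax == 0:
        return np.ones_like(dist)
    u = dist / dmax
    w = 1.0 - u**2
    w[w < 0] = 0.0
    if w.sum() == 0:  # all accepted at the maximum distance
        w = np.ones_like(dist)
    return w


def abc_loclinear(
    target_stats, ref_stats, ref_params, tolerance, max_stats: int = 300
) -> ABCResult:
    """Rejection plus kernel-weighted local-linear regression adjustment."""
    ref = np.asarray(ref_stats, dtype=float)
    theta = np.asarray(ref_params, dtype=float).ravel()
    target = np.asarray(target_stats, dtype=float).ravel()
    sel = select_correlated_stats(ref, theta, max_stats)
    idx, dist = _reject(target[sel], ref[:, sel], tolerance)
    w = _epanechnikov(dist)
    S = ref[np.ix_(idx, sel)] - target[sel]  # centred at the observation
    X = np.column_stack([np.ones(idx.shape[0]), S])
    W = w[:, None]
    XtWX = X.T @ (W * X)
    XtWy = X.T @ (w * theta[idx])
    warning = None
    try:
        coef = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        warning = "singular local-linear system; ridge fallback"
        warnings.warn(warning, stacklevel=2)
        lam = 1e-8 * max(np.trace(XtWX) / XtWX.shape[0], 1.0)
        try:
            coef = np.linalg.solve(XtWX + lam * np.eye(X.shape[1]), XtWy)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
    b = coef[1:]
    adjusted = theta[idx] - S @ b
    return ABCResult(
        accepted_params=theta[idx],
        adjusted_params=adjusted,
        accepted_idx=idx,
        distances=dist,
        tolerance=tolerance,
        warning=warning,
    )


def _fit_weighted_net(S, y, w, hidden: int, seed: int):
    """Weighted-MSE fit of a one-hidden-layer tanh network by L-BFGS.

    Returns a predictor over rows of S, or None when optimization fails.
    """
    n, p = S.shape
    rng = np.random.default_rng(seed)
    # scale inputs/targets for a well-conditioned optimization
    mu, sd = S.mean(axis=0), S.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (S - mu) / sd
    ym, ys = y.mean(), y.std()
    ys = ys if ys > 0 else 1.0
    t = (y - ym) / ys
    n_par = hidden * p + hidden + hidden + 1

    def unpack(v):
        o = 0
        W1 = v[o : o + hidden * p].reshape(hidden, p); o += hidden * p
        b1 = v[o : o + hidden]; o += hidden
        W2 = v[o : o + hidden]; o += hidden
        b2 = v[o]
        return W1, b1, W2, b2

    wn = w / w.sum()

    def loss_grad(v):
        W1, b1, W2, b2 = unpack(v)
        A = np.tanh(Z @ W1.T + b1)  # (n, hidden)
        out = A @ W2 + b2
        r = out - t
        loss = float((wn * r**2).sum())
        gout = 2.0 * wn * r
        gW2 = gout @ A
        gb2 = gout.sum()
        gA = gout[:, None] * W2[None, :]
        gpre = gA * (1.0 - A**2)
        gW1 = gpre.T @ Z
        gb1 = gpre.sum(axis=0)
        return loss, np.concatenate([gW1.ravel(), gb1, gW2, [gb2]])

    best = None
    for attempt in range(2):
        v0 = rng.normal(scale=0.5, size=n_par)
        res = minimize(loss_grad, v0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        return None
    W1, b1, W2, b2 = unpack(best.x)

    def predictor(Snew):
        Znew = (np.asarray(Snew, dtype=float) - mu) / sd
        return (np.tanh(Znew @ W1.T + b1) @ W2 + b2) * ys + ym

    return predictor


def abc_neuralnet(
    target_stats, ref_stats, ref_params, tolerance,
    max_stats: int = 300, hidden: int = 3, seed: int = 0,
) -> ABCResult:
    """Rejection plus a kernel-weighted single-hidden-layer network adjustment.

    The accepted draws are shifted by the fitted conditional-mean difference,
    ``theta* = theta - (m(s) - m(s_obs))``; on failure to converge the raw
    accepted draws are returned with a warning flag.
    """
    if hidden < 1:
        raise ValueError("the hidden layer needs at least one neuron")
    ref = np.asarray(ref_stats, dtype=float)
    theta = np.asarray(ref_params, dtype=float).ravel()
    target = np.asarray(target_stats, dtype=float).ravel()
    sel = select_correlated_stats(ref, theta, max_stats)
    idx, dist = _reject(target[sel], ref[:, sel], tolerance)
    w = _epanechnikov(dist)
    S = ref[np.ix_(idx, sel)]
    predictor = _fit_weighted_net(S, theta[idx], w, hidden, seed)
    if predictor is None:
        warnings.warn("neural-network adjustment failed; returning raw draws", stacklevel=2)
        return ABCResult(theta[idx], None, idx, dist, tolerance,
                         warning="nnet non-convergence")
    adjusted = theta[idx] - (predictor(S) - predictor(target[sel][None, :]))
    return ABCResult(theta[idx], np.asarray(adjusted).ravel(), idx, dist, tolerance)


def point_estimate(result: ABCResult, mode: str = "mean") -> float:
    """Posterior point estimate over adjusted (if available) else raw draws."""
    draws = result.posterior
    if draws.shape[0] < 1:
        raise ValueError("no accepted draws")
    if mode == "mean":
        return float(np.mean(draws))
    if mode == "median":
        return float(np.median(draws))
    raise ValueError(f"unknown point-estimate mode {mode!r}")
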