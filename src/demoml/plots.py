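"""Diagnostic plots: predicted-vs-observed panels, error surfaces, and
Shapley beeswarm / dependence views."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import ErrorSurface, EvalReport
from .interpret import ShapleyReport

__all__ = [
    "plot_predicted_vs_observed",
    "plot_error_surface",
    "plot_shap_beeswarm",
    "plot_shap_dependence",
]


def plot_predicted_vs_observed(report: EvalReport, path) -> None:
    params = sorted({p for p, _ in report.predictions})
    methods = sorted({m for _, m in report.predictions})
    fig, axes = plt.subplots(
        len(params), len(methods), figsize=(3 * len(methods), 3 * len(params)),
        squeeze=False,
    )
    for i, param in enumerate(params):
        y = report.targets[param]
        for j, method in enumerate(methods):
            ax = axes[i][j]
            yhat = report.predictions.get((param, method))
            if yhat is None:
                ax.axis("off")
                continue
            ax.plot(y, yhat, ".", ms=2, alpha=0.5)
            lims = [min(y.min(), yhat.min()), max(y.max(), yhat.max())]
            ax.plot(lims, lims, "k-", lw=0.8)
            if i == 0:
                ax.set_title(method)
            if j == 0:
                ax.set_ylabel(param, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_error_surface(surface: ErrorSurface, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    extent = [surface.edges_x[0], surface.edges_x[-1], surface.edges_y[0], surface.edges_y[-1]]
    im = ax.imshow(
        surface.grid.T, origin="lower", aspect="auto", extent=extent, cmap="coolwarm"
    )
    ax.set_xlabel(surface.top_params[0])
    ax.set_ylabel(surface.top_params[1])
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="mean |standardized error|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_shap_beeswarm(report: ShapleyReport, path, top: int = 10, seed: int = 0) -> None:
    rank = report.mean_abs().index[:top]
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(6, 0.5 * top + 1))
    for row, name in enumerate(reversed(list(rank))):
        j = report.feature_names.index(name)
        vals = report.shap_values[:, j]
        feat = report.feature_values[:, j]
        lo, hi = feat.min(), feat.max()
        color = (feat - lo) / (hi - lo) if hi > lo else np.full_like(feat, 0.5)
        ax.scatter(
            vals, row + rng.uniform(-0.25, 0.25, vals.shape[0]),
            c=color, cmap="coolwarm", s=8,
        )
    ax.set_yticks(range(top), list(reversed(list(rank))), fontsize=7)
    ax.axvline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("Shapley value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_shap_dependence(report: ShapleyReport, feature: str, path) -> None:
    dep = report.dependence(feature)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(dep["value"], dep["shap"], ".", color="grey", ms=4)
    ax.set_xlabel(feature)
    ax.set_ylabel("Shapley value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
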