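"""Plot side effects for the CLI report bundle (KM, ROC, forest, scatter)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from roscore.evaluation import CorrelationBlock, GroupComparison, RocBlock
from roscore.survival import CoxFit

_GROUP_COLORS = {"low": "#1f77b4", "high": "#2ca02c"}


def _steps(curve):
    t = np.concatenate([[0.0], curve.event_times])
    s = np.concatenate([[1.0], curve.survival])
    return t, s


def plot_km(comparison: GroupComparison, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in comparison.curves.items():
        t, s = _steps(curve)
        ax.step(
            t,
            s,
            where="post",
            color=_GROUP_COLORS.get(label, None),
            label=f"{label} (n={comparison.n[label]})",
        )
    ax.set_xlabel("years")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(
        f"log-rank p = {comparison.logrank.p:.3g}, HR(high vs low) = {comparison.hr_high_vs_low:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(block: RocBlock, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, roc in (
        ("covariates", block.roc_covariates),
        ("score", block.roc_score),
        ("covariates+score", block.roc_combined),
    ):
        if roc is None:
            continue
        ax.plot(1 - roc.specificity, roc.sensitivity, label=f"{name} (AUC {roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls=":", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(frameon=False, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_forest(fit: CoxFit, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 0.5 * len(fit.names) + 1.2))
    y = np.arange(len(fit.names))[::-1]
    ax.errorbar(
        fit.hr,
        y,
        xerr=[fit.hr - fit.ci_low, fit.ci_high - fit.hr],
        fmt="s",
        color="black",
        capsize=2,
    )
    ax.axvline(1.0, ls=":", c="gray", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(fit.names)
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_score_vs_median_os(block: CorrelationBlock, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    xs = [s for s, _ in block.pairs]
    ys = [m for _, m in block.pairs]
    ax.scatter(xs, ys, color="black", s=20)
    b, a = np.polyfit(xs, ys, 1)
    xr = np.array([min(xs), max(xs)])
    ax.plot(xr, b * xr + a, c="gray", lw=1)
    ax.set_xlabel("score")
    ax.set_ylabel("median OS (years)")
    ax.set_title(f"r = {block.r:.3f}, p = {block.p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
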