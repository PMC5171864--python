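"""Diagnostic plots: segmental regression and standard-curve layouts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_segmental(results, path: Path, title: str = "RMA/RAY vs REG/STU") -> Path:
    """Scatter with the fitted two-segment line and the breakpoint marked."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x, y = results.model.x, results.model.y
    p1 = results.phase_labels == "P1"
    ax.scatter(x[p1], y[p1], s=18, c="tab:blue", label="P1")
    ax.scatter(x[~p1], y[~p1], s=18, c="tab:red", label="P2")
    xs = np.linspace(float(x.min()), float(x.max()), 200)
    ax.plot(xs, results.predict(xs), "k-", lw=1.5)
    ax.axvline(results.x0, ls="--", c="grey", lw=1)
    ax.annotate(f"X0 = {results.x0:.4f}", (results.x0, ax.get_ylim()[1] * 0.9))
    ax.set_xlabel("REG/STU (mm)")
    ax.set_ylabel("RMA/RAY (mm)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_standard_curve(curve, x, y, path: Path, groups=None) -> Path:
    """Scatter of window data with the fitted standard line and 95%
    prediction band."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if groups is None:
        ax.scatter(x, y, s=18, c="tab:gray")
    else:
        for g in sorted(set(groups)):
            sel = np.asarray(groups) == g
            ax.scatter(x[sel], y[sel], s=18, label=str(g))
        ax.legend(frameon=False)
    xs = np.linspace(float(x.min()), float(x.max()), 200)
    ax.plot(xs, curve.predict(xs), "k-", lw=1.5)
    hw = curve.prediction_halfwidth(xs)
    ax.fill_between(xs, curve.predict(xs) - hw, curve.predict(xs) + hw,
                    alpha=0.15, color="k", lw=0)
    ax.set_xlabel("REG/STU (mm)")
    ax.set_ylabel("RMA/RAY (mm)")
    ax.set_title(f"Standard curve, r = {curve.r:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
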