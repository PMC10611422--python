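"""Plotting helpers: adjusted survival curves, spline curves, residuals.

All functions write a file (SVG/PNG by extension) and return the path; the
Agg backend is forced so they work headless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .survival import ResidualDiagnostics, SplineFitResult

__all__ = ["plot_adjusted_curves", "plot_spline", "plot_martingale"]


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.2))
    return plt, fig, ax


def plot_adjusted_curves(curves: pd.DataFrame, path: str | Path) -> Path:
    """Step plot of covariate-adjusted survival per methylation group."""
    plt, fig, ax = _axes()
    for col in curves.columns:
        ax.step(curves.index, curves[col], where="post", label=col)
    ax.set_xlabel("months")
    ax.set_ylabel("adjusted survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title="methylation group", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_spline(result: SplineFitResult, path: str | Path) -> Path:
    """Spline log-hazard-ratio curve over the index with its 95% band."""
    plt, fig, ax = _axes()
    ax.plot(result.grid, result.log_hr, color="C0", label=f"{result.basis} fit")
    ax.fill_between(
        result.grid, result.ci_lower, result.ci_upper, alpha=0.25, color="C0"
    )
    ax.axhline(0.0, color="grey", lw=0.8)
    for k in result.knots:
        ax.axvline(k, color="grey", lw=0.5, ls=":")
    ax.set_xlabel("methylation index (CpG sites methylated)")
    ax.set_ylabel("log hazard ratio vs index 0")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_martingale(diag: ResidualDiagnostics, path: str | Path) -> Path:
    """Martingale residuals vs index with the LOWESS smooth."""
    if diag.martingale is None or diag.smooth is None:
        raise ValueError("diagnostics object carries no martingale residuals")
    plt, fig, ax = _axes()
    ax.scatter(
        diag.martingale["index"], diag.martingale["residual"], s=8, alpha=0.35
    )
    ax.plot(diag.smooth["x"], diag.smooth["y"], color="C1", lw=2, label="smoothed")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("methylation index")
    ax.set_ylabel("martingale residual")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
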