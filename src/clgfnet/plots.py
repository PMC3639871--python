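"""Figure helpers for the group report: mean +/- SE bars and the
score-vs-motif scatter with its least-squares line."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

__all__ = ["group_bar_plot", "correlation_scatter"]


def group_bar_plot(report: dict, measures: list[str], path: str | Path,
                   groups: tuple[str, str] = ("control", "patient")) -> None:
    """One bar pair (mean with SE whisker) per measure."""
    fig, axes = plt.subplots(1, len(measures),
                             figsize=(2.2 * len(measures), 3.0))
    axes = np.atleast_1d(axes)
    for ax, m in zip(axes, measures):
        d = report["measures"][m]
        means = [d[g]["mean"] for g in groups]
        ses = [d[g]["se"] for g in groups]
        ax.bar(groups, means, yerr=ses, capsize=4,
               color=("#4878a8", "#c44e52"))
        ax.set_title(f"{m}\np = {d['p']:.3g}", fontsize=9)
        ax.tick_params(labelsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlation_scatter(table: pd.DataFrame, x: str, y: str,
                        path: str | Path, group: str = "patient") -> None:
    """Scatter of two subject-level columns with a least-squares line."""
    sub = table[table["group"] == group].dropna(subset=[x, y])
    xs = sub[x].to_numpy(float)
    ys = sub[y].to_numpy(float)
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.scatter(xs, ys, color="#c44e52")
    if np.ptp(xs) > 0:
        slope, intercept = np.polyfit(xs, ys, 1)
        grid = np.linspace(xs.min(), xs.max(), 10)
        ax.plot(grid, slope * grid + intercept, "k--", lw=1)
        r = np.corrcoef(xs, ys)[0, 1]
        ax.set_title(f"r = {r:.3f}", fontsize=9)
    ax.set_xlabel(x, fontsize=8)
    ax.set_ylabel(y, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
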