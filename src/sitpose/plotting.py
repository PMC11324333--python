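"""Figures for study reports: per-round training curves and group grids."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

GROUP_COLORS = {"PR": "#777777", "AR": "#1f77b4", "VR": "#d62728"}


def plot_per_round_curves(curves: pd.DataFrame, metric: str, ax=None):
    """Group means with CI bands across the 12 training rounds for one metric."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    sub = curves[curves["metric"] == metric]
    for group, rows in sub.groupby("group", observed=True):
        rows = rows.sort_values("round")
        color = GROUP_COLORS.get(str(group))
        ax.plot(rows["round"], rows["mean"], label=str(group), color=color)
        ax.fill_between(rows["round"], rows["ci_low"], rows["ci_high"],
                        alpha=0.2, color=color)
    ax.set_xlabel("training round")
    ax.set_ylabel(metric)
    ax.legend(frameon=False)
    return ax


def save_report_figures(report, out_dir: Path | str) -> list[Path]:
    """Write one SVG per per-round metric present in the report's curves."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves = pd.DataFrame(report.report["per_round"])
    paths: list[Path] = []
    if curves.empty:
        return paths
    for metric in sorted(curves["metric"].unique()):
        ax = plot_per_round_curves(curves, metric)
        path = out / f"per_round_{metric}.svg"
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
        paths.append(path)
    return paths
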