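"""Optional figures: distribution bands, correlation heatmaps, sweep curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .features import META_COLUMNS  # noqa: E402
from .stats import correlation_heatmap  # noqa: E402

__all__ = ["plot_percentile_bands", "plot_correlation", "plot_sweep",
           "save_standard_plots"]

_LABEL_COLORS = {"SR": "tab:blue", "AF": "tab:orange"}


def _x_values(columns) -> np.ndarray:
    return np.array([float(c.removeprefix("pRR")) for c in columns])


def plot_percentile_bands(summaries, ax=None):
    """Median with IQR and 10–90 percentile bands per label vs threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for label, summ in summaries.items():
        x = _x_values(summ.percentiles.columns)
        color = _LABEL_COLORS.get(label, None)
        p = summ.percentiles
        ax.fill_between(x, p.loc["p10"], p.loc["p90"], alpha=0.2, color=color)
        ax.fill_between(x, p.loc["p25"], p.loc["p75"], alpha=0.35, color=color)
        ax.plot(x, p.loc["p50"], lw=2, color=color, label=label)
    ax.set_xlabel("threshold x (ms)")
    ax.set_ylabel("pRRx (%)")
    ax.legend()
    return ax


def plot_correlation(table: pd.DataFrame, label: str, ax=None):
    """Spearman rho heatmap for one label."""
    rho = correlation_heatmap(table, label)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(rho.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(rho)), rho.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(rho)), rho.index, fontsize=6)
    ax.set_title(f"Spearman rho ({label})")
    plt.colorbar(im, ax=ax)
    return ax


def plot_sweep(sweep_df: pd.DataFrame, ax=None):
    """AUC and selected metric medians vs threshold x."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x = sweep_df["x_ms"]
    ax.plot(x, sweep_df["auc"], "o-", label="AUC")
    for m in ("sensitivity", "specificity", "accuracy"):
        col = f"{m}_median"
        if col in sweep_df:
            ax.plot(x, sweep_df[col], label=f"{m} (median)")
    ax.set_xlabel("threshold x (ms)")
    ax.set_ylabel("value")
    ax.legend(fontsize=8)
    return ax


def save_standard_plots(out_dir, table, summaries, sweep_df=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ax = plot_percentile_bands(summaries)
    ax.figure.savefig(out / "percentile_bands.png", dpi=150,
                      bbox_inches="tight")
    plt.close(ax.figure)
    for label in sorted(table["label"].unique()):
        if (table["label"] == label).sum() >= 3:
            ax = plot_correlation(table, label)
            ax.figure.savefig(out / f"correlation_{label}.png", dpi=150,
                              bbox_inches="tight")
            plt.close(ax.figure)
    if sweep_df is not None:
        ax = plot_sweep(sweep_df)
        ax.figure.savefig(out / "sweep.png", dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
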