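"""Basic figures: ratio-distribution histograms and DE scatter plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ratios import REFERENCE_RATIOS

__all__ = ["plot_ratio_distribution", "plot_scatter"]

_CALL_COLORS = {"up": "magenta", "down": "green", "ns": "black"}


def plot_ratio_distribution(dist: pd.DataFrame, path=None):
    """Histogram of binned ratios, one panel per partition.

    ``dist`` is the ratio_distribution table (bin_left, bin_right, count,
    partition); the overflow bin (right edge inf) is drawn at the cap.
    """
    parts = sorted(dist["partition"].unique())
    fig, axes = plt.subplots(1, len(parts), figsize=(4 * len(parts), 3), squeeze=False)
    for ax, part in zip(axes[0], parts):
        sub = dist[dist["partition"] == part]
        finite = sub[np.isfinite(sub["bin_right"])]
        width = float((finite["bin_right"] - finite["bin_left"]).iloc[0])
        color = "tab:orange" if part.startswith("cis") else "tab:blue"
        ax.bar(finite["bin_left"], finite["count"], width=width, align="edge", color=color)
        overflow = sub[~np.isfinite(sub["bin_right"])]
        if len(overflow):
            ax.bar(overflow["bin_left"], overflow["count"], width=width, align="edge",
                   color="grey")
        for r in (0.5, 1.0, 1.5, 2.0):
            ax.axvline(r, color="k", lw=0.5, ls="--")
        ax.set_title(part)
        ax.set_xlabel("aneuploid / control ratio")
        ax.set_ylabel("genes per bin")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_scatter(scatter: pd.DataFrame, path=None):
    """log2 fold change vs mean expression, coloured by significance call."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sub = scatter[scatter["finite"]]
    for call, color in _CALL_COLORS.items():
        pts = sub[sub["call"] == call]
        ax.scatter(pts["log2_fold_change"], pts["mean_expression"], s=4, c=color,
                   label=call, alpha=0.6)
    for r in REFERENCE_RATIOS:
        ax.axvline(np.log2(r), lw=0.5, ls="--", color="grey")
    ax.set_yscale("log")
    ax.set_xlabel("log2 fold change (aneuploid / control)")
    ax.set_ylabel("mean normalised count")
    ax.legend(markerscale=2, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
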