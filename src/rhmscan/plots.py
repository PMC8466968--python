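"""Plotting helpers: Manhattan plot of the windowed scan and LD-decay curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_manhattan(tab: pd.DataFrame, alpha: float = 0.001, ax=None, title: str = ""):
    """Per-window -log10 p against cumulative genome position; horizontal
    line at the significance threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0.0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(tab.groupby("chromosome", sort=True)):
        x = sub["midpoint"].to_numpy() + offset
        ax.scatter(x, sub["neglog10_p"], s=8, color=f"C{i % 2}")
        ticks.append(offset + sub["midpoint"].max() / 2)
        labels.append(str(chrom))
        offset += sub["end"].max()
    ax.axhline(-np.log10(alpha), color="tab:blue", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    if title:
        ax.set_title(title)
    return ax


def plot_ld_decay(pairs: pd.DataFrame, fit=None, ax=None, title: str = ""):
    """Scatter of pairwise r2 against distance with the fitted decay curve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(pairs["dist"] / 1e6, pairs["r2"], s=4, alpha=0.3, color="grey")
    if fit is not None:
        grid = np.linspace(max(pairs["dist"].min(), 1.0), pairs["dist"].max(), 400)
        ax.plot(grid / 1e6, fit.expected_r2(grid), color="tab:red", lw=1.5)
        if fit.half_decay_bp:
            ax.axvline(fit.half_decay_bp / 1e6, color="tab:blue", ls="--", lw=1)
    ax.set_xlabel("distance (Mb)")
    ax.set_ylabel(r"$r^2$")
    if title:
        ax.set_title(title)
    return ax
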