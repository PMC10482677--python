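"""Matplotlib figures: fishtail plots, screen comparisons, RER time courses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

#: significance palette: positive regulators light blue, negative orange
_COLORS = {"enriched_low": "#7fc3e8", "enriched_high": "#f5a24b", "none": "#bdbdbd"}


def fishtail_plot(table: pd.DataFrame, path, title: str = "") -> None:
    """Scatter log2 MI against total insertions, coloured by regulator call."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for direction, color in _COLORS.items():
        sub = table[table["direction"] == direction]
        ax.scatter(
            sub["x"], sub["y"], s=12, c=color, alpha=0.8,
            label={"enriched_low": "positive regulator", "enriched_high": "negative regulator", "none": "n.s."}[direction],
        )
    ax.axhline(0.0, lw=0.6, c="k")
    ax.set_xscale("log")
    ax.set_xlabel("insertions (high + low)")
    ax.set_ylabel("log2 mutational index")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def comparison_plot(comparison: pd.DataFrame, path, labels=("screen 1", "screen 2")) -> None:
    """Scatter per-gene log2 MI of one screen against the other."""
    sub = comparison[comparison["passes_filter"]]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(sub["log2_mi_screen2"], sub["log2_mi_screen1"], s=12, c="#888888", alpha=0.8)
    lim = np.nanmax(np.abs(sub[["log2_mi_screen1", "log2_mi_screen2"]].to_numpy())) * 1.1 if len(sub) else 1.0
    ax.plot([-lim, lim], [-lim, lim], lw=0.6, c="k")
    ax.set_xlabel(f"log2 MI ({labels[1]})")
    ax.set_ylabel(f"log2 MI ({labels[0]})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def rer_timecourse(analyzed: pd.DataFrame, path) -> None:
    """Per-animal RER over time bins."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for animal, grp in analyzed.groupby("animal_id"):
        grp = grp.sort_values("time_bin")
        ax.plot(grp["time_bin"], grp["rer"], marker=".", lw=0.8, label=str(animal))
    ax.set_xlabel("time bin")
    ax.set_ylabel("RER (VCO2/VO2)")
    ax.axhline(1.0, lw=0.5, c="k", ls=":")
    ax.axhline(0.7, lw=0.5, c="k", ls=":")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
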