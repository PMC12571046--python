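"""Plots for evidence sweeps and power grids (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_bayes_factor_sweep(bf: pd.DataFrame, ax=None):
    """Bayes factor vs interaction prior sd, one line per measure.

    Values above the y=1 reference favour the agreement-type model, below
    it the lexical-category model; the y-axis is logarithmic.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for measure, g in bf.groupby("measure"):
        g = g.sort_values("prior_sd")
        ax.plot(g["prior_sd"], g["bf"], marker="o", label=measure)
    ax.axhline(1.0, color="grey", lw=1)
    ax.set_yscale("log")
    ax.set_xlabel("prior sd of the interaction coefficient")
    ax.set_ylabel("Bayes factor (GramxAgrType / GramxLexCat)")
    ax.legend(fontsize=8)
    return ax


def plot_power_grid(power: pd.DataFrame, ax=None, threshold: float = 0.8):
    """Power vs participants, one line per item count; 0.8 reference line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for n_items, g in power.groupby("n_items"):
        g = g.sort_values("n_participants")
        ax.plot(g["n_participants"], g["power"], marker="o", label=f"{n_items} items")
    ax.axhline(threshold, color="grey", lw=1, ls="--")
    ax.set_ylim(0, 1)
    ax.set_xlabel("participants")
    ax.set_ylabel("power")
    ax.legend(fontsize=8)
    return ax
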