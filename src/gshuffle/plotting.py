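"""Convenience plots; tables are the contract, plots are optional."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_frequency_trajectories", "plot_isolate_matrix"]


def plot_frequency_trajectories(matrix: pd.DataFrame, path=None, ax=None):
    """Grouped bars of per-locus variant frequency by evolution round."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.5 * len(matrix)), 4))
    rounds = list(matrix.columns)
    x = np.arange(len(matrix))
    width = 0.8 / max(1, len(rounds))
    for j, rnd in enumerate(rounds):
        ax.bar(x + j * width, matrix[rnd].fillna(0.0), width, label=str(rnd))
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(matrix.index, rotation=90, fontsize=7)
    ax.set_ylabel("variant read fraction")
    ax.legend(title="round", fontsize=7)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax


_CALL_COLOR = {"homo": "#2ca02c", "het": "#d62728", "none": "#8c564b"}


def plot_isolate_matrix(calls: pd.DataFrame, path=None, ax=None):
    """Isolate x locus genotype heat map (homo/het/none)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(5, 0.35 * calls.shape[1]), 0.3 * calls.shape[0] + 1))
    codes = calls.replace({"none": 0, "het": 1, "homo": 2}).astype(int)
    cmap = matplotlib.colors.ListedColormap(
        [_CALL_COLOR["none"], _CALL_COLOR["het"], _CALL_COLOR["homo"]]
    )
    ax.imshow(codes.to_numpy(), cmap=cmap, vmin=0, vmax=2, aspect="auto")
    ax.set_xticks(range(calls.shape[1]))
    ax.set_xticklabels(calls.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(calls.shape[0]))
    ax.set_yticklabels(calls.index, fontsize=7)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
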