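"""Plotting helpers: grand-average ERP traces and single-trial overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .dataset import EpochSet
from .xdawn import class_average

CLASS_NAMES = {0: "Checkerboard", 1: "Tunnel"}
CLASS_COLORS = {0: "tab:blue", 1: "tab:red"}


def plot_erp(epochs: EpochSet, channel: str = "Oz", ax=None,
             n_single_trials: int = 0, seed: int = 0):
    """Grand-average ERP of both classes at one electrode.

    With ``n_single_trials`` > 0, that many randomly chosen single trials
    per class are overlaid in light color behind the averages (the
    classic trial-vs-average separability picture).
    """
    if channel not in epochs.channel_names:
        raise KeyError(f"unknown channel '{channel}'")
    ch = epochs.channel_names.index(channel)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t_ms = epochs.times * 1000.0
    rng = np.random.default_rng(seed)
    for k in (0, 1):
        if n_single_trials:
            idx = np.flatnonzero(epochs.labels == k)
            take = rng.choice(idx, size=min(n_single_trials, idx.size), replace=False)
            ax.plot(t_ms, epochs.data[take, ch].T, color=CLASS_COLORS[k],
                    alpha=0.08, lw=0.5)
        avg = class_average(epochs, k)
        ax.plot(t_ms, avg.matrix[ch], color=CLASS_COLORS[k], lw=2,
                label=f"{CLASS_NAMES[k]} (n={avg.n_trials_averaged})")
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (uV)")
    ax.set_title(f"Grand average at {channel}")
    ax.legend(frameon=False)
    return ax


def plot_accuracy_curve(curve: np.ndarray, electrode_order: list[str], ax=None):
    """Forward-selection accuracy as a function of electrode count."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    k = np.arange(1, len(curve) + 1)
    ax.plot(k, curve, "o-")
    ax.set_xticks(k)
    ax.set_xticklabels(electrode_order, rotation=45)
    ax.set_xlabel("electrodes (selection order)")
    ax.set_ylabel("LOSO accuracy")
    return ax
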