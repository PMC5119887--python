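"""Minimal figure helpers: peri-meal P_sleep curves and occupancy maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_psleep_curve", "plot_heatmap", "plot_grading"]


def plot_psleep_curve(curve: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3))
    k = curve["rel_minute"]
    m = curve["psleep_mean"]
    s = curve["psleep_sem"]
    ax.fill_between(k, m - s, m + s, alpha=0.3, lw=0)
    ax.plot(k, m, lw=1.2)
    ax.axvline(0, color="k", ls=":", lw=0.8)
    ax.set_xlabel("time relative to meal (min)")
    ax.set_ylabel("P_sleep")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(heat: np.ndarray, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(3, 5))
    ax.imshow(heat, origin="upper", cmap="magma", aspect="auto")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_grading(bins, path, xlabel: str = "meal volume (ul)") -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    x = [b.center for b in bins]
    y = [b.mean_dpsleep for b in bins]
    e = [b.sem_dpsleep for b in bins]
    ax.errorbar(x, y, yerr=e, fmt="o-", ms=4, capsize=2)
    ax.axhline(0, color="k", lw=0.6)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("20-min dP_sleep")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
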