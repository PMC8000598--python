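"""Minimal matplotlib figures: occupancy profiles and the difference logo."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .compare import moving_average
from .pauselogo import BASES, DiffLogoResult

_BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def plot_profiles(
    median_wt: np.ndarray,
    median_mut: np.ndarray,
    window: int,
    path: str | Path,
    labels: tuple[str, str] = ("WT", "spt4d"),
) -> None:
    """Overlay smoothed median occupancy profiles of the two strains."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    for values, label in ((median_wt, labels[0]), (median_mut, labels[1])):
        sm = moving_average(values, window)
        ax.plot(np.arange(1, len(sm) + 1), sm, label=label, linewidth=1)
    ax.set_xlabel("coordinate (transcription direction)")
    ax.set_ylabel(f"median occupancy, {window}-nt moving average")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_difference_logo(result: DiffLogoResult, path: str | Path) -> None:
    """Stacked signed per-base contributions per column; stars mark p < alpha.

    Bars above the axis are overrepresented in the mutant, below in WT.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = (
        result.labels
        if result.labels is not None
        else np.arange(result.heights.size)
    )
    x = np.arange(result.heights.size)
    fig, ax = plt.subplots(figsize=(10, 3))
    pos_base = np.zeros_like(result.heights)
    neg_base = np.zeros_like(result.heights)
    for i, base in enumerate(BASES):
        contrib = result.contributions[i]
        up = np.clip(contrib, 0, None)
        down = np.clip(contrib, None, 0)
        ax.bar(x, up, bottom=pos_base, color=_BASE_COLORS[base], label=base, width=0.8)
        ax.bar(x, down, bottom=neg_base, color=_BASE_COLORS[base], width=0.8)
        pos_base += up
        neg_base += down
    for xi in x[result.significant]:
        ax.annotate(
            "*", (xi, pos_base[xi] + 0.02), ha="center", color="red", fontsize=9
        )
    ax.axhline(0, color="black", linewidth=0.8)
    step = max(1, len(x) // 12)
    ax.set_xticks(x[::step])
    ax.set_xticklabels(labels[::step])
    ax.set_xlabel("position relative to LNT (label -1)")
    ax.set_ylabel("signed JSD contribution (bits)")
    handles, leg_labels = ax.get_legend_handles_labels()
    ax.legend(handles[:4], leg_labels[:4], frameon=False, ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
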