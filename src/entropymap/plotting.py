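"""Diagnostic plot of the histogram, Gaussian prior and entropy curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .entropy import EntropyAnalysis

__all__ = ["plot_entropy_analysis"]


def plot_entropy_analysis(
    analysis: EntropyAnalysis,
    g0: int | None = None,
    g1: int | None = None,
    path: str | Path | None = None,
):
    """Plot H(g), G(g) and R(g)H(g) with threshold markers.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    g = np.arange(256)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(g, analysis.hist.counts, drawstyle="steps-mid", lw=0.8, label="H(g)")
    ax.plot(g, analysis.gaussian, lw=1.0, label="G(g)")
    ax2 = ax.twinx()
    ax2.plot(g, analysis.weighted, color="tab:red", lw=0.8, label="R(g)H(g)")
    ax2.axhline(0, color="tab:red", lw=0.4, alpha=0.5)
    for t, name, color in ((g0, "g0", "k"), (g1, "g1", "tab:purple")):
        if t is not None:
            ax.axvline(t, color=color, ls="--", lw=0.8)
            ax.annotate(name, (t, ax.get_ylim()[1] * 0.9), fontsize=9, color=color)
    ax.set_xlabel("grey level g")
    ax.set_ylabel("pixel counts")
    ax2.set_ylabel("R(g)H(g)")
    handles1, labels1 = ax.get_legend_handles_labels()
    handles2, labels2 = ax2.get_legend_handles_labels()
    ax.legend(handles1 + handles2, labels1 + labels2, loc="upper left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
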