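"""Optional matplotlib figures for the neighbourhood analysis outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .neighbourhood import EnrichmentResult, PositionalProfile, RangeAttribution
from .samples import ALPHABET


def plot_profiles(pos: PositionalProfile, neg: PositionalProfile, path: str | Path) -> Path:
    """Per-position nucleotide frequency lines, positives over negatives."""
    fig, axes = plt.subplots(2, 1, figsize=(9, 5), sharex=True, sharey=True)
    for ax, prof, title in ((axes[0], pos, "positive"), (axes[1], neg, "negative")):
        for j, nt in enumerate(ALPHABET):
            ax.plot(prof.freq[:, j], label=nt, lw=1.2)
        ax.axvspan(21, 26, alpha=0.12, color="grey")
        ax.set_ylabel(f"{title}\nfrequency")
    axes[1].set_xlabel("position (candidate C at 20)")
    axes[0].legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_enrichment(result: EnrichmentResult, path: str | Path,
                    alpha: float = 0.05) -> Path:
    """Signed frequency differences per position, significant cells filled."""
    fig, ax = plt.subplots(figsize=(9, 3.2))
    width = 0.2
    xs = np.arange(result.difference.shape[0])
    for j, nt in enumerate(ALPHABET):
        sig = result.p_value[:, j] < alpha
        heights = result.difference[:, j]
        ax.bar(xs + (j - 1.5) * width, np.where(sig, heights, 0.0), width=width,
               label=nt)
        ax.bar(xs + (j - 1.5) * width, np.where(sig, 0.0, heights), width=width,
               alpha=0.25, color="grey")
    ax.axhline(0.0, color="black", lw=0.6)
    ax.set_xlabel("position")
    ax.set_ylabel("freq(pos) - freq(neg)")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_range_attribution(attr: RangeAttribution, path: str | Path) -> Path:
    """Bar chart of mean absolute attribution per position range."""
    fig, ax = plt.subplots(figsize=(6, 3))
    labels = [f"{a}-{b - 1}" for a, b in attr.ranges]
    ax.bar(labels, attr.values, color="#4878a8")
    ax.set_xlabel("position range")
    ax.set_ylabel("mean |attribution|")
    ax.set_title(f"method: {attr.method}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
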