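"""Genome-wide Z-score plots and Kaplan-Meier curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .genome import BinSet
from .instability import DEFAULT_Z_THRESHOLD


def genome_zscore_plot(binset: BinSet, z: np.ndarray, path: str,
                       threshold: float = DEFAULT_Z_THRESHOLD,
                       title: str | None = None) -> None:
    """Linear genome plot of per-bin Z-scores, gains red, losses blue.

    One x-axis across all chromosomes in grid order, with chromosome
    boundaries marked; bins beyond +/- threshold are highlighted.
    """
    finite = np.isfinite(z)
    x = np.arange(len(binset))
    colors = np.full(len(binset), "0.55", dtype=object)
    with np.errstate(invalid="ignore"):
        colors[z > threshold] = "tab:red"
        colors[z < -threshold] = "tab:blue"
    fig, ax = plt.subplots(figsize=(12, 3.2))
    ax.scatter(x[finite], z[finite], c=list(colors[finite]), s=6)
    ax.axhline(threshold, color="k", lw=0.6, ls="--")
    ax.axhline(-threshold, color="k", lw=0.6, ls="--")
    boundaries = []
    for chrom, sl in binset.chrom_slices().items():
        boundaries.append((chrom, sl.start, sl.stop))
        if sl.start > 0:
            ax.axvline(sl.start - 0.5, color="0.8", lw=0.5)
    ax.set_xticks([(s + e) / 2 for _, s, e in boundaries])
    ax.set_xticklabels([c.removeprefix("chr") for c, _, _ in boundaries],
                       fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("Z-score")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def km_plot(times: np.ndarray, events: np.ndarray, groups: np.ndarray,
            path: str, title: str | None = None) -> None:
    """Kaplan-Meier curves per group on one axis."""
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(5, 4))
    for label in np.unique(groups):
        mask = groups == label
        kmf = KaplanMeierFitter()
        kmf.fit(np.asarray(times)[mask], np.asarray(events)[mask],
                label=str(label))
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
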