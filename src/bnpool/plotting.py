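"""Figures for across-expert spread: mean/sd bars and boxplots.

Both functions take :class:`~bnpool.summaries.ExpertSpread` records (one
per node-state-subgroup cell) and draw the standard survey-spread views:
grouped mean bars with standard-deviation whiskers, and side-by-side
boxplots of the per-expert probabilities.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless; figures go to files
import matplotlib.pyplot as plt

from .summaries import ExpertSpread


def _cell_label(s: ExpertSpread) -> str:
    return f"{s.node}\n{s.state}" if s.state else s.node


def spread_barplot(spreads: Sequence[ExpertSpread], path=None, title: str | None = None):
    """Mean with +/- 1 sd error bars, grouped by node-state and subgroup."""
    cells = list(dict.fromkeys(_cell_label(s) for s in spreads))
    groups = list(dict.fromkeys(s.subgroup for s in spreads))
    fig, ax = plt.subplots(figsize=(max(6, 1.6 * len(cells)), 4))
    width = 0.8 / max(len(groups), 1)
    for gi, group in enumerate(groups):
        xs, means, sds = [], [], []
        for ci, cell in enumerate(cells):
            match = [s for s in spreads if s.subgroup == group and _cell_label(s) == cell]
            if match:
                xs.append(ci + gi * width)
                means.append(match[0].mean)
                sds.append(match[0].sd)
        ax.bar(xs, means, width=width, yerr=sds, capsize=3, label=group)
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(cells))])
    ax.set_xticklabels(cells, fontsize=8)
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def spread_boxplot(spreads: Sequence[ExpertSpread], path=None, title: str | None = None):
    """Boxplots of per-expert probabilities, one box per record."""
    labels = [f"{_cell_label(s)}\n{s.subgroup}" for s in spreads]
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(spreads)), 4))
    ax.boxplot([s.values for s in spreads], tick_labels=labels)
    ax.tick_params(axis="x", labelsize=7)
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
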