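"""Plot helpers for grid aggregates (accuracy vs sampling frequency)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_accuracy_by_frequency", "save_table"]


def plot_accuracy_by_frequency(agg: pd.DataFrame, out_path=None, title=""):
    """Bar chart of aggregated accuracy per (cg, cx) group across rates.

    ``agg`` is the output of :func:`paflz.grid.aggregate_median` or
    :func:`~paflz.grid.aggregate_max`.  Returns the matplotlib figure;
    saves to ``out_path`` when given.
    """
    pivot = agg.pivot_table(
        index=["cg", "cx"], columns="fs", values="accuracy"
    )
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(pivot)), 4))
    pivot.plot.bar(ax=ax)
    ax.set_ylabel("accuracy")
    ax.set_xlabel("coarse graining / complexity method")
    ax.set_ylim(0, 1)
    ax.legend(title="fs (Hz)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig


def save_table(frame: pd.DataFrame, out_path) -> None:
    """Write a ranked-results table (e.g. :func:`paflz.grid.rank_top`) as CSV."""
    frame.to_csv(out_path, index=False)
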