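"""Optional figure rendering for score tables and rankings.

All plots are thin matplotlib views of the tidy tables the scoring module
produces; nothing here affects the computed numbers.
"""

from __future__ import annotations

import pandas as pd


def inka_scatter(plot_set: pd.DataFrame, ax=None, highlight: list[str] | None = None):
    """Scatter of integrated score (y) versus skew (x) for the plot set."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    highlight = set(highlight or [])
    colors = ["red" if k in highlight else "black" for k in plot_set.index]
    ax.scatter(plot_set["skew"], plot_set["inka"], c=colors, s=18)
    for kinase, row in plot_set.iterrows():
        ax.annotate(kinase, (row["skew"], row["inka"]), fontsize=7,
                    xytext=(2, 2), textcoords="offset points")
    ax.set_xlim(0, 1)
    ax.set_xlabel("skew (kinase-centric 0 ↔ 1 substrate-centric)")
    ax.set_ylabel("INKA score")
    return ax


def ranking_bar(bar_graph: pd.DataFrame, ax=None, value: str = "inka"):
    """Horizontal bar graph of the ranked (top-20) kinases."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    block = bar_graph.iloc[::-1]
    ax.barh(block.index.astype(str), block[value], color="grey")
    ax.set_xlabel(value)
    return ax
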