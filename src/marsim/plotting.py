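"""Small plotting helpers for sweep and net-contribution tables."""

from __future__ import annotations

import pandas as pd


def plot_sweep(table: pd.DataFrame, lever: str, metric: str = "ccf", ax=None):
    """Line plot of a metric against one lever from a sweep table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    sub = table.sort_values(lever)
    ax.plot(sub[lever], sub[metric], marker="o")
    ax.set_xlabel(lever.replace("_", " "))
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_title(f"{metric} vs {lever}")
    return ax


def plot_net_contribution(table: pd.DataFrame, ax=None):
    """Bar plot of absolute net contribution by maternal age group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    groups = table[table["group"] != "total"]
    ax.bar(groups["group"], groups["absolute"])
    ax.set_ylabel("net contribution to CCF (children per woman)")
    ax.set_xlabel("maternal age group at birth")
    return ax
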