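"""Simple figures for sweep results and gap-statistic tables."""

from __future__ import annotations

__all__ = ["plot_sweep", "plot_delta_gap"]


def plot_sweep(sweep_df, ax=None):
    """Mean normalized partition distance vs sigma_G/sigma_P, one line per k."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grouped = (
        sweep_df.groupby(["k", "ratio"])["norm_dist_greedy"].mean().reset_index()
    )
    for k, sub in grouped.groupby("k"):
        ax.plot(sub["ratio"], sub["norm_dist_greedy"], marker="o", label=f"k={k}")
    ax.set_xscale("log")
    ax.set_xlabel(r"$\sigma_G / \sigma_P$")
    ax.set_ylabel("normalized partition distance")
    ax.legend()
    return ax


def plot_delta_gap(gap_table, ax=None):
    """deltaGap[k] bar plot; the smallest k with a non-negative bar is chosen."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = gap_table.table.dropna(subset=["delta_gap"])
    ax.bar(t["k"], t["delta_gap"])
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("k")
    ax.set_ylabel(r"$\Delta$Gap[k]")
    if gap_table.chosen_k is not None:
        ax.axvline(gap_table.chosen_k, color="r", ls="--", lw=0.8)
    return ax
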