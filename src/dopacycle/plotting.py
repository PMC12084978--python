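"""Quick-look plots for titrations, design sheets and GC trends.

matplotlib is imported lazily so headless pipelines that never plot pay no
import cost; every function accepts an existing ``ax`` and returns it.
"""

from __future__ import annotations

import pandas as pd


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_titration(titration: pd.DataFrame, ax=None):
    """Final dopamine (and residual l-DOPA) vs lysate mixing ratio."""
    ax = _get_ax(ax)
    ax.plot(titration["ratio"], titration["dopamine_mM"], "o-", label="dopamine")
    ax.plot(titration["ratio"], titration["dopa_mM"], "s--", label="l-DOPA")
    ax.set_xscale("log")
    ax.set_xlabel("HpaBC : Ddc lysate ratio")
    ax.set_ylabel("final concentration (mM)")
    ax.legend()
    return ax


def plot_design_space(sheet: pd.DataFrame, ax=None):
    """Designs in (GC_hpaBC, GC_ddc) space, colored by strategy."""
    ax = _get_ax(ax)
    for strategy, group in sheet.groupby("strategy"):
        ax.scatter(group["gc_hpaBC"], group["gc_ddc"], label=strategy, alpha=0.8)
    ax.set_xlabel("GC fraction, RBS hpaBC")
    ax.set_ylabel("GC fraction, RBS ddc")
    ax.legend(title="strategy")
    return ax


def plot_gc_response(results: pd.DataFrame, fixed_context: str = "hpaBC", ax=None):
    """Dopamine titre vs the free context's GC within the stratified band."""
    ax = _get_ax(ax)
    free_col = "gc_ddc" if fixed_context == "hpaBC" else "gc_hpaBC"
    means = results.groupby("design_id").mean(numeric_only=True)
    ax.scatter(means[free_col], means["dopamine_mg_per_L"])
    ax.set_xlabel(f"GC fraction, RBS {free_col.removeprefix('gc_')}")
    ax.set_ylabel("dopamine (mg/L)")
    return ax
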