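"""Plots: optimal-OR profiles across combination orders and the
RR-vs-frequency curve at fixed PAR."""

from __future__ import annotations

import pandas as pd

from .par import rr_frequency_curve


def plot_or_profile(profile: pd.DataFrame, ax=None):
    """Line plot of the optimal OR per combination order, one line per
    stratum; low-count results (exposed cases or controls < 100) are drawn
    dashed as a caution."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for stratum, sub in profile.groupby("stratum"):
        sub = sub.sort_values("order")
        line, = ax.plot(sub["order"], sub["odds_ratio"], marker="o", label=stratum)
        frail = sub[sub["flagged"]]
        if not frail.empty:
            ax.plot(frail["order"], frail["odds_ratio"], linestyle="--",
                    color=line.get_color())
    ax.set_xlabel("combination order k")
    ax.set_ylabel("optimal odds ratio")
    ax.legend(title="stratum")
    return ax


def plot_rr_frequency(par: float = 0.30, ax=None):
    """RR required versus risk-factor frequency at a fixed PAR."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    curve = rr_frequency_curve(par)
    ax.plot(curve["frequency"], curve["rr"])
    ax.axhline(curve["rr"].min(), linestyle=":", color="grey")
    ax.set_xlabel("risk-factor frequency")
    ax.set_ylabel("required relative risk")
    ax.set_title(f"PAR = {par:.0%}")
    return ax
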