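"""Convenience plots of the standard figure analogues.

Plots are conveniences only; the delimited tables written by the CLI are
the contract.
"""

from __future__ import annotations

import pandas as pd

from .analysis import approach_summary, feature_value_trajectories


def plot_approach_curves(frames: dict[str, pd.DataFrame], ax=None):
    """Session curves (mean +/- s.e.m.) of lever and magazine approach
    counts, one line style per ITI condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    styles = {"short": "--", "long": "-"}
    colors = {"n_goL": "tab:red", "n_goM": "tab:blue"}
    for cond, df in frames.items():
        summ = approach_summary(df)
        g = summ.groupby("session")[["n_goL", "n_goM"]]
        mean, sem = g.mean(), g.sem()
        for col, label in (("n_goL", "lever"), ("n_goM", "magazine")):
            ax.errorbar(
                mean.index,
                mean[col],
                yerr=sem[col],
                linestyle=styles.get(cond, "-"),
                color=colors[col],
                label=f"{label} ({cond} ITI)",
            )
    ax.set_xlabel("session")
    ax.set_ylabel("approaches per session")
    ax.legend(fontsize="small")
    return ax


def plot_value_trajectories(frames: dict[str, pd.DataFrame], ax=None):
    """Session-wise mean feature values of lever and magazine per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    styles = {"short": "--", "long": "-"}
    for cond, df in frames.items():
        traj = feature_value_trajectories(df)
        for col, color in (("v_L", "tab:red"), ("v_M", "tab:blue")):
            ax.plot(
                traj["session"],
                traj[col],
                linestyle=styles.get(cond, "-"),
                color=color,
                label=f"{col[2]} ({cond} ITI)",
            )
    ax.set_xlabel("session")
    ax.set_ylabel("feature value")
    ax.legend(fontsize="small")
    return ax
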