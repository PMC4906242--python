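"""Figure helpers (headless matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def average_trace(ax, times, traces, label=None):
    """Mean trace with a 95% CI band over boutons."""
    traces = np.atleast_2d(traces)
    m = np.nanmean(traces, axis=0)
    sem = np.nanstd(traces, axis=0, ddof=1) / np.sqrt(traces.shape[0])
    ax.plot(times, m, label=label)
    ax.fill_between(times, m - 1.96 * sem, m + 1.96 * sem, alpha=0.3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized fluorescence")
    return ax


def rate_boxplot(ax, rate_df, outcome="exo_rate"):
    groups = sorted(rate_df["group"].unique())
    data = [rate_df.loc[rate_df["group"] == g, outcome].dropna() for g in groups]
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel(outcome)
    return ax


def peak_cdf(ax, summaries: dict):
    """Empirical CDFs of normalized peaks, one curve per condition."""
    for label, s in summaries.items():
        ax.plot(s.grid, s.cdf, drawstyle="steps-post", label=label)
    ax.set_xlabel("normalized peak")
    ax.set_ylabel("cumulative probability")
    ax.legend()
    return ax


def save_figure(fig, path):
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
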