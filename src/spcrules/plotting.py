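"""Convenience plots: an annotated chart of a series, and the
likelihood-ratio summary of a simulation study.

These are diagnostic aids, not publication-grade renderings; signals are
highlighted, centre and sigma limits drawn when available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .analysis import AnalysisReport

__all__ = ["plot_chart", "plot_likelihood_ratios"]


def plot_chart(values: np.ndarray, report: AnalysisReport, path) -> None:
    """Plot the series with its centre line, any sigma limits, and the
    points that triggered a rule marked in red."""
    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(1, len(values) + 1)
    ax.plot(x, values, "o-", color="steelblue", ms=4)
    ax.axhline(report.centre, color="black", lw=1, label=f"centre ({report.centre_source})")
    if report.sd is not None:
        for k in (1, 2, 3):
            style = {"color": "grey", "lw": 0.8, "ls": ":" if k < 3 else "--"}
            ax.axhline(report.centre + k * report.sd, **style)
            ax.axhline(report.centre - k * report.sd, **style)
    flagged = sorted(
        {
            i
            for res in report.report.results.values()
            for i in res.evidence.get("indices", [])
            if res.signal
        }
    )
    if flagged:
        ax.plot(x[flagged], np.asarray(values)[flagged], "o", color="crimson", ms=6)
    ax.set_xlabel("observation")
    ax.set_ylabel("value")
    ax.set_title(report.verdict)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_likelihood_ratios(table: pd.DataFrame, path) -> None:
    """Dot plot of LR+ and LR− per rule set and series length, on a log
    scale with the conventional decision bands (LR+ > 10, LR− < 0.1)."""
    fig, ax = plt.subplots(figsize=(7, 5))
    rulesets = list(dict.fromkeys(table["ruleset"]))
    lengths = sorted(table["length"].unique())
    markers = dict(zip(lengths, ("o", "s", "^", "D", "v")))
    ypos = {rs: i for i, rs in enumerate(rulesets)}
    for _, row in table.iterrows():
        y = ypos[row["ruleset"]]
        m = markers[row["length"]]
        ax.plot(row["lr_pos"], y + 0.12, m, color="forestgreen", ms=6)
        ax.plot(row["lr_neg"], y - 0.12, m, color="firebrick", ms=6)
    ax.axvline(10, color="forestgreen", lw=0.8, ls="--")
    ax.axvline(0.1, color="firebrick", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(range(len(rulesets)), rulesets)
    ax.set_xlabel("likelihood ratio (green: LR+, red: LR−)")
    handles = [
        plt.Line2D([], [], marker=markers[n], ls="", color="grey", label=f"n = {n}")
        for n in lengths
    ]
    ax.legend(handles=handles, loc="center right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
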