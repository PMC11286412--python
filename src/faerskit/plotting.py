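"""Plain matplotlib plots for screening and descriptive outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_forest(df: pd.DataFrame, ax=None):
    """Forest plot of ROR point estimates with 95% CIs on a log axis.

    Expects the per-drug/per-category frame (columns drug, ror, ci_lower,
    ci_upper, signal); undefined RORs are skipped.
    """
    plot_df = df.dropna(subset=["ror"]).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.35 * max(len(plot_df), 4) + 1.5))
    y = range(len(plot_df))
    colors = ["tab:red" if s else "tab:gray" for s in plot_df["signal"]]
    ax.hlines(y, plot_df["ci_lower"], plot_df["ci_upper"], color=colors, lw=1.5)
    ax.scatter(plot_df["ror"], y, color=colors, zorder=3, s=18)
    ax.axvline(1.0, color="k", ls="--", lw=0.8)
    ax.set_xscale("log")
    ax.set_yticks(list(y), plot_df["drug"])
    ax.set_xlabel("ROR (95% CI), log scale")
    ax.figure.tight_layout()
    return ax


def plot_yearly_counts(counts: dict, ax=None):
    """Line plot of report counts per year (the "NA" stratum is dropped)."""
    items = [(k, v) for k, v in counts.items() if not isinstance(k, str)]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot([k for k, _ in items], [v for _, v in items], marker="o")
    ax.set_xlabel("year")
    ax.set_ylabel("reports")
    ax.figure.tight_layout()
    return ax


def plot_outcome_bars(df: pd.DataFrame, ax=None):
    """Bar chart of the most-severe-outcome distribution."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(df["outcome"], df["count"], color="tab:blue")
    ax.set_ylabel("reports")
    ax.figure.tight_layout()
    return ax
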