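"""Optional matplotlib figures mirroring the standard sweep/coverage layouts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_sweep", "plot_controls", "plot_abundance_curve"]


def plot_sweep(points: pd.DataFrame, path) -> None:
    """Dual-axis sweep figure: peptide counts (bars) and binder percentage (line)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = range(len(points))
    labels = [f"{100 * a:g}%" for a in points["fdr_threshold"]]
    ax.bar([i - 0.25 for i in x], points["n_total_peptides"], 0.25, color="0.75", label="all peptides")
    ax.bar(x, points["n_9_11"], 0.25, color="0.5", label="9–11mers")
    ax.bar([i + 0.25 for i in x], points["n_binders"], 0.25, color="0.25", label="predicted binders")
    ax.set_xticks(list(x), labels)
    ax.set_xlabel("peptide FDR threshold")
    ax.set_ylabel("unique peptides")
    ax.legend(loc="upper left", fontsize=8)
    ax2 = ax.twinx()
    ax2.plot(list(x), points["pct_binders"], "o-", color="tab:red")
    ax2.set_ylabel("% binders of 9–11mers", color="tab:red")
    ax2.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_controls(table: pd.DataFrame, path) -> None:
    """Matched vs scrambled vs mismatch binder fractions across thresholds."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = [100 * a for a in table["fdr_threshold"]]
    ax.plot(x, 100 * table["matched_fraction"], "o-", label="matched HLA")
    ax.plot(x, 100 * table["scrambled_fraction"], "s--", label="scrambled")
    if "mismatch_fraction" in table.columns:
        ax.plot(x, 100 * table["mismatch_fraction"], "^--", label="mismatch HLA")
    if "chance_rate_matched" in table.columns:
        ax.axhline(100 * table["chance_rate_matched"].iloc[0], color="0.6", lw=0.8, label="chance (MC)")
    ax.set_xscale("log")
    ax.set_xlabel("peptide FDR threshold (%)")
    ax.set_ylabel("% predicted binders")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_abundance_curve(curve: pd.DataFrame, path) -> None:
    """Cumulative hit percentage along the abundance-ranked proteome."""
    fig, ax = plt.subplots(figsize=(6, 4))
    n = len(curve)
    x = 100.0 * curve["rank"] / n
    for col in curve.columns:
        if col.startswith("cumulative_pct_"):
            ax.plot(x, curve[col], label=col.removeprefix("cumulative_pct_"))
    ax.plot([0, 100], [0, 100], "k--", lw=0.8, label="uniform (diagonal)")
    ax.set_xlabel("% of abundance-ranked proteins (high → low)")
    ax.set_ylabel("% of immunopeptidome source proteins")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
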