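"""Summary tables and figures comparing conditions and methods."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .stats import MethylationResults, compare_conditions

__all__ = ["decrease_table", "plot_estimates", "plot_bootstrap_distributions"]


def decrease_table(results: list[MethylationResults],
                   reference_condition: str = "untreated") -> pd.DataFrame:
    """Per-condition estimates plus the decrease from the reference.

    One row per (sample_id, condition); the ``decrease`` column is the
    reference condition's point estimate minus this condition's, with a
    paired-bootstrap CI when both fits carry replicate streams of equal
    length.
    """
    ref = {r.sample_id: r for r in results
           if r.condition == reference_condition}
    rows = []
    for r in results:
        row = {
            "sample_id": r.sample_id,
            "condition": r.condition,
            "pct_methylation": r.pct_methylation,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "decrease": float("nan"),
            "decrease_ci_low": float("nan"),
            "decrease_ci_high": float("nan"),
        }
        base = ref.get(r.sample_id)
        if base is not None and r.condition != reference_condition:
            cmp_ = compare_conditions(base, r)
            row["decrease"] = cmp_.difference
            if cmp_.ci_low is not None:
                row["decrease_ci_low"] = cmp_.ci_low
                row["decrease_ci_high"] = cmp_.ci_high
        rows.append(row)
    return pd.DataFrame(rows)


def plot_estimates(results: list[MethylationResults], path=None):
    """Point estimates with bootstrap CIs, one marker per sample/condition."""
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = [f"{r.sample_id}\n{r.condition}" for r in results]
    x = range(len(results))
    y = [r.pct_methylation for r in results]
    lo = [r.pct_methylation - r.ci_low for r in results]
    hi = [r.ci_high - r.pct_methylation for r in results]
    ax.errorbar(x, y, yerr=[lo, hi], fmt="o", capsize=4)
    ax.set_xticks(list(x), labels)
    ax.set_ylabel("% CpG methylation")
    ax.axhline(0, color="0.7", lw=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_bootstrap_distributions(results: list[MethylationResults], path=None):
    """Box plots of the bootstrap replicate distributions per estimate."""
    with_reps = [r for r in results if r.bootstrap_replicates is not None]
    fig, ax = plt.subplots(figsize=(6, 4))
    if with_reps:
        ax.boxplot([r.bootstrap_replicates for r in with_reps],
                   tick_labels=[f"{r.sample_id}\n{r.condition}"
                                for r in with_reps],
                   showfliers=False)
    ax.set_ylabel("% CpG methylation (bootstrap replicates)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
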