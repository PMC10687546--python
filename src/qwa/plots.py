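"""Optional figure mirrors: monthly correlation bars and three-phase
intra-annual profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_monthly_correlations(correlations: pd.DataFrame, path: str) -> None:
    """Bar chart of monthly Pearson correlations per climate variable;
    significant bars (bootstrap CI excluding zero) are starred."""
    variables = correlations["variable"].unique()
    fig, axes = plt.subplots(len(variables), 1, figsize=(10, 2.6 * len(variables)), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, var in zip(axes, variables):
        sub = correlations[correlations["variable"] == var]
        x = np.arange(len(sub))
        ax.bar(x, sub["r"], color=np.where(sub["significant"], "#b2182b", "#888888"))
        ax.vlines(x, sub["ci_low"], sub["ci_high"], color="black", lw=0.8)
        for xi, (r, sig) in enumerate(zip(sub["r"], sub["significant"])):
            if sig:
                ax.annotate("*", (xi, r), ha="center", va="bottom" if r >= 0 else "top")
        ax.axhline(0, color="black", lw=0.5)
        ax.set_ylabel(f"r ({var})")
        ax.set_xticks(x, sub["month"], rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phase_profiles(profiles: dict, path: str) -> None:
    """Before/during/after intra-annual profiles per group, mean with 95%
    band, one panel per group."""
    groups = sorted({g for g, _ in profiles})
    colors = {"before": "#1b7837", "during": "#b2182b", "after": "#2166ac"}
    fig, axes = plt.subplots(1, len(groups), figsize=(5.2 * len(groups), 3.6), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, group in zip(axes, groups):
        for phase in ("before", "during", "after"):
            gp = profiles.get((group, phase))
            if gp is None:
                continue
            ax.plot(gp.sectors, gp.mean, color=colors[phase], label=phase)
            ax.fill_between(gp.sectors, gp.low, gp.high, color=colors[phase], alpha=0.2)
        ax.set_title(group)
        ax.set_xlabel("ring sector (relative position x 100)")
    axes[0].set_ylabel("normalized trait value")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
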