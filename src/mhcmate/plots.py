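"""Publication-style figures: randomization histograms and choice curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .randomization import RandomizationResult

__all__ = ["plot_randomization", "plot_choice_curve"]


def plot_randomization(result: RandomizationResult, path: str | Path) -> None:
    """Histogram of simulated index means with the observed mean dashed."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.hist(result.simulated_means, bins=40, color="steelblue", alpha=0.85)
    ax.axvline(result.observed_mean, color="black", linestyle="--", lw=1.5)
    ax.set_xlabel(f"mean {result.index_name} over couples")
    ax.set_ylabel("frequency")
    ax.set_title(
        f"{result.index_name}: p = {result.p_two_tailed:.4g} "
        f"(B = {result.B}, n = {result.n_couples})",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_choice_curve(
    curve: pd.DataFrame,
    path: str | Path,
    table: pd.DataFrame | None = None,
    index_name: str = "MHC_INDEX",
) -> None:
    """Predicted choice probability vs index with the 95% bootstrap band."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.fill_between(curve["index"], curve["lo"], curve["hi"], alpha=0.3, color="steelblue")
    ax.plot(curve["index"], curve["prob"], color="steelblue", lw=2)
    if table is not None:
        ax.plot(
            table["MHC_INDEX"], table["CHOSEN"],
            linestyle="none", marker="o", ms=3, alpha=0.2, color="gray",
        )
    ax.set_xlabel(index_name)
    ax.set_ylabel("probability of being chosen")
    ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
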