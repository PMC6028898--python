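"""Summary figures for the model-grid results."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_rmse_heatmap", "plot_error_histograms", "plot_obs_vs_pred"]


def plot_rmse_heatmap(results: pd.DataFrame, path: str | Path) -> Path:
    """Phenophase x technique RMSE heatmap, one panel per predictor group."""
    groups = sorted(results["group"].unique())
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 4), squeeze=False)
    for ax, group in zip(axes[0], groups):
        sub = results[results["group"] == group]
        pivot = sub.pivot_table(index="phenophase_id", columns="technique", values="rmse")
        im = ax.imshow(pivot.to_numpy(), cmap="viridis_r", aspect="auto")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45)
        ax.set_yticks(range(len(pivot.index)), pivot.index)
        ax.set_title(group)
        fig.colorbar(im, ax=ax, label="RMSE (days)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_error_histograms(results, path: str | Path, techniques: Sequence[str] = ("gbm", "lasso")) -> Path:
    """Prediction-error distributions per phenophase for selected techniques."""
    chosen = [r for r in results if r.technique in techniques]
    if not chosen:  # none of the preferred techniques present: plot everything
        chosen = list(results)
    phens = sorted({r.phenophase_id for r in chosen})
    n = max(len(phens), 1)
    fig, axes = plt.subplots(n, 1, figsize=(6, 2.2 * n), squeeze=False)
    for ax, phen in zip(axes[:, 0], phens):
        for r in chosen:
            if r.phenophase_id == phen:
                ax.hist(r.errors, bins=25, alpha=0.5, label=f"{r.technique}/{r.group}")
        ax.set_title(phen)
        ax.set_xlabel("predicted - observed (days)")
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_obs_vs_pred(results, path: str | Path, technique: str = "gbm") -> Path:
    """Observed vs predicted onset DOY scatter for one technique."""
    chosen = [r for r in results if r.technique == technique]
    if not chosen:
        chosen = list(results)
    phens = sorted({r.phenophase_id for r in chosen})
    n = max(len(phens), 1)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.4), squeeze=False)
    for ax, phen in zip(axes[0], phens):
        for r in chosen:
            if r.phenophase_id == phen:
                ax.scatter(r.predictions["observed"], r.predictions["predicted"], s=6, alpha=0.5, label=r.group)
        lims = ax.get_xlim()
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_title(phen, fontsize=8)
        ax.set_xlabel("observed DOY")
        ax.set_ylabel("predicted DOY")
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
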