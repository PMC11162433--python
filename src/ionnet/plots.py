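"""Report figures: per-element radar plots and prediction scatter grids."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["radar_plot", "scatter_grid"]


def radar_plot(series_by_model: dict[str, pd.Series], path: str | Path, title: str = "") -> None:
    """One radar axis per task; one polygon per model."""
    first = next(iter(series_by_model.values()))
    labels = list(first.index)
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    for name, series in series_by_model.items():
        vals = series.reindex(labels).to_numpy(dtype=float)
        vals = np.nan_to_num(vals)
        ax.plot(np.r_[angles, angles[:1]], np.r_[vals, vals[:1]], label=name)
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_title(title)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def scatter_grid(
    pred: np.ndarray,
    obs: np.ndarray,
    task_names,
    path: str | Path,
    n_panels: int = 15,
    ranking: pd.Series | None = None,
) -> None:
    """Scatter panels of predicted vs observed, best-ranked tasks first."""
    task_names = list(task_names)
    if ranking is not None:
        order = list(ranking.sort_values(ascending=False).index)
        idx = [task_names.index(t) for t in order[:n_panels] if t in task_names]
    else:
        idx = list(range(min(n_panels, len(task_names))))
    ncol = 5
    nrow = int(np.ceil(len(idx) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for ax, t in zip(axes.ravel(), idx):
        ok = np.isfinite(pred[:, t]) & np.isfinite(obs[:, t])
        ax.axis("on")
        ax.scatter(obs[ok, t], pred[ok, t], s=6, alpha=0.5)
        ax.set_title(task_names[t], fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
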