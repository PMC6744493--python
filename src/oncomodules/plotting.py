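"""Minimal figures: consensus heatmaps and Kaplan–Meier curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .survival import kaplan_meier  # noqa: E402


def consensus_heatmap(matrix: np.ndarray, labels: pd.Series | None,
                      path: str | Path, title: str = "") -> None:
    """Heatmap of a consensus matrix, rows ordered by cluster label."""
    order = np.arange(matrix.shape[0])
    if labels is not None:
        order = np.argsort(labels.to_numpy(), kind="stable")
    M = matrix[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(M, cmap="Blues", vmin=0, vmax=1, interpolation="nearest")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_plot(records: pd.DataFrame, groups: pd.Series,
            path: str | Path, title: str = "") -> None:
    """Step survival curves, one per patient group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for g in sorted(groups.unique()):
        table = kaplan_meier(records.loc[groups.index[groups == g]])
        times = np.concatenate([[0.0], table["time"].to_numpy()])
        surv = np.concatenate([[1.0], table["survival"].to_numpy()])
        ax.step(times, surv, where="post", label=f"group {g}")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival fraction")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
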