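"""Scatter plots and tabular run summaries.

Plots follow the method's visual convention: compact clusters coloured and
numbered 1..K in the legend, mean-stage outliers as red dots labelled "-1",
std-stage calls as "+" markers labelled "-2", axes named after the two
strains. Plots are a byproduct and are asserted only structurally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dbscan import NOISE, ClusterLabeling
from .pipeline import Batch, BatchStats, DifferentialCallSet
from .preprocess import AggregatedProfile


@dataclass
class BatchPlotSpec:
    space: str = "mean"  # "mean" | "std"
    batch_index: int = 0
    path: str | Path = "batch.png"
    image_format: str = "png"

    def __post_init__(self) -> None:
        if self.space not in ("mean", "std"):
            raise ValueError(f"unknown space {self.space!r}")


def plot_batch(
    profile: AggregatedProfile,
    batch: Batch,
    labeling: ClusterLabeling,
    std_flags,
    spec: BatchPlotSpec,
) -> Path:
    """Render one batch in mean- or std-space; returns the written path."""
    if len(labeling.labels) != len(batch):
        raise ValueError("labeling is not aligned to the batch")
    points = (profile.mean_points() if spec.space == "mean" else profile.std_points())[
        batch.gene_positions
    ]
    std_set = set(np.asarray(list(std_flags), dtype=int).tolist()) if len(std_flags) else set()
    is_std = np.array([pos in std_set for pos in batch.gene_positions])
    labels = labeling.labels

    fig, ax = plt.subplots(figsize=(6, 6))
    cmap = plt.get_cmap("tab20")
    for k in range(1, labeling.n_clusters + 1):
        mask = (labels == k) & ~is_std
        ax.scatter(points[mask, 0], points[mask, 1], s=12, color=cmap((k - 1) % 20), label=str(k))
    noise_mask = labels == NOISE
    if noise_mask.any():
        ax.scatter(points[noise_mask, 0], points[noise_mask, 1], s=14, color="red", label="-1")
    if is_std.any():
        ax.scatter(
            points[is_std, 0], points[is_std, 1], s=40, marker="+", color="black", label="-2"
        )
    quantity = "mean" if spec.space == "mean" else "std"
    ax.set_xlabel(f"{quantity} log expression, {profile.strain_order[0]}")
    ax.set_ylabel(f"{quantity} log expression, {profile.strain_order[1]}")
    ax.set_title(f"batch {batch.index}")
    ax.legend(loc="best", fontsize="small")
    path = Path(spec.path)
    fig.savefig(path, format=spec.image_format, dpi=120)
    plt.close(fig)
    return path


def legend_entries(
    labeling: ClusterLabeling, std_flags
) -> list[str]:
    """The legend labels :func:`plot_batch` would draw, for structural checks."""
    entries = [str(k) for k in range(1, labeling.n_clusters + 1)]
    if np.any(labeling.labels == NOISE):
        entries.append("-1")
    if len(std_flags):
        entries.append("-2")
    return entries


def summarize_run(
    calls: DifferentialCallSet, per_batch_stats: list[BatchStats]
) -> pd.DataFrame:
    """Per-batch counts plus a totals row; totals match the call set."""
    rows = [
        {
            "batch": s.batch_index,
            "n_genes": s.n_genes,
            "n_clusters": s.n_clusters,
            "n_mean_outliers": s.n_mean_outliers,
            "n_std_outliers": s.n_std_outliers,
        }
        for s in per_batch_stats
    ]
    df = pd.DataFrame(
        rows, columns=["batch", "n_genes", "n_clusters", "n_mean_outliers", "n_std_outliers"]
    )
    totals = {
        "batch": "total",
        "n_genes": int(df["n_genes"].sum()) if len(df) else 0,
        "n_clusters": int(df["n_clusters"].sum()) if len(df) else 0,
        "n_mean_outliers": int(df["n_mean_outliers"].sum()) if len(df) else 0,
        "n_std_outliers": int(df["n_std_outliers"].sum()) if len(df) else 0,
    }
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def write_summary(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
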