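"""Qualitative figures: agent trajectories, entropy distributions per design
cell, and embedding-dimension means per testing mode."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_trajectory", "plot_entropy_box", "plot_embedding_means"]


def plot_trajectory(trace, last_seconds: float | None = None, path=None):
    """Agent path(s) in the arena; optionally only the trailing window
    (the interesting part of an evolved behavior is usually the attractor
    reached after the transient)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    sel = slice(None)
    if last_seconds is not None:
        dt = trace.time[1] - trace.time[0]
        sel = slice(-int(round(last_seconds / dt)), None)
    for a in range(trace.n_agents):
        ax.plot(trace.pose[sel, a, 0], trace.pose[sel, a, 1],
                label=f"agent {a + 1}")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_aspect("equal")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_entropy_box(table, path=None):
    """Box plot of best-of-run entropies per design cell."""
    fig, ax = plt.subplots(figsize=(6, 4))
    cells = sorted(table.groupby(["condition", "model"]).groups)
    data = [table[(table["condition"] == c) & (table["model"] == m)]
            ["entropy"].to_numpy() for c, m in cells]
    ax.boxplot(data, tick_labels=[f"{c}\n{m}-neuron" for c, m in cells])
    ax.set_ylabel("normalized neural entropy")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_embedding_means(embedding, path=None):
    """Mean embedding dimension per (condition, model, mode) cell."""
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = embedding.groupby(["condition", "model", "mode"])["m"]
    labels, means = [], []
    for (c, m, mode), vals in groups:
        labels.append(f"{mode}\n{c} {m}n")
        means.append(vals.mean())
    x = np.arange(len(labels))
    ax.scatter(x, means, marker="D", color="gray")
    ax.set_xticks(x, labels, fontsize=8)
    ax.set_ylabel("mean embedding dimension")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
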