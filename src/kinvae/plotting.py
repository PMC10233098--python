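"""Matplotlib views of the latent analysis (scatter, density maps, curves)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

GROUP_COLORS = {0: "tab:red", 1: "tab:blue"}  # TD red, ASD blue
GROUP_NAMES = {0: "TD", 1: "ASD"}


def plot_latent_scatter(projection, level: str = "task", path: str | Path | None = None):
    """Latent positions of task rows (or participant means), colored by group."""
    frame = (projection.task_points if level == "task"
             else projection.participant_points)
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in (0, 1):
        sub = frame[frame["group"] == g]
        ax.scatter(sub["z0"], sub["z1"], s=12, alpha=0.6,
                   c=GROUP_COLORS[g], label=GROUP_NAMES[g])
    ax.set_xlabel("z0")
    ax.set_ylabel("z1")
    ax.set_title(f"Latent space ({level} level)")
    ax.legend()
    return _finish(fig, path)


def plot_loss_history(history, path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(5, 4))
    for col in ("recon", "kl", "pred", "total"):
        ax.plot(history["epoch"], history[col], label=col)
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.set_yscale("log")
    ax.legend()
    return _finish(fig, path)


def plot_density_map(density, x_edges, y_edges, projection=None,
                     title: str = "", path: str | Path | None = None):
    """Perturbation density over the latent plane, class points overlaid."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.pcolormesh(x_edges, y_edges, density.T, cmap="Greys")
    if projection is not None:
        for g in (0, 1):
            sub = projection.task_points[projection.task_points["group"] == g]
            ax.scatter(sub["z0"], sub["z1"], s=6, alpha=0.4, c=GROUP_COLORS[g])
    ax.set_title(title)
    ax.set_xlabel("z0")
    ax.set_ylabel("z1")
    return _finish(fig, path)


def plot_response_curve(curve, path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.grid, curve.p_td, c=GROUP_COLORS[0], label="p(TD)")
    ax.fill_between(curve.grid, curve.p_td - curve.sd_td,
                    curve.p_td + curve.sd_td, color=GROUP_COLORS[0], alpha=0.2)
    ax.plot(curve.grid, curve.p_asd, c=GROUP_COLORS[1], label="p(ASD)")
    ax.fill_between(curve.grid, curve.p_asd - curve.sd_asd,
                    curve.p_asd + curve.sd_asd, color=GROUP_COLORS[1], alpha=0.2)
    ax.set_xlabel(curve.feature_name)
    ax.set_ylabel("assignment probability")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    return _finish(fig, path)


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
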