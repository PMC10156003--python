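"""Plotting helpers for quality control (matplotlib, Agg backend)."""

from __future__ import annotations

import numpy as np


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_simplified_image(img, path) -> None:
    """One panel per channel of a simplified image."""
    plt = _mpl()
    n = len(img.channel_names)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), squeeze=False)
    for ax, name in zip(axes[0], img.channel_names):
        ax.imshow(img.channel(name), vmin=0, vmax=1, cmap="magma")
        ax.set_title(name)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fit_trace(result, path) -> None:
    """Best (blue) and mean (red) objective per GA generation."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    gens = np.arange(len(result.trace_best))
    ax.plot(gens, result.trace_mean, color="red", label="average fit")
    ax.plot(gens, result.trace_best, color="blue", label="best fit")
    ax.set_xlabel("generation")
    ax.set_ylabel("ensemble distance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_side_by_side(target_img, best_img, path) -> None:
    """Target vs best-fit simplified images, channel by channel."""
    plt = _mpl()
    n = len(target_img.channel_names)
    fig, axes = plt.subplots(2, n, figsize=(3 * n, 6), squeeze=False)
    for row, (img, label) in enumerate(((target_img, "target"), (best_img, "best fit"))):
        for col, name in enumerate(img.channel_names):
            ax = axes[row][col]
            ax.imshow(img.channel(name), vmin=0, vmax=1, cmap="magma")
            ax.set_title(f"{label}: {name}")
            ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
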