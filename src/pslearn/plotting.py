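"""Plots: the data-fraction curves and Grad-CAM overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_SAVE_KW = {"dpi": 110, "metadata": {"Date": None}}  # no timestamp -> reproducible bytes


def plot_fraction_curves(results: pd.DataFrame, path, metrics=("accuracy", "sensitivity")) -> None:
    """Mean metric vs labeled fraction, one curve per condition, ±1 sd band."""
    fig, axes = plt.subplots(1, len(metrics), figsize=(4.2 * len(metrics), 3.4), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        sub = results[results["metric"] == metric]
        for cond, style in (("with_ps", "o-"), ("without_ps", "s--")):
            g = sub[sub["condition"] == cond].groupby("fraction")["value"]
            mean, sd = g.mean(), g.std().fillna(0.0)
            ax.errorbar(mean.index * 100, mean.values, yerr=sd.values, fmt=style,
                        capsize=3, label=cond.replace("_", " "))
        ax.set_xlabel("labeled training data (%)")
        ax.set_ylabel(metric)
        ax.set_ylim(0.0, 1.02)
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), **_SAVE_KW)
    plt.close(fig)


def gradcam_overlay(pixels: np.ndarray, cam: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Blend a heat map onto a grayscale slice; returns an (H, W, 3) uint8 image.

    Activated regions use a red-to-yellow colormap ('autumn'): red = weak,
    yellow = strong activation.
    """
    lo, hi = float(pixels.min()), float(pixels.max())
    gray = (pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(pixels)
    rgb = np.stack([gray] * 3, axis=-1)
    heat = matplotlib.colormaps["autumn"](cam)[..., :3]
    a = np.where(cam >= threshold, 0.5 * cam, 0.0)[..., None]
    out = (1 - a) * rgb + a * heat
    return (np.clip(out, 0, 1) * 255).astype(np.uint8)


def save_gradcam_panel(pixels: np.ndarray, cam: np.ndarray, path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(6.4, 3.2))
    axes[0].imshow(pixels, cmap="gray")
    axes[0].set_title("input")
    axes[1].imshow(gradcam_overlay(pixels, cam))
    axes[1].set_title("Grad-CAM")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(Path(path), **_SAVE_KW)
    plt.close(fig)
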