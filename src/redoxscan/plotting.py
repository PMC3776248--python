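"""Basic plotting helpers: index maps and fitted Fp-ratio histograms.

These are working diagnostics, not publication renderings; color maps and
layout are deliberately plain.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .histofit import BiGaussianResults
from .indices import Histogram, RedoxMaps

__all__ = ["plot_histogram_fit", "plot_index_map"]


def plot_histogram_fit(
    hist: Histogram,
    fit: BiGaussianResults | None = None,
    ax=None,
    title: str | None = None,
):
    """Histogram dots with the fitted bi-Gaussian curve and its two components."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(hist.bin_centers, hist.counts, "k.", ms=4, label="pixels")
    if fit is not None:
        xx = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 400)
        ax.plot(xx, fit.predict(xx), "r-", lw=1.2, label="bi-Gaussian")
        a1, a2, b1, b2, c1, c2 = fit.params
        ax.plot(xx, a1 * np.exp(-((xx - b1) ** 2) / (2 * c1**2)), "g--", lw=0.8)
        ax.plot(xx, a2 * np.exp(-((xx - b2) ** 2) / (2 * c2**2)), "m--", lw=0.8)
    ax.set_xlabel(hist.index)
    ax.set_ylabel("pixel count")
    if title:
        ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7)
    return ax


def plot_index_map(maps: RedoxMaps, index: str = "fp_ratio", ax=None):
    """Pseudo-color map of one index; undefined pixels render blank."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    arr = getattr(maps, index if index not in ("fp", "nadh") else f"{index}_um")
    kwargs = {"vmin": 0.0, "vmax": 1.0} if index == "fp_ratio" else {}
    im = ax.imshow(arr, interpolation="nearest", **kwargs)
    plt.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(f"{index} ({maps.group} {maps.animal_id}, {maps.depth_um:.0f} um)", fontsize=8)
    return ax


def save_figure(path: str | Path) -> Path:
    path = Path(path)
    plt.tight_layout()
    plt.savefig(path, dpi=120)
    plt.close("all")
    return path
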