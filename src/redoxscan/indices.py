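"""Redox-index maps, per-section summaries and histograms.

Five indices are computed pixelwise on valid pixels: the nominal Fp and NADH
concentrations (uM), the Fp redox ratio Fp/(Fp + NADH) in [0, 1], and the
two reciprocal ratios Fp/NADH and NADH/Fp.  Higher Fp ratio means a more
oxidized mitochondrial redox state.  Pixels where a ratio is undefined
(zero denominator) are dropped from that index only and counted in the
exclusion log; excluded pixels are NaN sentinels, never zero-filled.

All per-section statistics are means/SDs of the pixelwise values (the
histograms are pixelwise), never ratios of channel means — so the section
mean of Fp/(Fp+NADH) is *not* mean(Fp)/(mean(Fp)+mean(NADH)).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibratedSection
from .scan_io import INDEX_NAMES, SectionSummary

__all__ = [
    "RedoxMaps",
    "Histogram",
    "compute_redox_maps",
    "section_summary",
    "histogram_of",
    "DEFAULT_BINS",
]

DEFAULT_BINS = 64


@dataclass
class RedoxMaps:
    """The five index maps for one section; invalid pixels are NaN."""

    fp_um: np.ndarray
    nadh_um: np.ndarray
    fp_ratio: np.ndarray
    fp_over_nadh: np.ndarray
    nadh_over_fp: np.ndarray
    valid_mask: np.ndarray
    exclusions: dict[str, int]
    animal_id: str
    group: str
    depth_um: float

    def values(self, index: str) -> np.ndarray:
        """Finite pixel values of one index (1-D)."""
        if index not in INDEX_NAMES:
            raise KeyError(f"unknown index {index!r}")
        arr = getattr(self, index if index not in ("fp", "nadh") else f"{index}_um")
        return arr[np.isfinite(arr)]


def compute_redox_maps(cal: CalibratedSection) -> RedoxMaps:
    """Compute the five index maps on the valid pixels of a calibrated section.

    Pixels with ``fp + nadh == 0`` are undefined for the Fp ratio; pixels
    with ``nadh == 0`` (resp. ``fp == 0``) are undefined for Fp/NADH
    (resp. NADH/Fp).  Such pixels stay NaN in the affected map and are
    tallied in ``exclusions``.
    """
    valid = np.asarray(cal.valid_mask, dtype=bool)
    if not valid.any():
        raise ValueError("empty validity mask")
    shape = cal.fp_um.shape

    def masked(arr: np.ndarray) -> np.ndarray:
        out = np.full(shape, np.nan)
        out[valid] = arr[valid]
        return out

    fp = masked(cal.fp_um)
    nadh = masked(cal.nadh_um)
    total = fp + nadh

    with np.errstate(divide="ignore", invalid="ignore"):
        fp_ratio = np.where(total > 0, fp / total, np.nan)
        fp_over_nadh = np.where(nadh > 0, fp / nadh, np.nan)
        nadh_over_fp = np.where(fp > 0, nadh / fp, np.nan)

    n_valid = int(valid.sum())
    exclusions = {
        "fp_ratio_zero_total": int(n_valid - np.isfinite(fp_ratio).sum()),
        "fp_over_nadh_zero_nadh": int(n_valid - np.isfinite(fp_over_nadh).sum()),
        "nadh_over_fp_zero_fp": int(n_valid - np.isfinite(nadh_over_fp).sum()),
    }
    return RedoxMaps(
        fp_um=fp,
        nadh_um=nadh,
        fp_ratio=fp_ratio,
        fp_over_nadh=fp_over_nadh,
        nadh_over_fp=nadh_over_fp,
        valid_mask=valid,
        exclusions=exclusions,
        animal_id=cal.animal_id,
        group=cal.group,
        depth_um=cal.depth_um,
    )


def section_summary(maps: RedoxMaps) -> SectionSummary:
    """Arithmetic mean and sample SD (ddof=1) of each index over its defined pixels."""
    n_valid = int(maps.valid_mask.sum())
    if n_valid < 2:
        raise ValueError(f"need >= 2 valid pixels, got {n_valid}")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for idx in INDEX_NAMES:
        vals = maps.values(idx)
        if vals.size < 2:
            mean[idx] = float("nan")
            sd[idx] = float("nan")
        else:
            mean[idx] = float(vals.mean())
            sd[idx] = float(vals.std(ddof=1))
    return SectionSummary(
        animal_id=maps.animal_id,
        group=maps.group,
        depth_um=maps.depth_um,
        n_pixels=n_valid,
        mean=mean,
        sd=sd,
    )


@dataclass
class Histogram:
    """Binned pixel counts of one index for one section."""

    bin_edges: np.ndarray
    counts: np.ndarray
    index: str
    n_pixels: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "count": self.counts})

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        return path


def histogram_of(
    maps: RedoxMaps,
    index: str = "fp_ratio",
    bins: int = DEFAULT_BINS,
    support: tuple[float, float] | None = None,
) -> Histogram:
    """Histogram the defined pixels of one index.

    The Fp-ratio support is fixed to [0, 1] by default so histograms are
    comparable across sections; other indices use their data range.  The
    counts always sum to the number of contributing pixels.
    """
    if bins <= 0:
        raise ValueError(f"bin count must be positive, got {bins}")
    vals = maps.values(index)
    if vals.size < 2:
        raise ValueError(f"need >= 2 defined pixels for index {index!r}")
    if support is None:
        support = (0.0, 1.0) if index == "fp_ratio" else (float(vals.min()), float(vals.max()))
    lo, hi = support
    if not hi > lo:
        hi = lo + 1.0  # all-equal values: widen to a unit support
    counts, edges = np.histogram(np.clip(vals, lo, hi), bins=bins, range=(lo, hi))
    return Histogram(bin_edges=edges, counts=counts, index=index, n_pixels=int(vals.size))
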