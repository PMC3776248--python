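"""End-to-end analysis: calibrate -> index maps -> summaries, histograms, fits.

These functions are the programmatic spine that the command-line interface
wraps; tests and simulations call them directly on in-memory sections so no
disk round-trip is needed.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .calibrate import DEFAULT_SNR_THRESHOLD, calibrate_section
from .histofit import BiGaussianResults, FitError, fit_bi_gaussian, fits_to_frame
from .indices import DEFAULT_BINS, Histogram, compute_redox_maps, histogram_of, section_summary
from .scan_io import ScanSection, SectionSummary, StudyManifest, summaries_to_frame

__all__ = ["AnalysisOptions", "SectionAnalysis", "analyze_section", "analyze_study", "provenance_record"]


@dataclass(frozen=True)
class AnalysisOptions:
    """Analysis knobs, all of which are recorded in run provenance."""

    snr_threshold: float = DEFAULT_SNR_THRESHOLD
    bins: int = DEFAULT_BINS
    fit_histograms: bool = True
    fit_weighting: str = "none"
    fit_starts: int = 5

    def validate(self) -> None:
        if self.snr_threshold < 0:
            raise ValueError("SNR threshold must be non-negative")
        if self.bins <= 0:
            raise ValueError("bin count must be positive")


@dataclass
class SectionAnalysis:
    """Everything computed for one section."""

    summary: SectionSummary
    histogram: Histogram
    fit: BiGaussianResults | None
    calibration_record: dict
    exclusions: dict[str, int]


def analyze_section(
    section: ScanSection,
    standard_concentrations_um: Mapping[str, float],
    options: AnalysisOptions = AnalysisOptions(),
) -> SectionAnalysis:
    """Calibrate one section and compute its summary, histogram and fit."""
    options.validate()
    cal = calibrate_section(
        section, standard_concentrations_um, snr_threshold=options.snr_threshold
    )
    maps = compute_redox_maps(cal)
    summary = section_summary(maps)
    hist = histogram_of(maps, "fp_ratio", bins=options.bins)
    fit: BiGaussianResults | None = None
    if options.fit_histograms:
        try:
            fit = fit_bi_gaussian(
                hist, weighting=options.fit_weighting, n_starts=options.fit_starts
            )
        except FitError:
            fit = None  # recorded as a missing row; failures must not kill a study
    return SectionAnalysis(
        summary=summary,
        histogram=hist,
        fit=fit,
        calibration_record=cal.calibration_record,
        exclusions=maps.exclusions,
    )


def analyze_study(
    sections: Sequence[ScanSection],
    manifest: StudyManifest,
    options: AnalysisOptions = AnalysisOptions(),
) -> tuple[pd.DataFrame, pd.DataFrame, list[SectionAnalysis]]:
    """Analyze every section of a study.

    Returns the per-section summary table, the per-section bi-Gaussian fit
    table (possibly empty when fitting is disabled or fails everywhere) and
    the full per-section analyses.
    """
    analyses = [
        analyze_section(s, manifest.standard_concentrations_um, options) for s in sections
    ]
    summary_frame = summaries_to_frame([a.summary for a in analyses])
    fitted = [(a, s) for a, s in zip(analyses, sections) if a.fit is not None]
    fits_frame = fits_to_frame(
        [a.fit for a, _ in fitted],
        meta=[
            {"animal_id": s.animal_id, "group": s.group, "depth_um": s.depth_um}
            for _, s in fitted
        ],
    )
    return summary_frame, fits_frame, analyses


def provenance_record(options: AnalysisOptions, seed: int | None = None, extra: dict | None = None) -> dict:
    """Machine-readable record of what produced a set of outputs."""
    payload = {"options": asdict(options), "seed": seed, **(extra or {})}
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
    return {
        **payload,
        "redoxscan_version": __version__,
        "python": platform.python_version(),
        "config_hash": digest,
    }
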