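"""Intensity calibration against in-scan reference standards and SNR masking.

Each scanned surface carries two frozen reference standards (one NADH, one
FAD/Fp solution of known concentration) beside the tissue.  Raw counts are
converted to *nominal concentrations* by a one-point linear calibration with
background subtraction::

    C(x) = C_ref * (counts(x) - I_bg) / (I_ref - I_bg)

where ``I_ref`` is the mean count over the channel's standard region and
``I_bg`` the mean background count.  Pixel signal-to-noise is defined as
``SNR = (counts - I_bg) / sigma_bg`` with ``sigma_bg`` the background SD;
pixels with SNR < 3.5 in either channel are excluded from all analyses, so
every index is computed on an identical pixel set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .scan_io import CHANNELS, ScanSection

__all__ = [
    "CalibrationError",
    "ReferenceEstimate",
    "CalibratedSection",
    "estimate_reference",
    "to_concentration",
    "snr_map",
    "snr_mask",
    "calibrate_section",
    "DEFAULT_SNR_THRESHOLD",
]

DEFAULT_SNR_THRESHOLD = 3.5


class CalibrationError(ValueError):
    """Raised when a section cannot be calibrated or masks out entirely."""


@dataclass(frozen=True)
class ReferenceEstimate:
    """Per-channel calibration inputs estimated from one section."""

    i_ref: float      # mean counts over the channel's standard disk
    i_bg: float       # mean counts over the background region
    sigma_bg: float   # SD of counts over the background region
    n_standard: int
    n_background: int


@dataclass
class CalibratedSection:
    """Concentration maps, SNR maps and joint validity mask for one section."""

    fp_um: np.ndarray
    nadh_um: np.ndarray
    valid_mask: np.ndarray
    snr_fp: np.ndarray
    snr_nadh: np.ndarray
    calibration_record: dict
    animal_id: str
    group: str
    depth_um: float
    step_size_um: float

    def concentration(self, channel: str) -> np.ndarray:
        return self.fp_um if channel == "fp" else self.nadh_um


def estimate_reference(
    section: ScanSection,
    channel: str,
    *,
    sigma_floor: float = 0.0,
) -> ReferenceEstimate:
    """Estimate (I_ref, I_bg, sigma_bg) for one channel of one section.

    ``sigma_floor`` imposes a lower bound on the background SD, useful for
    synthetic data with a constant background; by default a zero background
    SD is an error because the SNR rule would be undefined.
    """
    std_mask = section.regions[f"standard_{channel}"]
    bg_mask = section.regions["background"]
    if not std_mask.any():
        raise CalibrationError(f"empty standard mask for channel {channel!r}")
    if not bg_mask.any():
        raise CalibrationError("empty background mask")
    counts = section.counts(channel).astype(np.float64)
    i_ref = float(counts[std_mask].mean())
    i_bg = float(counts[bg_mask].mean())
    sigma_bg = max(float(counts[bg_mask].std(ddof=1)), float(sigma_floor))
    if sigma_bg <= 0:
        raise CalibrationError(
            f"background SD is zero for channel {channel!r}; SNR undefined"
        )
    if i_ref <= i_bg:
        raise CalibrationError(
            f"standard indistinct from background in channel {channel!r}: "
            f"I_ref={i_ref:.3g} <= I_bg={i_bg:.3g}"
        )
    return ReferenceEstimate(
        i_ref=i_ref,
        i_bg=i_bg,
        sigma_bg=sigma_bg,
        n_standard=int(std_mask.sum()),
        n_background=int(bg_mask.sum()),
    )


def to_concentration(
    counts: np.ndarray,
    i_ref: float,
    i_bg: float,
    c_ref: float,
) -> np.ndarray:
    """Linear one-point conversion of counts to nominal concentration (uM).

    Values are clipped below at zero: a pixel dimmer than background carries
    no physical concentration.
    """
    if i_ref <= i_bg:
        raise CalibrationError(f"I_ref={i_ref} must exceed I_bg={i_bg}")
    if c_ref <= 0:
        raise CalibrationError(f"reference concentration must be positive, got {c_ref}")
    conc = c_ref * (np.asarray(counts, dtype=np.float64) - i_bg) / (i_ref - i_bg)
    return np.clip(conc, 0.0, None)


def snr_map(counts: np.ndarray, i_bg: float, sigma_bg: float) -> np.ndarray:
    """Pixelwise signal-to-noise: background-subtracted counts over background SD."""
    if sigma_bg <= 0:
        raise CalibrationError("sigma_bg must be positive")
    return (np.asarray(counts, dtype=np.float64) - i_bg) / sigma_bg


def snr_mask(
    section: ScanSection,
    refs: Mapping[str, ReferenceEstimate],
    threshold: float = DEFAULT_SNR_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SNR maps for both channels and the joint validity mask.

    A tissue pixel is valid when its SNR reaches the threshold in *both*
    channels (the exclusion rule is the strict ``SNR < threshold``, so a
    pixel exactly at the threshold is retained).
    """
    snr_fp = snr_map(section.fp_counts, refs["fp"].i_bg, refs["fp"].sigma_bg)
    snr_nadh = snr_map(section.nadh_counts, refs["nadh"].i_bg, refs["nadh"].sigma_bg)
    valid = section.regions["tissue"] & (snr_fp >= threshold) & (snr_nadh >= threshold)
    if not valid.any():
        raise CalibrationError(
            f"empty ROI: every tissue pixel excluded at SNR threshold {threshold} "
            f"(section {section.animal_id!r}, depth {section.depth_um} um)"
        )
    return snr_fp, snr_nadh, valid


def calibrate_section(
    section: ScanSection,
    standard_concentrations_um: Mapping[str, float],
    *,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    sigma_floor: float = 0.0,
) -> CalibratedSection:
    """Full per-section calibration: concentrations, SNR maps, validity mask.

    Standards are re-estimated for every section (they are rescanned with
    each milled surface); nothing is pooled across sections.
    """
    refs = {
        ch: estimate_reference(section, ch, sigma_floor=sigma_floor) for ch in CHANNELS
    }
    fp_um = to_concentration(
        section.fp_counts, refs["fp"].i_ref, refs["fp"].i_bg,
        standard_concentrations_um["fp"],
    )
    nadh_um = to_concentration(
        section.nadh_counts, refs["nadh"].i_ref, refs["nadh"].i_bg,
        standard_concentrations_um["nadh"],
    )
    snr_fp, snr_nadh, valid = snr_mask(section, refs, snr_threshold)
    record = {
        "snr_threshold": float(snr_threshold),
        "channels": {
            ch: {
                "i_ref_counts": refs[ch].i_ref,
                "i_bg_counts": refs[ch].i_bg,
                "sigma_bg_counts": refs[ch].sigma_bg,
                "standard_concentration_um": float(standard_concentrations_um[ch]),
                "n_standard_pixels": refs[ch].n_standard,
                "n_background_pixels": refs[ch].n_background,
            }
            for ch in CHANNELS
        },
        "n_tissue_pixels": int(section.regions["tissue"].sum()),
        "n_valid_pixels": int(valid.sum()),
        "n_excluded_low_snr": int(section.regions["tissue"].sum() - valid.sum()),
    }
    return CalibratedSection(
        fp_um=fp_um,
        nadh_um=nadh_um,
        valid_mask=valid,
        snr_fp=snr_fp,
        snr_nadh=snr_nadh,
        calibration_record=record,
        animal_id=section.animal_id,
        group=section.group,
        depth_um=section.depth_um,
        step_size_um=section.step_size_um,
    )
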