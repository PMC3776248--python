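"""Synthetic multi-section redox-scan studies with known ground truth.

The generator emulates the geometry and statistics of a cryogenic
two-channel (Fp/NADH) redox-scanning study of mouse pancreas: 128 x 128
scan matrices at a 100 um step, several milled sections per animal at
increasing depths (200-2340 um below the first surface, 100-400 um apart),
one NADH and one FAD reference-standard disk beside the tissue in every
scan, and a low-count background region.

Each group's pixelwise Fp-ratio distribution is a two-component Gaussian
mixture: the control phenotype is near-unimodal and narrow, the PTEN-null
phenotype wider, more bimodal and slightly more oxidized.  The upper
(more-oxidized) mixture component is painted into spatially contiguous
blobs rather than i.i.d. pixels, so images show localized oxidized foci
while the per-pixel marginal distribution — which is all the downstream
statistics use — is preserved.

Channel synthesis guarantees that calibration recovers the drawn ratio: a
total concentration T is drawn per pixel (lognormal around the combined
Fp+NADH scale), split as Fp = r*T and NADH = (1-r)*T for drawn ratio r,
and converted to counts as gain * concentration + background + noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import histofit
from .scan_io import (
    ScanSection,
    StudyManifest,
    save_manifest,
    write_section,
)

__all__ = [
    "PhantomError",
    "GaussianPairParams",
    "NoiseModel",
    "PhantomConfig",
    "PhantomStudy",
    "CONTROL_RATIO_MODEL",
    "PTEN_NULL_RATIO_MODEL",
    "GROUPS",
    "make_phantom_study",
    "true_summary",
    "write_study",
]

GROUPS: tuple[str, str] = ("control", "pten_null")


class PhantomError(ValueError):
    """Raised for impossible phantom configurations."""


@dataclass(frozen=True)
class GaussianPairParams:
    """Bi-Gaussian coefficients describing a group's Fp-ratio distribution.

    Heights ``a1, a2`` are relative (only the area weights a_i*c_i matter
    for sampling); centers ``b1 <= b2`` are ratio values in [0, 1]; widths
    ``c1, c2`` are the Gaussian width parameters.
    """

    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.b1 > self.b2:
            raise PhantomError(f"centers must satisfy b1 <= b2, got {self.b1} > {self.b2}")
        if self.c1 < 0 or self.c2 < 0:
            raise PhantomError("width parameters must be non-negative")
        if self.a1 < 0 or self.a2 < 0:
            raise PhantomError("heights must be non-negative")
        if not (0 <= self.b1 <= 1 and 0 <= self.b2 <= 1):
            raise PhantomError("centers must lie in the ratio support [0, 1]")

    @property
    def weights(self) -> tuple[float, float]:
        """Normalized mixture weights, proportional to component areas a_i*c_i.

        Falls back to height weights in the degenerate zero-width case so a
        two-point (c = 0) mixture keeps a defined component split.
        """
        w1, w2 = self.a1 * self.c1, self.a2 * self.c2
        if w1 + w2 <= 0:
            w1, w2 = self.a1, self.a2
            if w1 + w2 <= 0:
                raise PhantomError("mixture has zero total weight")
        total = w1 + w2
        return w1 / total, w2 / total

    def moments(self) -> tuple[float, float]:
        """Closed-form mixture mean and SD."""
        if self.c1 > 0 and self.c2 > 0:
            return histofit.mixture_moments(self.a1, self.a2, self.b1, self.b2, self.c1, self.c2)
        w1, w2 = self.weights
        mean = w1 * self.b1 + w2 * self.b2
        second = w1 * (self.c1 ** 2 + self.b1 ** 2) + w2 * (self.c2 ** 2 + self.b2 ** 2)
        return mean, math.sqrt(max(second - mean ** 2, 0.0))

    def shifted(self, delta: float) -> "GaussianPairParams":
        """Both centers moved by ``delta`` (a uniform redox shift)."""
        return replace(self, b1=self.b1 + delta, b2=self.b2 + delta)

    def scaled_widths(self, factor: float) -> "GaussianPairParams":
        return replace(self, c1=self.c1 * factor, c2=self.c2 * factor)


#: Default group models: a narrow, near-unimodal control phenotype and a
#: wider, more bimodal, slightly more oxidized PTEN-null phenotype
#: (mixture SDs ~0.057 and ~0.102 respectively).
CONTROL_RATIO_MODEL = GaussianPairParams(a1=54, a2=33, b1=0.31, b2=0.35, c1=0.032, c2=0.065)
PTEN_NULL_RATIO_MODEL = GaussianPairParams(a1=39, a2=24, b1=0.32, b2=0.37, c1=0.071, c2=0.12)


@dataclass(frozen=True)
class NoiseModel:
    """Detector-count noise: background level and additive signal noise.

    ``quantize=True`` rounds counts to integers (uint16 storage, the raw
    instrument format); set it False for idealized noise-free studies where
    calibration should be exact to float precision.
    """

    background_mean: float = 50.0
    background_sd: float = 8.0
    signal_sd: float = 20.0
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.background_sd < 0 or self.signal_sd < 0:
            raise PhantomError("noise SDs must be non-negative")


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of a synthetic study.

    Defaults emulate the study design the package targets: 3 animals per
    group, 9 control and 14 PTEN-null sections, 128 x 128 scans at a 100 um
    step, milling depths within 200-2340 um spaced 100-400 um apart.
    Between-section biological variability (a per-section random shift of
    the mixture centers and a lognormal jitter of the widths) makes section
    means scatter the way real multi-section specimens do; both default to
    realistic non-zero values and can be zeroed for idealized studies.
    ``depth_slope_per_um`` adds a linear drift of the mean ratio with
    milling depth (default 0; used to study depth-covariate modelling).
    """

    n_animals_per_group: int = 3
    sections_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"control": 9, "pten_null": 14}
    )
    matrix_size: int = 128
    step_size_um: float = 100.0
    depth_range_um: tuple[float, float] = (200.0, 2340.0)
    depth_spacing_um: tuple[float, float] = (100.0, 400.0)
    control_ratio_model: GaussianPairParams = CONTROL_RATIO_MODEL
    ptennull_ratio_model: GaussianPairParams = PTEN_NULL_RATIO_MODEL
    fp_concentration_scale_um: float = 300.0
    nadh_concentration_scale_um: float = 600.0
    total_concentration_lognorm_sd: float = 0.15
    standard_concentrations_um: Mapping[str, float] = field(
        default_factory=lambda: {"fp": 500.0, "nadh": 500.0}
    )
    gain_per_channel: Mapping[str, float] = field(
        default_factory=lambda: {"fp": 20.0, "nadh": 20.0}
    )
    noise_model: NoiseModel = NoiseModel()
    section_center_jitter_sd: float = 0.03
    section_width_lognorm_sd: float = 0.20
    depth_slope_per_um: float = 0.0
    blob_radius_px: tuple[float, float] = (1.5, 4.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals_per_group < 1:
            raise PhantomError("need at least one animal per group")
        if set(self.sections_per_group) != set(GROUPS):
            raise PhantomError(f"sections_per_group must cover exactly {GROUPS}")
        for g, n in self.sections_per_group.items():
            if n < self.n_animals_per_group:
                raise PhantomError(
                    f"group {g!r}: {n} sections cannot cover "
                    f"{self.n_animals_per_group} animals"
                )
        if self.matrix_size < 16:
            raise PhantomError("matrix_size must be >= 16 to place standards")
        if self.step_size_um <= 0:
            raise PhantomError("step size must be positive")
        lo, hi = self.depth_range_um
        if not 0 <= lo < hi:
            raise PhantomError(f"invalid depth range {self.depth_range_um}")
        slo, shi = self.depth_spacing_um
        if not 0 < slo <= shi:
            raise PhantomError(f"invalid depth spacing {self.depth_spacing_um}")
        if self.fp_concentration_scale_um <= 0 or self.nadh_concentration_scale_um <= 0:
            raise PhantomError("concentration scales must be positive")
        for ch in ("fp", "nadh"):
            if self.standard_concentrations_um[ch] <= 0:
                raise PhantomError(f"standard concentration for {ch!r} must be positive")
            if self.gain_per_channel[ch] <= 0:
                raise PhantomError(f"gain for {ch!r} must be positive")
        if self.section_center_jitter_sd < 0 or self.section_width_lognorm_sd < 0:
            raise PhantomError("jitter SDs must be non-negative")

    def model_for(self, group: str) -> GaussianPairParams:
        if group == "control":
            return self.control_ratio_model
        if group == "pten_null":
            return self.ptennull_ratio_model
        raise PhantomError(f"unknown group {group!r}")


@dataclass
class PhantomStudy:
    """A generated study: sections, per-section ground truth and the config."""

    config: PhantomConfig
    sections: list[ScanSection]
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.sections) != len(self.truth):
            raise PhantomError("truth record count does not match section count")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _disk(n: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:n, :n]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _build_regions(n: int) -> dict[str, np.ndarray]:
    """Tissue disk in the center, standard disks in one corner column."""
    tissue = _disk(n, (0.5 * n, 0.5 * n), 0.32 * n)
    std_fp = _disk(n, (0.15 * n, 0.15 * n), 0.07 * n)
    std_nadh = _disk(n, (0.15 * n, 0.85 * n), 0.07 * n)
    for name, mask in (("tissue", tissue), ("standard_fp", std_fp), ("standard_nadh", std_nadh)):
        if not mask.any():
            raise PhantomError(f"degenerate geometry: empty {name} region at size {n}")
    if (tissue & std_fp).any() or (tissue & std_nadh).any() or (std_fp & std_nadh).any():
        raise PhantomError(f"impossible geometry: regions overlap at matrix size {n}")
    background = ~(tissue | std_fp | std_nadh)
    if not background.any():
        raise PhantomError("impossible geometry: no background pixels left")
    return {
        "background": background,
        "tissue": tissue,
        "standard_fp": std_fp,
        "standard_nadh": std_nadh,
    }


def _blob_assignment(
    rng: np.random.Generator,
    tissue: np.ndarray,
    n_upper: int,
    radius_range: tuple[float, float],
) -> np.ndarray:
    """Boolean mask over the image: which tissue pixels belong to component 2.

    Random disks are unioned until the target pixel count is reached, then
    excess pixels are dropped at random, so the component-2 area fraction is
    exact while the spatial texture is blobby.
    """
    n = tissue.shape[0]
    coords = np.argwhere(tissue)
    chosen = np.zeros_like(tissue)
    guard = 0
    while chosen.sum() < n_upper and guard < 10000:
        guard += 1
        cr, cc = coords[rng.integers(len(coords))]
        radius = rng.uniform(*radius_range)
        chosen |= _disk(n, (float(cr), float(cc)), radius) & tissue
    excess = int(chosen.sum()) - n_upper
    if excess > 0:
        idx = np.argwhere(chosen)
        drop = idx[rng.choice(len(idx), size=excess, replace=False)]
        chosen[drop[:, 0], drop[:, 1]] = False
    return chosen


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------


def _animal_depths(rng: np.random.Generator, cfg: PhantomConfig, n_sections: int) -> np.ndarray:
    lo, hi = cfg.depth_range_um
    slo, shi = cfg.depth_spacing_um
    first = rng.uniform(lo, min(lo + 400.0, hi))
    spacings = rng.uniform(slo, shi, size=n_sections - 1)
    depths = first + np.concatenate([[0.0], np.cumsum(spacings)])
    if depths[-1] > hi:
        raise PhantomError(
            f"{n_sections} sections cannot fit in depth range {cfg.depth_range_um} "
            f"with spacing {cfg.depth_spacing_um}"
        )
    return np.round(depths, 1)


def _split_sections(total: int, n_animals: int) -> list[int]:
    base, extra = divmod(total, n_animals)
    return [base + (1 if i < extra else 0) for i in range(n_animals)]


def _generate_section(
    rng: np.random.Generator,
    cfg: PhantomConfig,
    regions: dict[str, np.ndarray],
    group: str,
    animal_id: str,
    depth: float,
) -> tuple[ScanSection, dict]:
    model = cfg.model_for(group)
    tissue = regions["tissue"]
    n_tissue = int(tissue.sum())

    # per-section biological state: shifted centers, jittered widths, depth drift
    shift = rng.normal(0.0, cfg.section_center_jitter_sd) if cfg.section_center_jitter_sd > 0 else 0.0
    wj = (
        float(np.exp(rng.normal(0.0, cfg.section_width_lognorm_sd)))
        if cfg.section_width_lognorm_sd > 0
        else 1.0
    )
    drift = cfg.depth_slope_per_um * (depth - cfg.depth_range_um[0])
    b1 = model.b1 + shift + drift
    b2 = model.b2 + shift + drift
    c1, c2 = model.c1 * wj, model.c2 * wj
    w1, w2 = model.weights  # area weights are jitter-invariant (both widths scale)

    # component assignment: upper component in contiguous blobs
    n_upper = int(round(w2 * n_tissue))
    upper = _blob_assignment(rng, tissue, n_upper, cfg.blob_radius_px)
    lower = tissue & ~upper

    ratio = np.zeros(tissue.shape)
    ratio[lower] = b1 + (c1 * rng.standard_normal(int(lower.sum())) if c1 > 0 else 0.0)
    ratio[upper] = b2 + (c2 * rng.standard_normal(n_upper) if c2 > 0 else 0.0)
    ratio_t = np.clip(ratio[tissue], 0.0, 1.0)
    ratio[tissue] = ratio_t

    # channel concentrations: split a lognormal total concentration by the ratio
    scale_total = cfg.fp_concentration_scale_um + cfg.nadh_concentration_scale_um
    ln_sd = cfg.total_concentration_lognorm_sd
    total_um = scale_total * (
        np.exp(rng.normal(0.0, ln_sd, size=n_tissue)) if ln_sd > 0 else np.ones(n_tissue)
    )
    fp_um = np.zeros(tissue.shape)
    nadh_um = np.zeros(tissue.shape)
    fp_um[tissue] = ratio_t * total_um
    nadh_um[tissue] = (1.0 - ratio_t) * total_um

    nm = cfg.noise_model
    shape = tissue.shape
    channels = {}
    for ch, conc in (("fp", fp_um), ("nadh", nadh_um)):
        gain = cfg.gain_per_channel[ch]
        counts = np.empty(shape)
        counts[regions["background"]] = rng.normal(
            nm.background_mean, nm.background_sd, size=int(regions["background"].sum())
        )
        for other in ("fp", "nadh"):
            std = regions[f"standard_{other}"]
            nstd = int(std.sum())
            if other == ch:
                level = gain * cfg.standard_concentrations_um[ch] + nm.background_mean
                counts[std] = level + rng.normal(0.0, nm.signal_sd, size=nstd)
            else:
                # the other fluorophore's standard is dark in this channel
                counts[std] = rng.normal(nm.background_mean, nm.background_sd, size=nstd)
        counts[tissue] = (
            gain * conc[tissue]
            + nm.background_mean
            + rng.normal(0.0, nm.signal_sd, size=n_tissue)
        )
        counts = np.clip(counts, 0.0, float(np.iinfo(np.uint16).max))
        if nm.quantize:
            counts = np.round(counts).astype(np.uint16)
        # unquantized counts stay float64 so idealized studies calibrate exactly
        channels[ch] = counts

    section = ScanSection(
        fp_counts=channels["fp"],
        nadh_counts=channels["nadh"],
        depth_um=float(depth),
        animal_id=animal_id,
        group=group,
        regions={k: v.copy() for k, v in regions.items()},
        step_size_um=cfg.step_size_um,
    )
    mean_model = w1 * b1 + w2 * b2
    second = w1 * (c1 ** 2 + b1 ** 2) + w2 * (c2 ** 2 + b2 ** 2)
    sd_model = math.sqrt(max(second - mean_model ** 2, 0.0))
    truth = {
        "group": group,
        "animal_id": animal_id,
        "depth_um": float(depth),
        "true_mean": float(mean_model),
        "true_sd": float(sd_model),
        "sample_mean": float(ratio_t.mean()),
        "sample_sd": float(ratio_t.std(ddof=1)) if n_tissue > 1 else 0.0,
        "true_fp_um": float(fp_um[tissue].mean()),
        "true_nadh_um": float(nadh_um[tissue].mean()),
        "n_tissue_pixels": n_tissue,
    }
    return section, truth


def make_phantom_study(config: PhantomConfig) -> PhantomStudy:
    """Generate one synthetic two-group study; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = _build_regions(config.matrix_size)
    sections: list[ScanSection] = []
    truth_rows: list[dict] = []
    for group in GROUPS:
        counts = _split_sections(config.sections_per_group[group], config.n_animals_per_group)
        for i, n_sec in enumerate(counts, start=1):
            animal_id = f"{group}_{i:02d}"
            depths = _animal_depths(rng, config, n_sec)
            for depth in depths:
                section, truth = _generate_section(
                    rng, config, regions, group, animal_id, float(depth)
                )
                sections.append(section)
                truth_rows.append(truth)
    return PhantomStudy(config=config, sections=sections, truth=pd.DataFrame(truth_rows))


def true_summary(study: PhantomStudy) -> pd.DataFrame:
    """Per-section ground-truth table: one row per generated section."""
    return study.truth.copy()


def write_study(study: PhantomStudy, outdir: str | Path) -> Path:
    """Write the study in the standard on-disk format; returns the manifest path.

    The layout is exactly what :func:`redoxscan.scan_io.load_study` reads, so
    the analysis pipeline cannot distinguish a phantom from a real study.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for section in study.sections:
        paths = write_section(section, outdir / "sections")
        records.append(
            {
                "animal_id": section.animal_id,
                "group": section.group,
                "depth_um": section.depth_um,
                "fp_path": str(paths["fp"].relative_to(outdir)),
                "nadh_path": str(paths["nadh"].relative_to(outdir)),
                "mask_path": str(paths["mask"].relative_to(outdir)),
            }
        )
    manifest = StudyManifest(
        standard_concentrations_um=dict(study.config.standard_concentrations_um),
        sections=records,
        step_size_um=study.config.step_size_um,
    )
    manifest_path = save_manifest(manifest, outdir / "manifest.yaml")
    study.truth.to_csv(outdir / "truth.csv", index=False, float_format="%.17g")
    return manifest_path
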