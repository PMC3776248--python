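"""Data model and file I/O for redox-scanner sections, manifests and result tables.

A *section* is one milled surface of a frozen specimen, raster-scanned in two
fluorescence channels (Fp and NADH).  On disk a section is three TIFF files —
one per channel plus a labelled region mask — tied together by a YAML study
manifest that also records the reference-standard concentrations.  All
round-trips are lossless: raw counts are stored as 16-bit unsigned integers
(or 32-bit floats for unquantized synthetic data), masks as 8-bit labels.

Coordinate convention: row-major, pixel (0, 0) at the scan origin, 0-based
indices; the physical step size (default 100 um) is carried in metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "FormatError",
    "REGION_LABELS",
    "REGION_NAMES",
    "INDEX_NAMES",
    "CHANNELS",
    "ScanSection",
    "StudyManifest",
    "SectionSummary",
    "write_section",
    "read_section",
    "save_manifest",
    "load_manifest",
    "load_study",
    "summaries_to_frame",
    "write_summary_table",
    "read_summary_table",
]


class FormatError(ValueError):
    """Raised when files or metadata violate the on-disk format contract."""


#: Integer codes used in the labelled region-mask TIFF.
REGION_LABELS: Mapping[str, int] = {
    "background": 0,
    "tissue": 1,
    "standard_fp": 2,
    "standard_nadh": 3,
}
REGION_NAMES: tuple[str, ...] = tuple(REGION_LABELS)

#: The five redox indices, in the order reported throughout the package.
INDEX_NAMES: tuple[str, ...] = (
    "fp",
    "nadh",
    "fp_ratio",
    "fp_over_nadh",
    "nadh_over_fp",
)

CHANNELS: tuple[str, ...] = ("fp", "nadh")


@dataclass
class ScanSection:
    """One milled section: two raw-count channel images plus region masks.

    Parameters
    ----------
    fp_counts, nadh_counts
        Raw detector counts for the Fp and NADH channels; same shape.
    depth_um
        Milling depth of this surface below the first milled surface of the
        specimen, in micrometres.  The top section carries its own recorded
        milling depth (e.g. 200 um), not zero.
    animal_id, group
        Specimen labels; ``group`` is ``"control"`` or ``"pten_null"``.
    regions
        Boolean masks named ``tissue``, ``standard_fp``, ``standard_nadh``
        and ``background``; pairwise disjoint, same shape as the channels.
    step_size_um
        Physical scan step between adjacent pixels.
    """

    fp_counts: np.ndarray
    nadh_counts: np.ndarray
    depth_um: float
    animal_id: str
    group: str
    regions: dict[str, np.ndarray]
    step_size_um: float = 100.0

    def __post_init__(self) -> None:
        self.fp_counts = np.asarray(self.fp_counts)
        self.nadh_counts = np.asarray(self.nadh_counts)
        if self.fp_counts.shape != self.nadh_counts.shape:
            raise FormatError(
                f"channel shape mismatch: fp {self.fp_counts.shape} vs "
                f"nadh {self.nadh_counts.shape}"
            )
        if self.depth_um < 0:
            raise FormatError(f"negative depth {self.depth_um}")
        missing = [r for r in REGION_NAMES if r not in self.regions]
        if missing:
            raise FormatError(f"missing region masks: {missing}")
        overlap = np.zeros(self.fp_counts.shape, dtype=int)
        for name in REGION_NAMES:
            mask = np.asarray(self.regions[name], dtype=bool)
            if mask.shape != self.fp_counts.shape:
                raise FormatError(f"region {name!r} shape mismatch")
            self.regions[name] = mask
            overlap += mask
        if (overlap > 1).any():
            raise FormatError("region masks overlap")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.fp_counts.shape

    def counts(self, channel: str) -> np.ndarray:
        if channel not in CHANNELS:
            raise KeyError(f"unknown channel {channel!r}")
        return self.fp_counts if channel == "fp" else self.nadh_counts


def _label_image(regions: Mapping[str, np.ndarray]) -> np.ndarray:
    shape = next(iter(regions.values())).shape
    labels = np.zeros(shape, dtype=np.uint8)
    for name, code in REGION_LABELS.items():
        labels[np.asarray(regions[name], dtype=bool)] = code
    return labels


def _regions_from_labels(labels: np.ndarray) -> dict[str, np.ndarray]:
    regions = {name: labels == code for name, code in REGION_LABELS.items()}
    present = {int(v) for v in np.unique(labels)}
    unknown = present - set(REGION_LABELS.values())
    if unknown:
        raise FormatError(f"unknown region codes in mask: {sorted(unknown)}")
    return regions


def _counts_to_storage(counts: np.ndarray) -> np.ndarray:
    """uint16 for integer-valued counts; float TIFF at native width otherwise."""
    if np.issubdtype(counts.dtype, np.integer):
        if counts.min() < 0 or counts.max() > np.iinfo(np.uint16).max:
            raise FormatError("integer counts outside uint16 range")
        return counts.astype(np.uint16)
    return counts.astype(np.float32) if counts.dtype == np.float32 else counts.astype(np.float64)


def write_section(section: ScanSection, outdir: str | Path, stem: str | None = None) -> dict[str, Path]:
    """Write one section as three TIFFs; returns the paths keyed fp/nadh/mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stem is None:
        stem = f"{section.group}_{section.animal_id}_d{int(round(section.depth_um)):05d}"
    paths = {
        "fp": outdir / f"{stem}_fp.tif",
        "nadh": outdir / f"{stem}_nadh.tif",
        "mask": outdir / f"{stem}_mask.tif",
    }
    tifffile.imwrite(paths["fp"], _counts_to_storage(section.fp_counts))
    tifffile.imwrite(paths["nadh"], _counts_to_storage(section.nadh_counts))
    tifffile.imwrite(paths["mask"], _label_image(section.regions))
    return paths


def read_section(
    fp_path: str | Path,
    nadh_path: str | Path,
    mask_path: str | Path,
    *,
    depth_um: float,
    animal_id: str,
    group: str,
    step_size_um: float = 100.0,
) -> ScanSection:
    """Read one section from its channel and mask TIFFs."""
    for p in (fp_path, nadh_path, mask_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"section file not found: {p}")
    fp = tifffile.imread(fp_path)
    nadh = tifffile.imread(nadh_path)
    labels = tifffile.imread(mask_path)
    if fp.shape != nadh.shape or fp.shape != labels.shape:
        raise FormatError(
            f"shape mismatch among {fp_path}, {nadh_path}, {mask_path}: "
            f"{fp.shape}, {nadh.shape}, {labels.shape}"
        )
    return ScanSection(
        fp_counts=fp,
        nadh_counts=nadh,
        depth_um=depth_um,
        animal_id=animal_id,
        group=group,
        regions=_regions_from_labels(labels),
        step_size_um=step_size_um,
    )


# ---------------------------------------------------------------------------
# Study manifest
# ---------------------------------------------------------------------------

_SECTION_RECORD_KEYS = {"animal_id", "group", "depth_um", "fp_path", "nadh_path", "mask_path"}


@dataclass
class StudyManifest:
    """Study-level metadata: section records plus calibration constants.

    ``sections`` is a list of dicts with keys ``animal_id``, ``group``,
    ``depth_um`` and the three relative file paths.  The manifest schema is
    published in ``docs/manifest.schema.json``.
    """

    standard_concentrations_um: dict[str, float]
    sections: list[dict] = field(default_factory=list)
    step_size_um: float = 100.0

    def validate(self) -> None:
        if not self.sections:
            raise FormatError("manifest lists no sections")
        for ch in CHANNELS:
            c = self.standard_concentrations_um.get(ch)
            if c is None or c <= 0:
                raise FormatError(f"standard concentration for {ch!r} missing or non-positive")
        seen: set[tuple[str, float]] = set()
        groups: set[str] = set()
        for rec in self.sections:
            missing = _SECTION_RECORD_KEYS - set(rec)
            if missing:
                raise FormatError(f"section record missing keys {sorted(missing)}: {rec}")
            key = (str(rec["animal_id"]), float(rec["depth_um"]))
            if key in seen:
                raise FormatError(f"duplicate (animal_id, depth) record: {key}")
            seen.add(key)
            groups.add(str(rec["group"]))
        if not groups:
            raise FormatError("manifest defines no groups")


def save_manifest(manifest: StudyManifest, path: str | Path) -> Path:
    manifest.validate()
    path = Path(path)
    doc = {
        "standard_concentrations_um": {
            k: float(v) for k, v in manifest.standard_concentrations_um.items()
        },
        "step_size_um": float(manifest.step_size_um),
        "sections": [
            {
                "animal_id": str(r["animal_id"]),
                "group": str(r["group"]),
                "depth_um": float(r["depth_um"]),
                "fp_path": str(r["fp_path"]),
                "nadh_path": str(r["nadh_path"]),
                "mask_path": str(r["mask_path"]),
            }
            for r in manifest.sections
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def load_manifest(path: str | Path) -> StudyManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"manifest {path} is not a mapping")
    try:
        manifest = StudyManifest(
            standard_concentrations_um=dict(doc["standard_concentrations_um"]),
            sections=list(doc.get("sections") or []),
            step_size_um=float(doc.get("step_size_um", 100.0)),
        )
    except KeyError as exc:
        raise FormatError(f"manifest {path} missing key {exc}") from exc
    manifest.validate()
    return manifest


def load_study(manifest_path: str | Path) -> tuple[list[ScanSection], StudyManifest]:
    """Load every section referenced by a manifest.

    Sections are returned ordered by ``(group, animal_id, depth_um)``
    regardless of the row order in the manifest file.  Relative paths are
    resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = load_manifest(manifest_path)
    base = manifest_path.parent
    records = sorted(
        manifest.sections,
        key=lambda r: (str(r["group"]), str(r["animal_id"]), float(r["depth_um"])),
    )
    sections = []
    for rec in records:
        paths = {k: base / rec[f"{k}_path"] for k in ("fp", "nadh", "mask")}
        for p in paths.values():
            if not p.exists():
                raise FileNotFoundError(f"manifest references absent file: {p}")
        sections.append(
            read_section(
                paths["fp"],
                paths["nadh"],
                paths["mask"],
                depth_um=float(rec["depth_um"]),
                animal_id=str(rec["animal_id"]),
                group=str(rec["group"]),
                step_size_um=manifest.step_size_um,
            )
        )
    return sections, manifest


# ---------------------------------------------------------------------------
# Section summaries
# ---------------------------------------------------------------------------


@dataclass
class SectionSummary:
    """Per-section mean and sample SD of the five redox indices over the ROI."""

    animal_id: str
    group: str
    depth_um: float
    n_pixels: int
    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be positive")
        for idx in INDEX_NAMES:
            if idx not in self.mean or idx not in self.sd:
                raise ValueError(f"summary missing index {idx!r}")
            if np.isfinite(self.sd[idx]) and self.sd[idx] < 0:
                raise ValueError(f"negative SD for {idx!r}")
        r = self.mean["fp_ratio"]
        if np.isfinite(r) and not (0.0 <= r <= 1.0):
            raise ValueError(f"mean fp_ratio {r} outside [0, 1]")


_SUMMARY_COLUMNS = ["animal_id", "group", "depth_um", "n_pixels"] + [
    f"{idx}_{stat}" for idx in INDEX_NAMES for stat in ("mean", "sd")
]


def summaries_to_frame(rows: Sequence[SectionSummary]) -> pd.DataFrame:
    """Flatten summaries to a DataFrame with a stable column order."""
    data = []
    for s in rows:
        rec = {
            "animal_id": s.animal_id,
            "group": s.group,
            "depth_um": s.depth_um,
            "n_pixels": s.n_pixels,
        }
        for idx in INDEX_NAMES:
            rec[f"{idx}_mean"] = s.mean[idx]
            rec[f"{idx}_sd"] = s.sd[idx]
        data.append(rec)
    return pd.DataFrame(data, columns=_SUMMARY_COLUMNS)


def write_summary_table(rows: Sequence[SectionSummary] | pd.DataFrame, path: str | Path) -> Path:
    """Write section summaries as CSV (full float precision, stable columns)."""
    if isinstance(rows, pd.DataFrame):
        frame = rows[_SUMMARY_COLUMNS]
    else:
        if len(rows) == 0:
            raise ValueError("no summary rows to write")
        frame = summaries_to_frame(rows)
    if frame.empty:
        raise ValueError("no summary rows to write")
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_summary_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(_SUMMARY_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"summary table missing columns {sorted(missing)}")
    return frame
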