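"""Shared fixtures: small phantom studies and hand-built sections.

Everything is generated programmatically; no binary fixtures live in the
repository.  Study-level fixtures use a 48-pixel scan matrix — large enough
for stable per-section statistics, small enough to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import redoxscan as rs
from redoxscan.phantom import PhantomConfig, make_phantom_study
from redoxscan.scan_io import ScanSection, StudyManifest


def small_config(**overrides) -> PhantomConfig:
    defaults = dict(matrix_size=48, seed=1)
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def default_study():
    """Default two-phenotype study at reduced matrix size."""
    return make_phantom_study(small_config())


@pytest.fixture(scope="session")
def default_manifest(default_study) -> StudyManifest:
    cfg = default_study.config
    return StudyManifest(
        standard_concentrations_um=dict(cfg.standard_concentrations_um),
        sections=[
            {
                "animal_id": s.animal_id,
                "group": s.group,
                "depth_um": s.depth_um,
                "fp_path": "unused",
                "nadh_path": "unused",
                "mask_path": "unused",
            }
            for s in default_study.sections
        ],
        step_size_um=cfg.step_size_um,
    )


@pytest.fixture(scope="session")
def analyzed_study(default_study, default_manifest):
    """(summaries, fits, analyses) of the default study."""
    return rs.analyze_study(default_study.sections, default_manifest)


def make_flat_section(
    n: int = 32,
    fp_level: float = 4000.0,
    nadh_level: float = 8000.0,
    std_level: float = 10000.0,
    bg_level: float = 10.0,
    bg_noise_sd: float = 1.0,
    seed: int = 0,
) -> ScanSection:
    """A hand-built section with constant tissue counts and a noisy background."""
    rng = np.random.default_rng(seed)
    regions = {
        "tissue": np.zeros((n, n), dtype=bool),
        "standard_fp": np.zeros((n, n), dtype=bool),
        "standard_nadh": np.zeros((n, n), dtype=bool),
        "background": np.zeros((n, n), dtype=bool),
    }
    regions["tissue"][n // 4 : 3 * n // 4, n // 4 : 3 * n // 4] = True
    regions["standard_fp"][1:4, 1:4] = True
    regions["standard_nadh"][1:4, n - 4 : n - 1] = True
    regions["background"] = ~(
        regions["tissue"] | regions["standard_fp"] | regions["standard_nadh"]
    )
    fp = np.full((n, n), bg_level)
    nadh = np.full((n, n), bg_level)
    fp[regions["background"]] += rng.normal(0, bg_noise_sd, int(regions["background"].sum()))
    nadh[regions["background"]] += rng.normal(0, bg_noise_sd, int(regions["background"].sum()))
    fp[regions["tissue"]] = fp_level
    nadh[regions["tissue"]] = nadh_level
    fp[regions["standard_fp"]] = std_level
    nadh[regions["standard_nadh"]] = std_level
    # the other fluorophore's standard is dark in each channel
    fp[regions["standard_nadh"]] = bg_level
    nadh[regions["standard_fp"]] = bg_level
    return ScanSection(
        fp_counts=fp,
        nadh_counts=nadh,
        depth_um=200.0,
        animal_id="hand_01",
        group="control",
        regions=regions,
    )
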