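"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from petbloodnorm import (
    CohortSpec,
    Volume,
    build_analysis_mask,
    build_default_atlas,
    simulate_cohort,
)

GRID = (48, 48, 96)
VOXEL_MM = 0.5


@pytest.fixture(scope="session")
def atlas():
    return build_default_atlas(GRID, VOXEL_MM)


@pytest.fixture(scope="session")
def default_cohort(atlas):
    """One default (noisy, blurred) WT-vs-KO cohort, 11 per arm."""
    scans, truths = simulate_cohort(atlas, CohortSpec(seed=1))
    return scans, truths


@pytest.fixture(scope="session")
def ideal_cohort(atlas):
    """Noise-free, blur-free, assay-error-free cohort (the ideal limit)."""
    spec = CohortSpec(seed=7, psf_sigma_mm=0.0, noise_scale=0.0, blood_assay_cv=0.0)
    scans, truths = simulate_cohort(atlas, spec)
    return scans, truths


@pytest.fixture(scope="session")
def default_mask(default_cohort):
    scans, _ = default_cohort
    return build_analysis_mask(scans)


def full_mask(shape, voxel_mm=1.0) -> Volume:
    return Volume(np.ones(shape, dtype=np.int16), (voxel_mm,) * 3, "label")
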