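"""Shared fixtures: tiny geometries for unit tests and the three desk-scale
study runs (brain-in-PBS vial, iodine vials, bar pattern) that several
integration and acceptance tests analyze. The studies are expensive, so they
are session-scoped and simulated once."""

import numpy as np
import pytest

from hybridct.geometry import ScanGeometry
from hybridct.pipeline import (StudySettings, brain_study, resolution_study,
                               vials_study)
from hybridct.projector import Projector
from hybridct.recon import ReconConfig


@pytest.fixture(scope="session")
def tiny_geometry():
    return ScanGeometry(n_views=60, angular_span=180.0, n_rows=1, n_cols=96,
                        pixel_pitch=0.1, n_tiles=8)


@pytest.fixture(scope="session")
def tiny_projector(tiny_geometry):
    return Projector(tiny_geometry, 64, 0.15, nz=1)


def disk_image(n_pix: int, voxel_mm: float, radius_mm: float,
               value: float = 1.0, center=(0.0, 0.0)) -> np.ndarray:
    x = (np.arange(n_pix) - (n_pix - 1) / 2) * voxel_mm
    xx, yy = np.meshgrid(x, x, indexing="ij")
    return np.where((xx - center[0]) ** 2 + (yy - center[1]) ** 2
                    <= radius_mm**2, value, 0.0)


@pytest.fixture(scope="session")
def brain_results():
    """Full corrected brain-in-PBS-vial study at desk scale."""
    return brain_study(seed=1)


@pytest.fixture(scope="session")
def vials_results():
    """Iodine vials phantom study (four stock concentrations)."""
    return vials_study(seed=2, settings=StudySettings(n_rows=4))


@pytest.fixture(scope="session")
def resolution_results():
    """Bar-pattern phantom reconstructed PCD-only / EID-only / hybrid."""
    return resolution_study(seed=3, settings=StudySettings(n_rows=2))
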