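"""Shared fixtures.

Forward solves are the expensive step, so solved pipelines on a compact
test head (70 mm outer radius, 2 mm voxels) are session-scoped and reused
across test modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import tdcsim as t

TEST_VOXEL_MM = 2.0
TEST_LAYERS = {"skin": 6.0, "skull": 5.0, "csf": 3.0, "gray": 4.0}
TEST_RADIUS_MM = 70.0


@dataclass
class SolvedCase:
    head: t.LabelVolume
    montage: t.Montage
    potential: t.PotentialField
    report: t.SolveReport
    raster: t.MontageRaster
    sigma: np.ndarray
    efield: t.EFieldVolume
    surface: "t.CorticalSurface"
    cmap: t.CorticalMap


def _solve_case(head: t.LabelVolume, montage: t.Montage) -> SolvedCase:
    pot, report, raster, sigma = t.solve_montage(head, montage)
    ef = t.gradient_to_efield(pot, head)
    surface = t.extract_cortical_surface(head)
    cmap = t.normal_component_map(ef, surface)
    return SolvedCase(head, montage, pot, report, raster, sigma, ef, surface, cmap)


@pytest.fixture(scope="session")
def test_head() -> t.LabelVolume:
    spec = t.SphereSpec(TEST_RADIUS_MM, TEST_LAYERS, voxel_mm=TEST_VOXEL_MM)
    return t.make_layered_sphere_phantom(spec)


@pytest.fixture(scope="session")
def pad_case(test_head) -> SolvedCase:
    return _solve_case(test_head, t.preset_pad_m1_so(test_head))


@pytest.fixture(scope="session")
def hd_case(test_head) -> SolvedCase:
    return _solve_case(test_head, t.preset_hd_4x1(test_head))


@pytest.fixture(scope="session")
def hd_polar_case(test_head) -> SolvedCase:
    """4x1 ring centered on the grid pole: the four cathodes are related by
    exact 90-degree grid rotations, so their rasterizations are identical."""
    montage = t.preset_hd_4x1(test_head, center_angles_rad=(0.0, 0.0))
    return _solve_case(test_head, montage)


@pytest.fixture(scope="session")
def fine_head() -> t.LabelVolume:
    """1 mm head used for geometry-only checks (no solve)."""
    spec = t.SphereSpec(92.0, {"skin": 7, "skull": 5, "csf": 2, "gray": 3}, voxel_mm=1.0)
    return t.make_layered_sphere_phantom(spec)
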