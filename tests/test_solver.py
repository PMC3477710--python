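"""Finite-volume assembly and conjugate-gradient solve."""

import numpy as np
import pytest

import tdcsim as t
from tdcsim.solver import (
    DisconnectedCircuitError,
    SolverConfig,
    assemble_system,
    face_conductances,
    solve_potential,
)


class TestFaceConductances:
    def test_equal_conductivities_pass_through(self):
        sigma = np.full((2, 1, 1), 0.3)
        g = face_conductances(sigma, 1e-3)[0]
        assert g[0, 0, 0] == pytest.approx(0.3 * 1e-3)

    def test_harmonic_mean_of_contrasting_pair(self):
        # hand calculation: 2 / (1/0.01 + 1/1.65) = 0.0198795...
        sigma = np.array([0.01, 1.65]).reshape(2, 1, 1)
        g = face_conductances(sigma, 1e-3)[0]
        assert g[0, 0, 0] == pytest.approx(0.019879518 * 1e-3, rel=1e-6)

    def test_operator_rows_sum_to_zero_in_interior(self, test_head):
        montage = t.preset_pad_m1_so(test_head)
        raster = t.rasterize_montage(test_head, montage)
        sigma = t.build_sigma_volume(raster.volume, t.default_table())
        system = assemble_system(sigma, raster)
        # rows of the full operator sum to zero except where ground columns
        # were eliminated: check a random interior sample of free voxels
        row_sums = np.asarray(system.A.sum(axis=1)).ravel()
        cathode = np.concatenate(
            [raster.electrodes[e.name].conductor_idx for e in montage.cathodes]
        )
        neighbor_of_ground = np.zeros(sigma.size, dtype=bool)
        mask = np.zeros(sigma.size, dtype=bool)
        mask[cathode] = True
        m3 = mask.reshape(sigma.shape)
        from scipy import ndimage

        dil = ndimage.binary_dilation(m3, ndimage.generate_binary_structure(3, 1))
        neighbor_of_ground = dil.ravel()[system.free_idx]
        assert np.allclose(row_sums[~neighbor_of_ground], 0.0, atol=1e-12)
        # voxels next to the eliminated ground keep a positive diagonal excess
        assert (row_sums[neighbor_of_ground] > 0).any()

    def test_rejects_nonpositive_sigma(self, test_head):
        montage = t.preset_pad_m1_so(test_head)
        raster = t.rasterize_montage(test_head, montage)
        sigma = t.build_sigma_volume(raster.volume, t.default_table())
        sigma[0, 0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            assemble_system(sigma, raster)


class TestSlabClosedForm:
    def test_uniform_field_matches_ohms_law(self):
        """1 mA through a sigma = 1 S/m slab with 10 x 10 cm plates gives
        |E| = I / (A sigma) = 0.1 V/m."""
        raster = t.make_slab_with_plates((100, 100, 50), tissue="gray", voxel_mm=2.0)
        table = t.default_table().with_overrides(gray=1.0)
        sigma = t.build_sigma_volume(raster.volume, table)
        system = assemble_system(sigma, raster)
        pot, report = solve_potential(system)
        ef = t.gradient_to_efield(pot, raster.volume)
        nx, ny, nz = raster.volume.shape
        core = ef.magnitude[nx // 4 : -nx // 4, ny // 4 : -ny // 4, nz // 2]
        assert np.allclose(core, 0.1, rtol=0.01)
        assert report.final_relative_residual <= 1e-6

    def test_grid_convergence_of_slab_field(self):
        errs = []
        for h in (4.0, 2.0, 1.0):
            raster = t.make_slab_with_plates((40, 40, 24), tissue="gray", voxel_mm=h)
            table = t.default_table().with_overrides(gray=1.0)
            sigma = t.build_sigma_volume(raster.volume, table)
            pot, _ = solve_potential(assemble_system(sigma, raster))
            ef = t.gradient_to_efield(pot, raster.volume)
            nx, ny, nz = raster.volume.shape
            mid = ef.magnitude[nx // 2, ny // 2, nz // 2]
            expected = 1e-3 / (0.04 * 0.04 * 1.0)
            errs.append(abs(mid - expected) / expected)
        assert errs[0] >= errs[1] >= errs[2]

    def test_doubling_current_doubles_potential(self):
        raster = t.make_slab_with_plates((40, 40, 24), tissue="gray", voxel_mm=2.0)
        sigma = t.build_sigma_volume(raster.volume, t.default_table())
        pot1, _ = solve_potential(assemble_system(sigma, raster))
        raster2 = t.make_slab_with_plates(
            (40, 40, 24), tissue="gray", voxel_mm=2.0, total_current_A=2e-3
        )
        pot2, _ = solve_potential(assemble_system(sigma, raster2))
        assert np.allclose(pot2.V, 2 * pot1.V, rtol=1e-6, atol=1e-12)


class TestSolveOnHead:
    def test_converges_to_tolerance_with_zero_ground(self, pad_case):
        rep = pad_case.report
        assert rep.final_relative_residual <= 1e-6
        cathode_idx = pad_case.raster.electrodes["cathode_so"].conductor_idx
        assert np.all(pad_case.potential.V.ravel()[cathode_idx] == 0.0)
        assert np.all(np.isfinite(pad_case.potential.V))

    def test_current_audit_pad(self, pad_case):
        cur = pad_case.report.per_electrode_current_A
        assert cur["anode_m1"] == pytest.approx(1e-3, rel=1e-3)
        assert cur["cathode_so"] == pytest.approx(-1e-3, rel=1e-3)
        assert pad_case.report.conservation_error_A <= 1e-3 * 1e-3

    def test_symmetric_ring_splits_current_equally(self, hd_polar_case):
        cur = hd_polar_case.report.per_electrode_current_A
        assert cur["anode_center"] == pytest.approx(1e-3, rel=1e-3)
        for i in range(4):
            assert cur[f"cathode_ring_{i}"] == pytest.approx(-0.25e-3, rel=0.01)

    def test_closer_cathode_draws_more_current(self, test_head, hd_polar_case):
        import dataclasses

        montage = hd_polar_case.montage
        els = list(montage.electrodes)
        moved = els[1]
        theta, phi = moved.position
        els[1] = dataclasses.replace(moved, position=(theta * 0.55, phi))
        m2 = t.Montage(tuple(els), 1e-3, "hd_moved")
        _, rep2, _, _ = t.solve_montage(test_head, m2)
        assert abs(rep2.per_electrode_current_A[moved.name]) > 0.25e-3

    def test_equipotential_mode_agrees_with_resistive(self, pad_case):
        cfg = SolverConfig(electrode_mode="equipotential")
        system = assemble_system(pad_case.sigma, pad_case.raster, cfg)
        pot_eq, _ = solve_potential(system, cfg)
        tissue = ~pad_case.head.mask("air")
        rel = np.linalg.norm((pot_eq.V - pad_case.potential.V)[tissue]) / np.linalg.norm(
            pad_case.potential.V[tissue]
        )
        assert rel < 0.01

    def test_maximum_principle_on_phantom(self, pad_case):
        head = pad_case.raster.volume
        deep = head.mask("gray") | head.mask("white") | head.mask("csf")
        V = pad_case.potential.V
        assert V[deep].max() < V.max()
        assert V[deep].min() > V.min()

    def test_disconnected_circuit_detected_before_solve(self):
        raster = t.make_slab_with_plates((40, 40, 24), tissue="gray", voxel_mm=2.0)
        # sever the slab with an air gap
        nz = raster.volume.shape[2]
        raster.volume.labels[:, :, nz // 2] = raster.volume.code("air")
        sigma = t.build_sigma_volume(raster.volume, t.default_table())
        with pytest.raises(DisconnectedCircuitError):
            assemble_system(sigma, raster)

    def test_deterministic_resolve(self, test_head):
        m = t.preset_pad_m1_so(test_head)
        pot1, rep1, _, _ = t.solve_montage(test_head, m)
        pot2, rep2, _, _ = t.solve_montage(test_head, m)
        assert np.array_equal(pot1.V, pot2.V)
        assert rep1.iterations == rep2.iterations
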