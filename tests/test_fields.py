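"""E-field derivation, cortical surface extraction, and surface maps."""

import numpy as np
import pytest

import tdcsim as t
from tdcsim.fields import cortical_map_to_dataframe
from tdcsim.solver import PotentialField


class TestGradientToEfield:
    def test_linear_potential_gives_uniform_field(self):
        n = 12
        z = np.arange(n) * 1.0  # mm
        V = -1e-3 * np.broadcast_to(z, (n, n, n)).copy()  # -1 mV per mm along z
        ef = t.gradient_to_efield(PotentialField(V=V, voxel_mm=1.0))
        interior = ef.E[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior[..., 2], 1.0)
        assert np.allclose(interior[..., 0], 0.0)
        assert np.allclose(ef.magnitude[1:-1, 1:-1, 1:-1], 1.0)

    def test_magnitude_is_euclidean_norm(self):
        rng = np.random.default_rng(0)
        V = rng.normal(size=(8, 8, 8))
        ef = t.gradient_to_efield(PotentialField(V=V, voxel_mm=1.0))
        assert np.allclose(ef.magnitude, np.linalg.norm(ef.E, axis=-1))
        assert (ef.magnitude >= 0).all()

    def test_air_boundary_uses_one_sided_differences(self):
        """A tissue voxel at the scalp edge must not blend air-side values."""
        vol = t.make_slab_phantom((16, 16, 8), tissue="gray", voxel_mm=2.0)
        nx, ny, nz = vol.shape
        z = np.arange(nz) * 2e-3
        V = np.broadcast_to(z, vol.shape).copy()  # 1 V/m slope inside and out
        V[vol.mask("air")] = 99.0  # garbage in air
        ef = t.gradient_to_efield(PotentialField(V=V, voxel_mm=2.0), vol)
        tissue_core = vol.mask("gray")
        # one-sided differencing keeps the slope estimate clean at the edges
        assert np.allclose(ef.magnitude[tissue_core], 1.0)


class TestCorticalSurface:
    def test_sphere_surface_sits_at_gray_outer_radius(self, test_head):
        surf = t.extract_cortical_surface(test_head)
        c = np.asarray(test_head.center_vox)
        r = np.linalg.norm((surf.locations - c) * test_head.voxel_mm, axis=1)
        gray_outer = 70.0 - 6 - 5 - 3
        assert (r < gray_outer).all()
        assert (r >= gray_outer - test_head.voxel_mm).all()

    def test_normals_radial_within_5_degrees(self, fine_head):
        surf = t.extract_cortical_surface(fine_head)
        assert np.allclose(np.linalg.norm(surf.normals, axis=1), 1.0, atol=1e-6)
        c = np.asarray(fine_head.center_vox)
        radial = surf.locations - c
        radial = radial / np.linalg.norm(radial, axis=1, keepdims=True)
        ang = np.degrees(
            np.arccos(np.clip(np.einsum("ij,ij->i", surf.normals, radial), -1, 1))
        )
        assert np.percentile(ang, 95) < 5.0

    def test_gyrated_surface_reaches_fold_troughs(self):
        spec = t.SphereSpec(60, {"skin": 5, "skull": 4, "csf": 6, "gray": 4}, 2.0)
        gy = t.make_gyrated_phantom(spec, t.GyriSpec(4.0, 6, seed=1))
        surf = t.extract_cortical_surface(gy)
        c = np.asarray(gy.center_vox)
        r = np.linalg.norm((surf.locations - c) * gy.voxel_mm, axis=1)
        smooth_gray_outer = spec.shell_outer_radii_mm["gray"]
        assert r.min() < smooth_gray_outer - 2.0

    def test_no_gray_csf_adjacency_is_an_error(self):
        vol = t.make_slab_phantom((20, 20, 10), tissue="gray", voxel_mm=2.0)
        with pytest.raises(ValueError, match="adjacency|CSF"):
            t.extract_cortical_surface(vol)


class TestNormalComponentMap:
    def _radial_field_map(self, head, inward=True):
        surf = t.extract_cortical_surface(head)
        c = np.asarray(head.center_vox)
        E = np.zeros(head.shape + (3,))
        idx = np.indices(head.shape).reshape(3, -1).T
        d = idx - c
        d = d / np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-9)
        sign = -1.0 if inward else 1.0
        E.reshape(-1, 3)[:] = sign * d  # unit radial field
        ef = t.EFieldVolume(E=E, magnitude=np.linalg.norm(E, axis=-1), voxel_mm=head.voxel_mm)
        return t.normal_component_map(ef, surf)

    def test_inward_radial_field_is_fully_positive(self, test_head):
        cmap = self._radial_field_map(test_head, inward=True)
        # E points inward, normals outward: ef_normal = -E.n = +|E|
        assert np.allclose(cmap.ef_normal, cmap.ef_magnitude, atol=0.15)

    def test_tangential_field_has_zero_normal_component(self, test_head):
        surf = t.extract_cortical_surface(test_head)
        c = np.asarray(test_head.center_vox)
        E = np.zeros(test_head.shape + (3,))
        idx = np.indices(test_head.shape).reshape(3, -1).T
        d = (idx - c).astype(float)
        tang = np.stack([-d[:, 1], d[:, 0], np.zeros(len(d))], axis=1)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-9)
        E.reshape(-1, 3)[:] = tang
        ef = t.EFieldVolume(E=E, magnitude=np.linalg.norm(E, axis=-1), voxel_mm=2.0)
        cmap = t.normal_component_map(ef, surf)
        # tangential current has no inward/outward component (normals are
        # near-radial so the residual is the small normal-estimate error)
        assert np.abs(cmap.ef_normal).mean() < 0.1

    def test_normal_component_bounded_by_magnitude(self, hd_case):
        assert (np.abs(hd_case.cmap.ef_normal) <= hd_case.cmap.ef_magnitude + 1e-12).all()

    def test_hd_anode_region_receives_net_inward_current(self, hd_case):
        """Under the ring's center anode the mean normal component is inward
        (positive), the anodal/depolarizing direction."""
        u = hd_case.montage.anode.direction
        c = np.asarray(hd_case.head.center_vox)
        d = hd_case.cmap.locations - c
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        under = d @ u > np.cos(np.deg2rad(10))
        assert under.sum() > 10
        assert hd_case.cmap.ef_normal[under].mean() > 0

    def test_surface_peak_below_gray_volume_peak(self, hd_case):
        gray_peak = hd_case.efield.magnitude[hd_case.head.mask("gray")].max()
        assert hd_case.cmap.ef_magnitude.max() <= gray_peak + 1e-12

    def test_dataframe_export_columns(self, hd_case):
        df = cortical_map_to_dataframe(hd_case.cmap)
        assert list(df.columns) == [
            "x", "y", "z", "nx", "ny", "nz",
            "ef_magnitude_V_per_m", "ef_normal_V_per_m",
        ]
        assert len(df) == len(hd_case.cmap)


class TestCrossSections:
    def test_slicing_partitions_the_grid(self, pad_case):
        V = pad_case.potential.V
        slices = [t.cross_section_slice(pad_case.potential, 0, i).data for i in range(V.shape[0])]
        assert np.array_equal(np.stack(slices, axis=0), V)

    def test_out_of_range_index_rejected(self, pad_case):
        with pytest.raises(IndexError):
            t.cross_section_slice(pad_case.potential, 2, 10_000)

    def test_conductivity_contrast_channels_current_into_csf(self, pad_case):
        """In a slice through the sphere center the CSF annulus carries far
        more current than the adjacent shells: the sigma contrast drives
        current density |J| = sigma |E| into the CSF (the resistive skull
        instead shows large |E| at tiny |J|)."""
        head = pad_case.head
        k = int(head.center_vox[2])
        J = pad_case.efield.magnitude * pad_case.sigma
        sl = t.cross_section_slice(J, 2, k).data
        csf = head.mask("csf")[:, :, k]
        skull = head.mask("skull")[:, :, k]
        gray = head.mask("gray")[:, :, k]
        assert np.median(sl[csf]) > np.median(sl[skull])
        assert np.median(sl[csf]) > np.median(sl[gray])

    def test_rotating_montage_rotates_cortical_map(self, test_head, hd_case):
        """Quarter-turn equivariance on the sphere: solving with the montage
        rotated 90 degrees about the head axis permutes the solution grid."""
        import dataclasses

        rot = tuple(
            dataclasses.replace(e, position=(e.position[0], e.position[1] + np.pi / 2))
            for e in hd_case.montage.electrodes
        )
        m_rot = t.Montage(rot, 1e-3, "hd_rot90")
        pot_rot, _, _, _ = t.solve_montage(test_head, m_rot)
        # rotating the original solution by 90 deg about z: (x,y) -> (-y,x)
        V_pred = np.rot90(hd_case.potential.V, k=1, axes=(0, 1))
        scale = np.linalg.norm(pot_rot.V)
        assert np.linalg.norm(pot_rot.V - V_pred) / scale < 0.02
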