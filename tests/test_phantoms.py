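"""Phantom generators: shell geometry, determinism, volume conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tdcsim as t
from tdcsim.phantoms import LABEL_CODES


def brute_force_shell_counts(spec: t.SphereSpec) -> dict[str, int]:
    """Independent oracle: classify every voxel center by its distance."""
    half = int(np.ceil(spec.outer_radius_mm / spec.voxel_mm)) + 3
    n = 2 * half + 1
    radii = spec.shell_outer_radii_mm
    counts = {k: 0 for k in ("air", "skin", "skull", "csf", "gray", "white")}
    ax = (np.arange(n) - half) * spec.voxel_mm
    # loop over slabs to keep the oracle dumb and obviously correct
    for i in range(n):
        r = np.sqrt(ax[i] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
        for name, lo, hi in (
            ("white", 0.0, radii["white"]),
            ("gray", radii["white"], radii["gray"]),
            ("csf", radii["gray"], radii["csf"]),
            ("skull", radii["csf"], radii["skull"]),
            ("skin", radii["skull"], radii["skin"]),
            ("air", radii["skin"], np.inf),
        ):
            counts[name] += int(((r >= lo) & (r < hi)).sum())
    return counts


class TestLayeredSphere:
    def test_center_is_white_and_outside_is_air(self):
        spec = t.SphereSpec(60, {"skin": 5, "skull": 5, "csf": 3, "gray": 4}, 2.0)
        vol = t.make_layered_sphere_phantom(spec)
        c = tuple(int(v) for v in vol.center_vox)
        assert vol.labels[c] == LABEL_CODES["white"]
        assert vol.labels[0, 0, 0] == LABEL_CODES["air"]
        corner_r = np.linalg.norm(np.array(vol.center_vox)) * spec.voxel_mm
        assert corner_r > spec.outer_radius_mm

    def test_skull_shell_volume_matches_analytic_and_brute_force(self):
        spec = t.SphereSpec(92, {"skin": 7, "skull": 5, "csf": 2, "gray": 3}, 1.0)
        vol = t.make_layered_sphere_phantom(spec)
        analytic = 4 * np.pi / 3 * (85.0**3 - 80.0**3)
        count = vol.count("skull")
        assert abs(count - analytic) / analytic < 0.02
        assert count == brute_force_shell_counts(spec)["skull"]

    @pytest.mark.parametrize(
        "bad_kwargs, match",
        [
            (dict(layer_thicknesses_mm={"skin": -1, "skull": 5, "csf": 2, "gray": 3}), "skin"),
            (dict(layer_thicknesses_mm={"skin": 40, "skull": 40, "csf": 10, "gray": 10}), "outer_radius_mm"),
            (dict(voxel_mm=5.0), "voxel_mm"),
        ],
    )
    def test_invalid_specs_rejected_naming_offender(self, bad_kwargs, match):
        kwargs = dict(
            outer_radius_mm=60.0,
            layer_thicknesses_mm={"skin": 5, "skull": 5, "csf": 3, "gray": 4},
            voxel_mm=1.0,
        )
        kwargs.update(bad_kwargs)
        with pytest.raises(ValueError, match=match):
            t.SphereSpec(**kwargs)

    def test_shell_volumes_converge_with_resolution(self):
        layers = {"skin": 6, "skull": 5, "csf": 3, "gray": 4}
        analytic = {
            "skull": 4 * np.pi / 3 * (64.0**3 - 59.0**3),
            "csf": 4 * np.pi / 3 * (59.0**3 - 56.0**3),
        }
        errs = []
        for h in (2.0, 1.0, 0.5):
            vol = t.make_layered_sphere_phantom(t.SphereSpec(70, layers, h))
            err = max(
                abs(vol.count(k) * h**3 - analytic[k]) / analytic[k] for k in analytic
            )
            errs.append(err)
        assert errs[0] >= errs[1] >= errs[2]

    def test_volume_conservation_and_determinism(self):
        spec = t.SphereSpec(52, {"skin": 5, "skull": 4, "csf": 3, "gray": 4}, 2.0)
        a = t.make_layered_sphere_phantom(spec)
        b = t.make_layered_sphere_phantom(spec)
        assert np.array_equal(a.labels, b.labels)
        total = sum(a.count(k) for k in ("air", "skin", "skull", "csf", "gray", "white"))
        assert total == a.labels.size

    def test_radial_nesting_order(self, fine_head):
        """Along any ray from the center, labels appear white -> gray -> csf
        -> skull -> skin -> air with no inversions."""
        order = {LABEL_CODES[k]: i for i, k in enumerate(
            ("white", "gray", "csf", "skull", "skin", "air"))}
        rng = np.random.default_rng(7)
        c = np.asarray(fine_head.center_vox)
        n = fine_head.shape[0]
        for _ in range(40):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            steps = np.arange(0, n // 2, 0.5)
            ijk = np.round(c + steps[:, None] * d).astype(int)
            ijk = ijk[(ijk >= 0).all(1) & (ijk < n).all(1)]
            ranks = [order[int(fine_head.labels[tuple(p)])] for p in ijk]
            assert all(a <= b for a, b in zip(ranks, ranks[1:]))


class TestGyratedPhantom:
    SPEC = t.SphereSpec(60, {"skin": 5, "skull": 4, "csf": 6, "gray": 4}, 2.0)

    def test_zero_amplitude_degenerates_to_smooth_sphere(self):
        smooth = t.make_layered_sphere_phantom(self.SPEC)
        gy = t.make_gyrated_phantom(self.SPEC, t.GyriSpec(0.0, 6, seed=3))
        assert np.array_equal(smooth.labels, gy.labels)

    def test_seeds_differ_but_gray_volume_is_stable(self):
        g1 = t.make_gyrated_phantom(self.SPEC, t.GyriSpec(4.0, 6, seed=1))
        g2 = t.make_gyrated_phantom(self.SPEC, t.GyriSpec(4.0, 6, seed=2))
        assert not np.array_equal(g1.labels, g2.labels)
        c1, c2 = g1.count("gray"), g2.count("gray")
        assert abs(c1 - c2) / c1 < 0.05

    def test_determinism_per_seed(self):
        g1 = t.make_gyrated_phantom(self.SPEC, t.GyriSpec(4.0, 6, seed=9))
        g2 = t.make_gyrated_phantom(self.SPEC, t.GyriSpec(4.0, 6, seed=9))
        assert np.array_equal(g1.labels, g2.labels)

    def test_fold_amplitude_bounded_by_csf_plus_gray(self):
        with pytest.raises(ValueError, match="fold_amplitude"):
            t.make_gyrated_phantom(self.SPEC, t.GyriSpec(10.5, 6, seed=0))

    def test_nesting_holds_outside_the_fold_band(self):
        gy = t.make_gyrated_phantom(self.SPEC, t.GyriSpec(4.0, 6, seed=1))
        radii = self.SPEC.shell_outer_radii_mm
        c = np.asarray(gy.center_vox)
        idx = np.indices(gy.shape).reshape(3, -1).T
        r = np.linalg.norm((idx - c) * gy.voxel_mm, axis=1).reshape(gy.shape)
        # outside the modulated band the labels match the smooth sphere
        smooth = t.make_layered_sphere_phantom(self.SPEC)
        band = (r >= radii["white"] - 4.0) & (r < radii["gray"] + 4.0)
        assert np.array_equal(gy.labels[~band], smooth.labels[~band])

    def test_volume_conservation(self):
        gy = t.make_gyrated_phantom(self.SPEC, t.GyriSpec(4.0, 8, seed=5))
        total = sum(gy.count(k) for k in gy.label_codes)
        assert total == gy.labels.size


class TestSlabPhantom:
    def test_interior_uniform_and_padded_by_air(self):
        vol = t.make_slab_phantom((100, 100, 50), tissue="gray", voxel_mm=2.0)
        assert (vol.labels[1:-1, 1:-1, 1:-1] == LABEL_CODES["gray"]).all()
        assert (vol.labels[0] == LABEL_CODES["air"]).all()
        assert vol.count("gray") == 50 * 50 * 25

    def test_csf_slab_maps_to_csf_conductivity(self):
        vol = t.make_slab_phantom((40, 40, 20), tissue="csf", voxel_mm=2.0)
        sigma = t.build_sigma_volume(vol, t.default_table())
        assert np.allclose(sigma[1:-1, 1:-1, 1:-1], 1.65)

    def test_rejects_nonpositive_extent(self):
        with pytest.raises(ValueError):
            t.make_slab_phantom((100, -1, 50))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    outer=st.floats(45, 75),
    skin=st.floats(3, 7),
    skull=st.floats(3, 7),
    csf=st.floats(2, 5),
    gray=st.floats(2, 5),
)
def test_volume_conservation_property(outer, skin, skull, csf, gray):
    spec = t.SphereSpec(
        outer, {"skin": skin, "skull": skull, "csf": csf, "gray": gray}, 2.0
    )
    vol = t.make_layered_sphere_phantom(spec)
    assert sum(vol.count(k) for k in vol.label_codes) == vol.labels.size
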