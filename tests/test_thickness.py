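"""Thickness of binary volumes: 2V/S summaries, local thickness maps,
exact rank tests."""

import numpy as np
import pytest
from scipy import ndimage

from chondromorph.synth import PhantomSpec, generate_phantom
from chondromorph.thickness import (
    BOUNDARY_MODES,
    BinaryVolume,
    average_object_thickness,
    compare_groups,
    local_thickness_map,
)


def brute_force_thickness(vol: BinaryVolume, boundary: str) -> np.ndarray:
    """Exhaustive inscribed-ball oracle, independent of the propagation code.

    For every foreground voxel v take its distance-map radius R (same
    boundary convention), and assign diameter 2R to every voxel whose center
    lies within R of v; each voxel keeps the largest diameter received.
    """
    from chondromorph.thickness import _squared_distance_maps

    fg = vol.occupancy
    a2, b2 = _squared_distance_maps(fg)
    if boundary == "included":
        b2 = a2
    elif boundary == "excluded":
        a2 = b2
    out = np.zeros(fg.shape)
    coords = np.argwhere(fg)
    for v in coords:
        a = int(a2[tuple(v)])
        b = int(b2[tuple(v)])
        radius = (np.sqrt(a) + np.sqrt(b)) / 2.0
        diam = 2.0 * radius
        for w in coords:
            m2 = int(((w - v) ** 2).sum())
            L = 4 * m2 - a - b
            if (L <= 0 or L * L <= 4 * a * b) and out[tuple(w)] < diam:
                out[tuple(w)] = diam
    return out * vol.spacing


def random_blob(rng, size=14):
    noise = rng.random((size, size, size)) > 0.55
    blob = ndimage.binary_closing(noise, iterations=1)
    blob = ndimage.binary_opening(blob, iterations=1)
    if not blob.any():
        blob[size // 2, size // 2, size // 2] = True
    return BinaryVolume(occupancy=blob, spacing=1.0)


class TestAverageThickness:
    def test_sphere_parallel_plate(self):
        vol = generate_phantom(PhantomSpec("solid_sphere", grid=(47, 47, 47),
                                           radius=20))
        s = average_object_thickness(vol)
        assert s.average_thickness == pytest.approx(2 * 20 / 3, rel=0.05)
        assert s.average_thickness == pytest.approx(
            2 * s.volume / s.surface_area, rel=1e-12)

    def test_slab_parallel_plate_large_aspect(self):
        vol = generate_phantom(PhantomSpec("slab", grid=(18, 800, 800),
                                           thickness=10))
        s = average_object_thickness(vol)
        assert s.average_thickness == pytest.approx(10.0, rel=0.03)

    def test_slab_rim_contribution_documented(self):
        # at 200x200 the rim adds ~10% of the surface, pulling 2V/S well
        # below the plate value — the reason the large-aspect slab is used
        vol = generate_phantom(PhantomSpec("slab", grid=(18, 200, 200),
                                           thickness=10))
        s = average_object_thickness(vol)
        assert 8.5 < s.average_thickness < 9.6

    def test_voxel_faces_overestimates_surface(self):
        vol = generate_phantom(PhantomSpec("solid_sphere", grid=(47, 47, 47),
                                           radius=20))
        mesh = average_object_thickness(vol, "mesh")
        faces = average_object_thickness(vol, "voxel_faces")
        assert faces.surface_area > mesh.surface_area
        assert faces.surface_area < 1.6 * mesh.surface_area

    def test_spacing_scales_thickness(self):
        vol = generate_phantom(PhantomSpec("solid_sphere", grid=(25, 25, 25),
                                           radius=8, spacing=6.49))
        unit = generate_phantom(PhantomSpec("solid_sphere", grid=(25, 25, 25),
                                            radius=8, spacing=1.0))
        a = average_object_thickness(vol)
        b = average_object_thickness(unit)
        assert a.average_thickness == pytest.approx(6.49 * b.average_thickness,
                                                    rel=1e-6)

    def test_convergence_to_continuum(self):
        errs = []
        for r in (10, 20):
            vol = generate_phantom(PhantomSpec(
                "solid_sphere", grid=(2 * r + 7,) * 3, radius=r))
            s = average_object_thickness(vol)
            errs.append(abs(s.average_thickness / (2 * r / 3) - 1))
        assert errs[1] < errs[0] < 0.05

    def test_empty_volume_errors(self):
        vol = BinaryVolume(occupancy=np.zeros((5, 5, 5), bool), spacing=1.0)
        with pytest.raises(ValueError, match="foreground"):
            average_object_thickness(vol)


class TestLocalThicknessMap:
    def test_slab_interior_values(self):
        vol = generate_phantom(PhantomSpec("slab", grid=(20, 60, 60),
                                           thickness=10))
        interior = {}
        for mode in BOUNDARY_MODES:
            tm = local_thickness_map(vol, mode)
            vals = tm.values[:, 25:35, 25:35]
            interior[mode] = np.unique(vals[vals > 0])
        np.testing.assert_array_equal(interior["included"], [10.0])
        np.testing.assert_array_equal(interior["excluded"], [8.0])
        np.testing.assert_array_equal(interior["averaged"], [9.0])

    def test_sphere_max_is_diameter(self):
        vol = generate_phantom(PhantomSpec("solid_sphere", grid=(37, 37, 37),
                                           radius=15))
        tm = local_thickness_map(vol)
        assert abs(tm.values.max() - 30.0) <= 1.0

    def test_single_voxel_limiting_case(self):
        occ = np.zeros((7, 7, 7), bool)
        occ[3, 3, 3] = True
        vol = BinaryVolume(occupancy=occ, spacing=1.0)
        vals = {m: local_thickness_map(vol, m).values[3, 3, 3]
                for m in BOUNDARY_MODES}
        assert vals["excluded"] == 0.0
        assert vals["averaged"] == pytest.approx(1.0)
        assert vals["included"] == pytest.approx(2.0)
        assert vals["excluded"] < vals["averaged"] < vals["included"]

    def test_map_zero_exactly_off_foreground(self):
        vol = generate_phantom(PhantomSpec("solid_sphere", grid=(17, 17, 17),
                                           radius=5))
        tm = local_thickness_map(vol)
        assert np.all(tm.values[~vol.occupancy] == 0)
        assert np.all(tm.values[vol.occupancy] > 0)

    @pytest.mark.parametrize("boundary", BOUNDARY_MODES)
    def test_matches_brute_force_oracle(self, boundary, rng):
        for _ in range(3):
            vol = random_blob(rng)
            got = local_thickness_map(vol, boundary).values
            expected = brute_force_thickness(vol, boundary)
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_invariant_to_rotation_and_padding(self, rng):
        vol = random_blob(rng)
        base = local_thickness_map(vol).values
        rotated = BinaryVolume(np.rot90(vol.occupancy, axes=(1, 2)).copy(),
                               spacing=1.0)
        np.testing.assert_allclose(local_thickness_map(rotated).values,
                                   np.rot90(base, axes=(1, 2)), atol=1e-9)
        padded = BinaryVolume(np.pad(vol.occupancy, 4), spacing=1.0)
        np.testing.assert_allclose(
            local_thickness_map(padded).values[4:-4, 4:-4, 4:-4],
            base, atol=1e-9)

    def test_dilation_monotonicity(self, rng):
        vol = random_blob(rng)
        base = local_thickness_map(vol).values
        grown = BinaryVolume(ndimage.binary_dilation(vol.occupancy),
                             spacing=1.0)
        bigger = local_thickness_map(grown).values
        assert np.all(bigger[vol.occupancy] >= base[vol.occupancy] - 1e-9)

    def test_hollow_shell_thickness(self):
        vol = generate_phantom(PhantomSpec("hollow_shell", grid=(71, 71, 71),
                                           radius=30, thickness=6))
        tm = local_thickness_map(vol)
        med = np.median(tm.foreground_values())
        assert abs(med - 6.0) <= 1.0

    def test_curved_rod_thickness_is_tube_diameter(self):
        vol = generate_phantom(PhantomSpec("curved_rod", grid=(15, 45, 45),
                                           arc_radius=14, tube_radius=4,
                                           arc_degrees=270))
        tm = local_thickness_map(vol)
        med = np.median(tm.foreground_values())
        assert abs(med - 8.0) <= 1.0


class TestCompareGroups:
    def test_textbook_example(self):
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("n1, n2, expected", [
        (5, 4, 2 / 126),
        (5, 6, 2 / 462),
    ])
    def test_fully_separated_small_groups(self, n1, n2, expected):
        a = list(range(100, 100 + n1))
        b = list(range(n2))
        res = compare_groups(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        assert compare_groups(b, a).p_value == pytest.approx(expected,
                                                             rel=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(0.7, size=5)
            ours = compare_groups(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.u == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            res = compare_groups([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_ties_handled_by_midranks(self):
        res = compare_groups([1, 2, 2, 3], [2, 4, 5])
        assert res.method == "exact"
        assert 0 < res.p_value <= 1

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="nonempty"):
            compare_groups([], [1.0])
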