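"""Shape measurements: volume, diameter, area, sphericity, NOD, invariants."""

import numpy as np
import pytest

from adipo3d import (
    equivalent_diameter,
    measure_all,
    measure_surface_area,
    measure_volume,
    nearest_object_distance,
    sphericity,
    total_object_volume,
)
from adipo3d.morphometry import NODUndefinedError
from adipo3d.volumes import ParameterError

from conftest import rasterize_sphere

ISO = (1.0, 1.0, 1.0)
LIGHTSHEET_VOXEL = (1.62, 1.62, 4.0)


def brute_force_nod(points):
    points = np.asarray(points, float)
    out = []
    for i, p in enumerate(points):
        d = [np.linalg.norm(p - q) for j, q in enumerate(points) if j != i]
        out.append(min(d))
    return np.array(out)


class TestMeasureVolume:
    def test_single_voxel_lightsheet_geometry(self):
        labels = np.zeros((3, 3, 3), np.int32)
        labels[1, 1, 1] = 1
        v = measure_volume(labels, LIGHTSHEET_VOXEL)
        assert v[1] == pytest.approx(10.4976)

    def test_cube_isotropic(self):
        labels = np.zeros((12, 12, 12), np.int32)
        labels[1:11, 1:11, 1:11] = 1
        assert measure_volume(labels, ISO)[1] == 1000.0

    def test_rasterized_sphere_close_to_analytic(self):
        mask = rasterize_sphere(40.0, LIGHTSHEET_VOXEL)
        v = measure_volume(mask.astype(np.int32), LIGHTSHEET_VOXEL)
        assert v[1] == pytest.approx(268_082.57, rel=0.03)


class TestEquivalentDiameter:
    @pytest.mark.parametrize(
        "volume, expected",
        [
            (523_598.776, 100.0),       # sphere of radius 50 µm
            (1.0, (6.0 / np.pi) ** (1.0 / 3.0)),
            (299_242.0, 82.99),          # healthy/obese scale check
        ],
    )
    def test_closed_form(self, volume, expected):
        assert equivalent_diameter(volume) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            equivalent_diameter(0.0)


class TestSurfaceArea:
    def test_sphere_r20_isotropic(self):
        mask = rasterize_sphere(20.0, ISO).astype(np.int32)
        a = measure_surface_area(mask, ISO)[1]
        assert a == pytest.approx(4 * np.pi * 400.0, rel=0.03)

    def test_cube_side_40(self):
        labels = np.zeros((50, 50, 50), np.int32)
        labels[5:45, 5:45, 5:45] = 1
        a = measure_surface_area(labels, ISO)[1]
        assert a == pytest.approx(9600.0, rel=0.05)

    def test_sphere_r20_anisotropic(self):
        mask = rasterize_sphere(20.0, LIGHTSHEET_VOXEL).astype(np.int32)
        a = measure_surface_area(mask, LIGHTSHEET_VOXEL)[1]
        assert a == pytest.approx(4 * np.pi * 400.0, rel=0.08)

    def test_too_thin_object_flagged_nan(self):
        labels = np.zeros((5, 5, 5), np.int32)
        labels[2, 2, :] = 1  # 1-voxel-thick line
        a = measure_surface_area(labels, ISO)
        assert np.isnan(a[1])


class TestSphericity:
    def test_analytic_sphere_is_one(self):
        r = 17.3
        v, a = 4.0 / 3.0 * np.pi * r**3, 4.0 * np.pi * r**2
        assert sphericity(v, a) == pytest.approx(1.0, abs=1e-12)

    def test_cube_closed_form(self):
        a_side = 3.7
        psi = sphericity(a_side**3, 6 * a_side**2)
        assert psi == pytest.approx((np.pi / 6.0) ** (1.0 / 3.0), abs=1e-12)

    def test_prolate_spheroid_against_analytic_area(self):
        # semi-axes (a, a, c) = (1, 1, 2): analytic prolate surface area
        a_ax, c_ax = 1.0, 2.0
        e = np.sqrt(1 - (a_ax / c_ax) ** 2)
        area = 2 * np.pi * a_ax**2 * (1 + (c_ax / (a_ax * e)) * np.arcsin(e))
        vol = 4.0 / 3.0 * np.pi * a_ax**2 * c_ax
        assert sphericity(vol, area) == pytest.approx(0.929, abs=0.001)

    def test_measured_spheroid_matches_analytic(self):
        zz, yy, xx = np.ogrid[:100, :100, :100]
        mask = ((((zz - 50) / 30.0) ** 2 + ((yy - 50) / 15.0) ** 2
                 + ((xx - 50) / 15.0) ** 2) <= 1).astype(np.int32)
        v = measure_volume(mask, ISO)[1]
        a = measure_surface_area(mask, ISO)[1]
        assert sphericity(v, a) == pytest.approx(0.929, abs=0.02)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            sphericity(-1.0, 10.0)


class TestNOD:
    def test_two_points_symmetric(self):
        nod = nearest_object_distance([(0, 0, 0), (10, 0, 0)])
        np.testing.assert_allclose(nod, [10.0, 10.0])

    def test_three_point_example(self):
        nod = nearest_object_distance([(0, 0, 0), (3, 4, 0), (10, 0, 0)])
        np.testing.assert_allclose(nod, [5.0, 5.0, 8.0622577], rtol=1e-6)

    def test_single_point_undefined(self):
        with pytest.raises(NODUndefinedError):
            nearest_object_distance([(0, 0, 0)])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 500, size=(rng.integers(2, 40), 3))
        np.testing.assert_allclose(
            nearest_object_distance(pts), brute_force_nod(pts), rtol=1e-12
        )


class TestTotalObjectVolume:
    def test_empty_mask_zero(self):
        assert total_object_volume(np.zeros((4, 4, 4), np.int32), ISO) == 0.0

    def test_conservation_with_per_label_volumes(self, five_sphere_phantom):
        ph = five_sphere_phantom
        per_label = measure_volume(ph.labels.data, ph.image.voxel_size)
        total = total_object_volume(ph.labels.data, ph.image.voxel_size)
        assert per_label.sum() == total  # exact, both are voxel counts x voxvol

    def test_ecm_shell_volume_close_to_analytic(self):
        # fine isotropic grid so the 4 µm shell is well resolved
        from adipo3d import GeneratorParams, generate_phantom
        from conftest import NO_OPTICS

        params = GeneratorParams(
            n_cells=3, domain_size=(220.0, 220.0, 140.0), volume_mean=100_000.0,
            volume_cv=0.2, ecm_gap=4.0, voxel_size=(1.5, 1.5, 1.5), seed=17,
            **NO_OPTICS,
        )
        ph = generate_phantom(params)
        ecm_mask = ph.image.channel("ecm") > 0.5
        measured = total_object_volume(ecm_mask.astype(np.int32), ph.image.voxel_size)
        # analytic shell: sum over cells of (4/3)π[(r+gap)³ - r³]; cells are
        # far enough apart here that shells do not overlap
        analytic = sum(
            4.0 / 3.0 * np.pi * ((c.true_radius + 4.0) ** 3 - c.true_radius**3)
            for c in ph.cells
        )
        assert measured == pytest.approx(analytic, rel=0.10)


class TestMeasureAll:
    def test_five_sphere_feature_table(self, five_sphere_phantom):
        ph = five_sphere_phantom
        df = measure_all(ph.labels.data, ph.image.voxel_size)
        assert len(df) == 5
        # internal consistency of d_eq with V via the closed form
        np.testing.assert_allclose(
            df["equivalent_diameter_um"],
            (6 * df["volume_um3"] / np.pi) ** (1 / 3),
            rtol=1e-9,
        )
        # against generator ground truth (all radii >= 5 voxels here)
        true = {c.label_id: c.true_volume for c in ph.cells}
        for _, row in df.iterrows():
            assert row["volume_um3"] == pytest.approx(true[row["label_id"]], rel=0.03)

    def test_two_object_nod_equals_centroid_distance(self):
        labels = np.zeros((10, 10, 30), np.int32)
        labels[4:6, 4:6, 2:4] = 1
        labels[4:6, 4:6, 20:22] = 2
        df = measure_all(labels, ISO)
        c = df[["centroid_x_um", "centroid_y_um", "centroid_z_um"]].to_numpy()
        d = np.linalg.norm(c[0] - c[1])
        np.testing.assert_allclose(df["nod_um"], [d, d])

    def test_translation_invariance(self):
        mask = rasterize_sphere(8.0, ISO).astype(np.int32)
        big = np.zeros((40, 40, 40), np.int32)
        big[2 : 2 + mask.shape[0], 3 : 3 + mask.shape[1], 4 : 4 + mask.shape[2]] = mask
        shifted = np.roll(big, (5, 6, 7), axis=(0, 1, 2))
        df1 = measure_all(big, ISO)
        df2 = measure_all(shifted, ISO)
        for col in ("volume_um3", "equivalent_diameter_um", "surface_area_um2"):
            assert df1[col][0] == pytest.approx(df2[col][0], rel=1e-9)
        # centroids shift by exactly the translation (x, y, z) = (7, 6, 5)
        assert df2["centroid_x_um"][0] - df1["centroid_x_um"][0] == pytest.approx(7.0)
        assert df2["centroid_y_um"][0] - df1["centroid_y_um"][0] == pytest.approx(6.0)
        assert df2["centroid_z_um"][0] - df1["centroid_z_um"][0] == pytest.approx(5.0)

    def test_scaling_law(self):
        small = rasterize_sphere(8.0, ISO).astype(np.int32)
        large = rasterize_sphere(16.0, ISO).astype(np.int32)
        d_small = measure_all(small, ISO)
        d_large = measure_all(large, ISO)
        s = 2.0
        assert d_large["volume_um3"][0] == pytest.approx(
            s**3 * d_small["volume_um3"][0], rel=0.02
        )
        assert d_large["surface_area_um2"][0] == pytest.approx(
            s**2 * d_small["surface_area_um2"][0], rel=0.02
        )
        assert d_large["sphericity"][0] == pytest.approx(
            d_small["sphericity"][0], abs=0.02
        )

    def test_sphere_attains_maximal_sphericity(self):
        zz, yy, xx = np.ogrid[:100, :100, :100]
        sphere = ((zz - 50) ** 2 + (yy - 50) ** 2 + (xx - 50) ** 2 <= 400).astype(np.int32)
        cube = np.zeros((40, 40, 40), np.int32)
        cube[4:36, 4:36, 4:36] = 1
        spheroid = ((((zz - 50) / 40.0) ** 2 + ((yy - 50) / 13.0) ** 2
                     + ((xx - 50) / 13.0) ** 2) <= 1).astype(np.int32)
        psis = {
            name: measure_all(arr, ISO)["sphericity"][0]
            for name, arr in (("sphere", sphere), ("cube", cube), ("spheroid", spheroid))
        }
        assert psis["sphere"] > psis["cube"]
        assert psis["sphere"] > psis["spheroid"]

    def test_empty_labels_empty_table(self):
        df = measure_all(np.zeros((4, 4, 4), np.int32), ISO)
        assert df.empty
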