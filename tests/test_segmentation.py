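"""Segmentation chain: thresholding, opening, watershed separation, filtering."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from adipo3d import (
    SegmentationConfig,
    binarize,
    circular_open,
    filter_objects,
    segment,
    separate_objects,
    zstack_average,
)
from adipo3d.segmentation import ThresholdError
from adipo3d.volumes import ParameterError

from conftest import rasterize_sphere

ISO = (1.0, 1.0, 1.0)
NO_CORR = SegmentationConfig(depth_correction="none")


def brute_force_otsu(values):
    """Exhaustive threshold search maximizing between-class variance."""
    values = np.sort(values.ravel())
    best_t, best_var = None, -1.0
    for t in np.unique(values)[:-1]:
        lo, hi = values[values <= t], values[values > t]
        w0, w1 = len(lo) / len(values), len(hi) / len(values)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestBinarize:
    def test_two_level_image_split_between_modes(self):
        # half the voxels at 10, half at 200, in a solid block (no enclosed
        # holes, so hole filling is a no-op)
        img = np.full((12, 12, 12), 10.0)
        img[:6] = 200.0
        mask = binarize(img, NO_CORR)
        # oracle: exhaustive between-class variance search lands between modes
        t = brute_force_otsu(img)
        assert 10.0 <= t < 200.0
        np.testing.assert_array_equal(mask, img > t)

    def test_constant_input_raises(self):
        with pytest.raises(ThresholdError):
            binarize(np.full((5, 5, 5), 3.0), NO_CORR)

    def test_noise_free_sphere_mask_matches_rasterization(self, five_sphere_phantom):
        ph = five_sphere_phantom
        mask = binarize(ph.image.channel("lipid"), NO_CORR, ph.image.voxel_size)
        true = ph.labels.data > 0
        assert abs(mask.sum() - true.sum()) <= 0.03 * true.sum()

    def test_holes_are_filled(self):
        img = np.zeros((10, 10, 10))
        img[2:8, 2:8, 2:8] = 1.0
        img[5, 5, 5] = 0.0  # enclosed hole
        mask = binarize(img, NO_CORR)
        assert mask[5, 5, 5]


class TestCircularOpen:
    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(1)
        mask = rng.random((10, 10, 10)) < 0.3
        np.testing.assert_array_equal(circular_open(mask, 0.0, ISO), mask)

    def test_removes_thin_tube_keeps_sphere(self):
        # sphere r=10 voxels with an attached 3-voxel-wide tube; radius-4 open
        grid = np.zeros((30, 30, 60), dtype=bool)
        zz, yy, xx = np.ogrid[:30, :30, :60]
        sphere = (zz - 15) ** 2 + (yy - 15) ** 2 + (xx - 15) ** 2 <= 100
        tube = (np.abs(zz - 15) <= 1) & (np.abs(yy - 15) <= 1) & (xx >= 15) & (xx < 55)
        grid |= sphere | tube
        opened = circular_open(grid, 4.0, ISO)
        # oracle: brute-force erosion-then-dilation with the same ball
        ball = np.zeros((9, 9, 9), dtype=bool)
        bz, by, bx = np.ogrid[-4:5, -4:5, -4:5]
        ball[(bz**2 + by**2 + bx**2) <= 16] = True
        expected = ndi.binary_dilation(ndi.binary_erosion(grid, ball), ball)
        np.testing.assert_array_equal(opened, expected)
        assert not opened[15, 15, 50]  # tube gone
        assert opened[15, 15, 15]  # sphere body retained

    @pytest.mark.parametrize("seed", range(5))
    def test_anti_extensive_idempotent_monotone(self, seed):
        rng = np.random.default_rng(seed)
        blob = ndi.binary_closing(ndi.binary_opening(rng.random((25, 25, 25)) < 0.5))
        prev = None
        for r in (0.0, 1.0, 2.0, 3.0, 5.0):
            cur = circular_open(blob, r, ISO)
            assert (cur <= blob).all()  # anti-extensive
            np.testing.assert_array_equal(circular_open(cur, r, ISO), cur)  # idempotent
            if prev is not None:
                assert (cur <= prev).all()  # monotone in radius
            prev = cur


class TestSeparateObjects:
    def test_two_overlapping_spheres_split(self):
        # centers 36 µm apart, radius 20 µm: union is a single blob
        grid_shape = (60, 60, 100)
        zz, yy, xx = np.ogrid[:60, :60, :100]
        c1, c2 = np.array([30, 30, 30]), np.array([30, 30, 66])
        mask = ((zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2 <= 400) | (
            (zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2 <= 400
        )
        assert ndi.label(mask)[1] == 1  # truly connected
        labels = separate_objects(mask, ISO, SegmentationConfig(h_maxima=4.0))
        assert labels.max() == 2
        coms = np.array(ndi.center_of_mass(mask, labels, [1, 2]))
        d = np.linalg.norm(coms[:, None, :] - np.array([c1, c2])[None], axis=2)
        # each basin centroid within 2 µm of one true center, one-to-one
        assert d.min(axis=1).max() < 2.0
        assert set(np.argmin(d, axis=1)) == {0, 1}

    def test_single_sphere_single_label(self):
        mask = rasterize_sphere(20.0, ISO)
        labels = separate_objects(mask, ISO)
        assert labels.max() == 1

    def test_empty_mask_empty_labels(self):
        labels = separate_objects(np.zeros((5, 5, 5), bool), ISO)
        assert labels.max() == 0

    def test_covers_mask(self, five_sphere_phantom):
        ph = five_sphere_phantom
        mask = ph.labels.data > 0
        labels = separate_objects(mask, ph.image.voxel_size)
        covered = (labels > 0).sum()
        assert covered >= 0.99 * mask.sum()
        assert not (labels[~mask] > 0).any()  # union of labels within the mask


class TestFilterObjects:
    def test_identity_when_disabled(self):
        labels = np.zeros((6, 6, 6), np.int32)
        labels[1:3, 1:3, 1:3] = 1
        labels[4:6, 4:6, 4:6] = 2  # touches the border
        cfg = SegmentationConfig(min_volume=0.0, border_policy="keep")
        np.testing.assert_array_equal(filter_objects(labels, ISO, cfg), labels)

    def test_border_touching_removed(self):
        labels = np.zeros((20, 20, 20), np.int32)
        labels[5:10, 5:10, 5:10] = 1  # interior, 125 voxels
        labels[0:4, 0:4, 0:4] = 2  # touches boundary
        cfg = SegmentationConfig(min_volume=0.0, border_policy="exclude_touching")
        out = filter_objects(labels, ISO, cfg)
        assert out.max() == 1
        assert (out[5:10, 5:10, 5:10] == 1).all()

    def test_min_volume_threshold(self):
        labels = np.zeros((40, 40, 40), np.int32)
        labels[1:3, 1:3, 1:3] = 1       # 8 voxels
        labels[10:14, 10:14, 10:14] = 2  # 64 voxels
        labels[20:28, 20:28, 20:28] = 3  # 512 voxels
        cfg = SegmentationConfig(min_volume=50.0, border_policy="keep")
        out = filter_objects(labels, ISO, cfg)
        assert set(np.unique(out)) == {0, 1, 2}  # relabeled contiguously
        assert (out > 0).sum() == 64 + 512


class TestSegment:
    def test_five_sphere_recovery(self, five_sphere_phantom):
        ph = five_sphere_phantom
        cfg = SegmentationConfig(depth_correction="none")
        labels, log = segment(ph.image, cfg)
        assert labels.data.max() == 5
        coms = np.array(
            ndi.center_of_mass(labels.data > 0, labels.data, list(range(1, 6)))
        )
        dz, dy, dx = (
            ph.image.voxel_size[2], ph.image.voxel_size[1], ph.image.voxel_size[0],
        )
        found = coms * np.array([dz, dy, dx])
        true = np.array([[c.true_centroid[2], c.true_centroid[1], c.true_centroid[0]]
                         for c in ph.cells])
        d = np.linalg.norm(found[:, None] - true[None], axis=2)
        assert (d.min(axis=1) < 3.0).all()
        assert sorted(np.argmin(d, axis=1)) == list(range(5))
        assert log["final_objects"] == 5

    def test_min_volume_above_all_cells_gives_zero(self, five_sphere_phantom):
        cfg = SegmentationConfig(min_volume=1e9, depth_correction="none")
        labels, _ = segment(five_sphere_phantom.image, cfg)
        assert labels.data.max() == 0

    def test_default_noise_object_count(self, noisy_phantom_50):
        labels, _ = segment(noisy_phantom_50.image, SegmentationConfig())
        n = labels.data.max()
        assert abs(n - 50) <= 0.05 * 50

    def test_deterministic(self, noisy_phantom_50):
        l1, _ = segment(noisy_phantom_50.image, SegmentationConfig())
        l2, _ = segment(noisy_phantom_50.image, SegmentationConfig())
        np.testing.assert_array_equal(l1.data, l2.data)


class TestZStackAverage:
    def test_window_one_is_identity(self):
        stack = np.random.default_rng(0).random((6, 4, 4))
        np.testing.assert_allclose(zstack_average(stack, 1), stack)

    def test_constant_stack_stays_constant(self):
        stack = np.full((9, 3, 3), 2.5)
        out = zstack_average(stack, 5)
        np.testing.assert_allclose(out, 2.5)

    def test_output_depth(self):
        stack = np.zeros((9, 2, 2))
        assert zstack_average(stack, 5).shape[0] == 5

    def test_window_exceeding_depth_rejected(self):
        with pytest.raises(ParameterError):
            zstack_average(np.zeros((3, 2, 2)), 4)
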