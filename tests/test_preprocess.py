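"""Normalization statistics, target transformation and patch cropping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from somaseg.preprocess import (
    DegenerateInputError,
    NormalizationStats,
    compute_stats,
    crop_patches,
    make_training_targets,
    patch_origins,
    zscore_normalize,
)

S26 = np.ones((3, 3, 3), dtype=bool)


class TestComputeStats:
    def test_pooled_mean_and_population_std(self):
        stats = compute_stats([np.array([[[0.0, 2.0], [4.0, 6.0]]])])
        assert stats.mean == pytest.approx(3.0)
        assert stats.std == pytest.approx(np.sqrt(5.0))
        assert stats.n_voxels == 4

    def test_pooling_across_volumes(self):
        a = np.zeros((2, 2, 2))
        b = np.full((2, 2, 2), 6.0)
        stats = compute_stats([a, b])
        assert stats.mean == pytest.approx(3.0)
        assert stats.std == pytest.approx(3.0)
        assert stats.n_voxels == 16

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_stats([np.ones((2, 2, 2)), np.ones((1, 1, 1))])
        with pytest.raises(DegenerateInputError):
            compute_stats([np.array([[[5.0]]])])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_stats([])


class TestZscore:
    def test_known_arithmetic(self):
        stats = NormalizationStats(mean=3.0, std=2.0, n_voxels=4)
        out = zscore_normalize(np.array([[[0.0, 2.0, 4.0, 6.0]]]), stats)
        np.testing.assert_allclose(out, [[[-1.5, -0.5, 0.5, 1.5]]])

    def test_constant_volume_maps_to_zero(self):
        stats = NormalizationStats(mean=7.0, std=2.0, n_voxels=1)
        assert not zscore_normalize(np.full((3, 3, 3), 7.0), stats).any()

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.normal(10, 5, size=(4, 5, 6))
        stats = compute_stats([vol])
        back = zscore_normalize(vol, stats) * stats.std + stats.mean
        np.testing.assert_allclose(back, vol, atol=1e-4)

    def test_self_normalization_standardizes(self):
        rng = np.random.default_rng(0)
        vol = rng.gamma(2.0, 50.0, size=(8, 8, 8))
        stats = compute_stats([vol])
        out = zscore_normalize(vol, stats)
        assert abs(out.mean()) < 1e-5
        assert abs(out.std() - 1.0) < 1e-5


class TestTrainingTargets:
    def test_empty_labels(self):
        t = make_training_targets(np.zeros((4, 4, 4), dtype=int))
        assert not t.soma.any() and not t.boundary.any()

    def test_single_cube_shell_and_core(self):
        """A 5^3 cube: 2-voxel-thick boundary shell, single-voxel soma core,
        verified against a brute-force neighborhood scan."""
        labels = np.zeros((9, 9, 9), dtype=int)
        labels[2:7, 2:7, 2:7] = 1
        t = make_training_targets(labels)
        assert t.soma.sum() == 1
        assert t.soma[4, 4, 4]
        assert t.boundary.sum() == 5**3 - 1

        # brute-force oracle: raw boundary by exhaustive 6-neighbor scan,
        # then dilation by the 7-voxel cross, clipped to the foreground
        raw = np.zeros_like(labels, dtype=bool)
        for z in range(9):
            for y in range(9):
                for x in range(9):
                    if labels[z, y, x] == 0:
                        continue
                    for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                        zz, yy, xx = z + dz, y + dy, x + dx
                        neighbor = (
                            labels[zz, yy, xx]
                            if 0 <= zz < 9 and 0 <= yy < 9 and 0 <= xx < 9
                            else 0
                        )
                        if neighbor != labels[z, y, x]:
                            raw[z, y, x] = True
        expected_boundary = (
            ndimage.binary_dilation(
                raw, structure=ndimage.generate_binary_structure(3, 1)
            )
            & (labels > 0)
        )
        np.testing.assert_array_equal(t.boundary, expected_boundary)

    def test_touching_spheres_disconnect(self):
        """Two touching radius-7 spheres: every interface voxel lands in the
        boundary mask and the soma mask splits into exactly 2 components."""
        shape = (20, 20, 34)
        labels = np.zeros(shape, dtype=int)
        zz, yy, xx = np.indices(shape)
        c1, c2 = (10, 10, 10), (10, 10, 23)
        d1 = (zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2
        d2 = (zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2
        labels[d1 <= 49] = 1
        labels[(d2 <= 49) & (labels == 0)] = 2
        t = make_training_targets(labels)
        interface = np.zeros(shape, dtype=bool)
        interface[:, :, :-1] |= (labels[:, :, :-1] == 1) & (labels[:, :, 1:] == 2)
        interface[:, :, 1:] |= (labels[:, :, 1:] == 2) & (labels[:, :, :-1] == 1)
        assert (t.boundary & interface).sum() == interface.sum()
        _, n = ndimage.label(t.soma, structure=S26)
        assert n == 2

    def test_targets_partition_foreground(self, small_phantom):
        _, labels = small_phantom
        t = make_training_targets(labels)
        assert not (t.soma & t.boundary).any()
        np.testing.assert_array_equal(t.soma | t.boundary, labels > 0)

    def test_soma_components_stay_within_single_instances(self, small_phantom):
        _, labels = small_phantom
        t = make_training_targets(labels)
        comp, n = ndimage.label(t.soma, structure=S26)
        for c in range(1, n + 1):
            owners = np.unique(labels[comp == c])
            assert len(owners) == 1 and owners[0] > 0

    def test_label_permutation_invariance(self, rng):
        labels = rng.integers(0, 5, size=(12, 12, 12))
        perm = np.array([0, 3, 1, 4, 2])  # 0 stays background
        t1 = make_training_targets(labels)
        t2 = make_training_targets(perm[labels])
        np.testing.assert_array_equal(t1.soma, t2.soma)
        np.testing.assert_array_equal(t1.boundary, t2.boundary)


class TestCropPatches:
    @pytest.mark.parametrize(
        "axis_len,patch,stride,expected",
        [
            (10, 4, 3, [0, 3, 6]),
            (8, 8, 4, [0]),
            (285, 80, 48, [0, 48, 96, 144, 192, 205]),
            (64, 32, 24, [0, 24, 32]),
        ],
    )
    def test_origin_sequences(self, axis_len, patch, stride, expected):
        assert patch_origins(axis_len, patch, stride) == expected

    def test_full_coverage_and_overlap(self, rng):
        vol = rng.normal(size=(20, 13, 10))
        patches = crop_patches(vol, patch_size=8, stride=5)
        covered = np.zeros(vol.shape, dtype=int)
        for p in patches:
            z, y, x = p.origin
            np.testing.assert_array_equal(
                p.data, vol[z : z + 8, y : y + 8, x : x + 8]
            )
            covered[z : z + 8, y : y + 8, x : x + 8] += 1
        assert (covered >= 1).all()

    def test_short_axis_gets_symmetric_padding(self):
        vol = np.ones((4, 10, 10))
        patches = crop_patches(vol, patch_size=8, stride=5)
        assert patches[0].pad_before == (2, 0, 0)
        assert patches[0].data.shape == (8, 8, 8)
        assert patches[0].data[:2].sum() == 0  # zero padding on top

    def test_invalid_patch_stride(self):
        with pytest.raises(ValueError):
            crop_patches(np.zeros((8, 8, 8)), patch_size=4, stride=4)
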