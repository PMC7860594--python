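"""Patch assembly, thresholding and watershed instance splitting."""

import numpy as np
import pytest
from scipy import ndimage

from somaseg.evaluation import instance_dice, match_detections
from somaseg.phantom import PhantomConfig, generate_phantom
from somaseg.postprocess import (
    assemble_patches,
    binarize,
    extract_result,
    split_instances,
)
from somaseg.preprocess import crop_patches, make_training_targets


def brute_force_owner(origins, axis_len, patch, margin):
    """Per-voxel owner along one axis by the center-region rule: later
    patches win inside their ownership interval."""
    owner = np.full(axis_len, -1)
    for i, o in enumerate(origins):
        start = 0 if i == 0 else o + margin
        end = axis_len if i == len(origins) - 1 else o + patch - margin
        owner[start:end] = i
    return owner


class TestAssembly:
    def test_single_patch_identity(self, rng):
        vol = rng.random((8, 8, 8)).astype(np.float32)
        out = assemble_patches([(vol, vol, (0, 0, 0))], (8, 8, 8),
                               patch_size=8, stride=6)
        np.testing.assert_array_equal(out.soma_prob, vol)

    def test_ownership_matches_brute_force_1d(self):
        """L=10, P=4, S=3 -> origins 0,3,6; piecewise-constant patches land
        exactly on the brute-force ownership partition."""
        L, P, S = 10, 4, 3
        margin = (P - S) // 2
        origins = [0, 3, 6]
        owner1d = brute_force_owner(origins, L, P, margin)
        # constant-valued patches: patch (z0,y0,x0) carries its x-origin index
        preds = [
            (np.full((P, P, P), float(ix), np.float32),
             np.full((P, P, P), float(ix), np.float32),
             (z0, y0, x0))
            for z0 in origins for y0 in origins
            for ix, x0 in enumerate(origins)
        ]
        out = assemble_patches(preds, (L, L, L), patch_size=P, stride=S)
        # along any x-line the assembled value is the owning patch's index
        for z in (0, 5, 9):
            np.testing.assert_array_equal(out.soma_prob[z, 0, :], owner1d)

    def test_full_coverage_on_real_crop(self, rng):
        vol = rng.random((20, 20, 20)).astype(np.float32)
        patches = crop_patches(vol, patch_size=8, stride=6)
        preds = [(p.data, p.data, p.origin) for p in patches]
        out = assemble_patches(preds, vol.shape, patch_size=8, stride=6)
        # every voxel comes from the patch owning it, so values match source
        np.testing.assert_array_equal(out.soma_prob, vol)

    def test_inconsistent_patch_shape_rejected(self):
        with pytest.raises(ValueError):
            assemble_patches(
                [(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), (0, 0, 0))],
                (8, 8, 8), patch_size=8, stride=6,
            )


class TestBinarize:
    def test_tie_is_foreground(self):
        assert binarize(np.array([0.5]), 0.5).all()

    def test_empty(self):
        assert not binarize(np.zeros((3, 3, 3))).any()

    def test_duality(self, rng):
        p = rng.random((5, 5, 5))
        t = 0.3
        a = binarize(p, t)
        b = ~((1 - p) > (1 - t))  # complement of strict > on the complement
        np.testing.assert_array_equal(a, b)


class TestSplitInstances:
    def test_single_sphere_no_boundary(self):
        shape = (20, 20, 20)
        zz, yy, xx = np.indices(shape)
        sphere = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 36
        inst = split_instances(
            sphere, np.zeros(shape, bool), sphere.astype(np.float32)
        )
        assert inst.max() == 1
        np.testing.assert_array_equal(inst > 0, sphere)

    def test_two_touching_spheres_split_and_refill(self):
        shape = (24, 24, 38)
        zz, yy, xx = np.indices(shape)
        s1 = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 49
        s2 = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 25) ** 2 <= 49
        soma_mask = s1 | s2
        interface = ndimage.binary_dilation(s1, iterations=2) & ndimage.binary_dilation(s2, iterations=2)
        inst = split_instances(
            soma_mask, interface, soma_mask.astype(np.float32)
        )
        assert inst.max() == 2
        assert (inst > 0).sum() >= 0.95 * soma_mask.sum()

    def test_small_marker_filtered(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[3:5, 3:5, 3:5] = True  # 8 voxels < default 27
        inst = split_instances(mask, np.zeros_like(mask), mask.astype(float))
        assert inst.max() == 0

    def test_never_merges_markers(self, small_phantom):
        _, labels = small_phantom
        t = make_training_targets(labels)
        inst = split_instances(t.soma, t.boundary, t.soma.astype(np.float32))
        # each output instance contains exactly one marker component
        core = ndimage.binary_opening(
            t.soma & ~t.boundary,
            structure=ndimage.generate_binary_structure(3, 1),
        )
        markers, _ = ndimage.label(core, structure=np.ones((3, 3, 3), bool))
        for k in range(1, inst.max() + 1):
            ids = np.unique(markers[(inst == k) & (markers > 0)])
            assert len(ids) == 1


class TestExtractResult:
    def test_corner_cube_centroid(self):
        labels = np.zeros((6, 6, 6), dtype=int)
        labels[0:3, 0:3, 0:3] = 1
        res = extract_result(labels)
        assert res.centers == [(1.0, 1.0, 1.0)]

    def test_empty(self):
        res = extract_result(np.zeros((4, 4, 4), dtype=int))
        assert res.centers == []

    def test_matches_brute_force_averaging(self, rng):
        labels = rng.integers(0, 4, size=(10, 10, 10))
        res = extract_result(labels)
        for k, center in enumerate(res.centers, start=1):
            coords = np.argwhere(res.instances == k)
            np.testing.assert_allclose(center, coords.mean(axis=0), atol=1e-9)

    def test_labels_made_consecutive(self):
        labels = np.zeros((6, 6, 6), dtype=int)
        labels[0, 0, 0] = 5
        labels[3, 3, 3] = 9
        res = extract_result(labels)
        assert sorted(np.unique(res.instances)) == [0, 1, 2]


class TestGroundTruthOracle:
    def test_phantom_ground_truth_round_trip(self):
        """Feeding ground-truth targets through the splitting stage recovers
        the exact instance count with high per-instance Dice — isolating
        post-processing correctness from network quality."""
        for seed in range(5):
            img, labels = generate_phantom(PhantomConfig(seed=seed))
            t = make_training_targets(labels)
            inst = split_instances(t.soma, t.boundary, t.soma.astype(np.float32))
            assert inst.max() == labels.max()
            res, gt = extract_result(inst), extract_result(labels)
            m = match_detections(
                np.array(res.centers), np.array(gt.centers), rc=7.0
            )
            assert m.n_tp == labels.max()
            assert min(instance_dice(res.instances, gt.instances, m)) >= 0.9
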