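"""Threshold, binary clean-up, watershed separation and plausibility filtering."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from axonmetrics.containers import SemanticMap
from axonmetrics.morphometry import EllipseFit, FiberRecord
from axonmetrics.segmentation import (
    FilterRule,
    filter_instances,
    preprocess_contrast,
    segment,
    separate_instances,
    threshold_semantic,
)

from conftest import disk_mask


def _record(axon_minor=0.5, outer_minor=1.0, g=None, flags=()):
    def fit(minor):
        return EllipseFit((0, 0), minor * 1.3, minor, 0.5, 0.0, 1.0)

    rec = FiberRecord(fiber_id=1, axon_fit=fit(axon_minor), outer_fit=fit(outer_minor))
    rec.g_ratio = g if g is not None else axon_minor / outer_minor
    rec.qc_flags = list(flags)
    return rec


class TestPreprocessContrast:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 3.5)
        np.testing.assert_array_equal(preprocess_contrast(img), img)

    def test_range_preserved(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(10, 60, size=(128, 128))
        out = preprocess_contrast(img)
        assert out.min() >= img.min() - 1e-9
        assert out.max() <= img.max() + 1e-9

    def test_step_image_levels_stay_separable(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        out = preprocess_contrast(img)
        assert out[:, :16].mean() < out[:, 48:].mean()

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            preprocess_contrast(np.zeros((4, 4, 3)))


class TestThresholdSemantic:
    def test_one_hot_phantom_recovers_ground_truth(self, phantom_50):
        _, smap, inst, _ = phantom_50
        axon, myelin = threshold_semantic(smap)
        np.testing.assert_array_equal(axon, inst.axon_labels > 0)
        np.testing.assert_array_equal(myelin, inst.myelin_labels > 0)

    def test_argmax_rule(self):
        scores = np.zeros((4, 4, 3), dtype=np.float32)
        scores[...] = [0.2, 0.5, 0.3]  # axon wins the argmax
        smap = SemanticMap(scores)
        axon, myelin = threshold_semantic(smap, min_object_px=1)
        assert axon.all()
        assert not myelin.any()

    def test_small_speck_removed(self):
        scores = np.zeros((32, 32, 3), dtype=np.float32)
        scores[:, :, 0] = 1.0
        scores[5, 5:7, 2] = 1.0  # 2-px myelin speck
        scores[5, 5:7, 0] = 0.0
        axon, myelin = threshold_semantic(SemanticMap(scores), min_object_px=10)
        assert not myelin.any()


class TestSeparateInstances:
    def test_single_annulus_is_one_instance(self):
        outer = disk_mask((128, 128), (64, 64), 30)
        axon = disk_mask((128, 128), (64, 64), 18)
        inst = separate_instances(axon, outer & ~axon)
        assert list(inst.ids()) == [1]

    def test_empty_masks_give_empty_instances(self):
        z = np.zeros((32, 32), bool)
        inst = separate_instances(z, z)
        assert inst.ids().size == 0

    def test_kissing_disks_split_near_tangent_plane(self):
        # two tangent equal disks (r=20), tangent plane at column 70
        union = disk_mask((101, 141), (50, 50), 20) | disk_mask((101, 141), (50, 90), 20)
        inst = separate_instances(union, np.zeros_like(union), peak_min_distance=10)
        labels = np.where(inst.axon_labels > 0, inst.axon_labels, inst.myelin_labels)
        ids = inst.ids()
        assert len(ids) == 2
        cols_a = np.nonzero(labels == ids[0])[1]
        cols_b = np.nonzero(labels == ids[1])[1]
        left, right = sorted([cols_a, cols_b], key=lambda c: c.mean())
        assert left.max() <= 72
        assert right.min() >= 68

    def test_watershed_conserves_pixels(self, phantom_50, segmented_50):
        _, smap, _, _ = phantom_50
        axon, myelin = threshold_semantic(smap)
        union = axon | myelin
        labels = np.where(
            segmented_50.axon_labels > 0,
            segmented_50.axon_labels,
            segmented_50.myelin_labels,
        )
        assert (labels > 0).sum() == union.sum()
        sizes = np.bincount(labels.reshape(-1))[1:]
        assert sizes.sum() == union.sum()

    def test_instance_count_matches_fiber_count(self, phantom_50, segmented_50):
        cfg, _, _, truth = phantom_50
        assert len(segmented_50.ids()) == cfg.fiber_count

    def test_invariance_to_rotation_and_translation(self, phantom_50):
        _, smap, _, _ = phantom_50
        base = segment(smap)
        base_sizes = np.sort(np.bincount(
            np.where(base.axon_labels > 0, base.axon_labels, base.myelin_labels
                     ).reshape(-1))[1:])

        rot = SemanticMap(np.rot90(smap.scores, axes=(0, 1)).copy(), smap.pixel_size_nm)
        rot_inst = segment(rot)
        rot_sizes = np.sort(np.bincount(
            np.where(rot_inst.axon_labels > 0, rot_inst.axon_labels,
                     rot_inst.myelin_labels).reshape(-1))[1:])
        np.testing.assert_array_equal(base_sizes, rot_sizes)

        # translate by padding with background (avoids wrap-around at edges)
        padded = np.pad(smap.scores, ((17, 0), (31, 0), (0, 0)))
        padded[:17, :, 0] = 1.0
        padded[:, :31, 0] = 1.0
        shifted = SemanticMap(padded, smap.pixel_size_nm)
        shift_inst = segment(shifted)
        shift_sizes = np.sort(np.bincount(
            np.where(shift_inst.axon_labels > 0, shift_inst.axon_labels,
                     shift_inst.myelin_labels).reshape(-1))[1:])
        np.testing.assert_array_equal(base_sizes, shift_sizes)


class TestFilterInstances:
    def test_g_ratio_above_one_rejected(self):
        kept, rejected = filter_instances([_record(g=1.2)])
        assert not kept
        assert rejected[0][1] == "g_ratio_out_of_range"

    def test_empty_input(self):
        kept, rejected = filter_instances([])
        assert kept == [] and rejected == []

    def test_partition_is_complete(self):
        records = [
            _record(axon_minor=d, outer_minor=2 * d)
            for d in (0.5, 0.6, 0.7, 16.0, 17.0, 18.0, 0.8, 0.9, 1.0, 1.1)
        ]
        kept, rejected = filter_instances(
            records, FilterRule(max_axon_diameter_um=15.0, max_outer_diameter_um=30.0)
        )
        assert len(kept) == 7
        assert len(kept) + len(rejected) == 10
        assert all(r == "axon_diameter_out_of_range" for _, r in rejected)

    def test_no_myelin_flag_rejected(self):
        kept, rejected = filter_instances([_record(flags=["no_myelin"])])
        assert rejected[0][1] == "no_myelin"

    def test_border_policy(self):
        rec = _record(flags=["touches_border"])
        kept, _ = filter_instances([rec], FilterRule(drop_border_fibers=False))
        assert kept
        _, rejected = filter_instances([rec], FilterRule(drop_border_fibers=True))
        assert rejected[0][1] == "touches_border"

    @pytest.mark.parametrize("loose,tight", [
        (FilterRule(max_axon_diameter_um=15.0), FilterRule(max_axon_diameter_um=0.7)),
        (FilterRule(min_g_ratio=0.0), FilterRule(min_g_ratio=0.6)),
    ])
    def test_loosening_bounds_never_decreases_kept(self, loose, tight):
        rng = np.random.default_rng(3)
        records = [
            _record(axon_minor=d, outer_minor=d / g)
            for d, g in zip(rng.uniform(0.2, 2.0, 50), rng.uniform(0.3, 0.9, 50))
        ]
        kept_loose, _ = filter_instances(records, loose)
        kept_tight, _ = filter_instances(records, tight)
        assert len(kept_loose) >= len(kept_tight)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            FilterRule(min_axon_diameter_um=2.0, max_axon_diameter_um=1.0)
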