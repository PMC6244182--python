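"""Skin extraction, fat/fibroglandular clustering, sub-clustering, statistics."""

from __future__ import annotations

import numpy as np
import pytest

import breastphantom as bp
from breastphantom.masking import BreastMask
from breastphantom.mri_io import MRIVolume
from breastphantom.segmentation import (
    FAT,
    FGT_FIRST,
    SKIN,
    cluster_statistics,
    extract_skin_layer,
    segment_tissues,
    subcluster_fgt,
)


def _mask_from(arr, spacing=(1.0, 1.0, 1.0)):
    return BreastMask(np.asarray(arr, dtype=bool), 0.0, spacing)


def _brute_force_shell(mask, spacing, thickness):
    """Direct distance computation from every mask voxel to the exterior."""
    coords = np.argwhere(mask) * np.asarray(spacing)
    ext = np.argwhere(~mask) * np.asarray(spacing)
    out = np.zeros_like(mask)
    for voxel, (i, j, k) in zip(coords, np.argwhere(mask)):
        d = np.sqrt(((ext - voxel) ** 2).sum(axis=1)).min()
        out[i, j, k] = d <= thickness
    return out


class TestExtractSkinLayer:
    def test_single_voxel_mask_is_all_skin(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        shell = extract_skin_layer(_mask_from(m), 1.5)
        np.testing.assert_array_equal(shell, m)

    def test_cube_shell_matches_brute_force_distances(self):
        m = np.zeros((24, 24, 24), dtype=bool)
        m[2:22, 2:22, 2:22] = True  # 20 mm cube on a 1 mm grid
        mask = _mask_from(m)
        shell = extract_skin_layer(mask, 1.5)
        expected = _brute_force_shell(m, mask.spacing_mm, 1.5)
        np.testing.assert_array_equal(shell, expected)

    def test_anisotropic_spacing_shell_matches_brute_force(self):
        m = np.zeros((12, 12, 8), dtype=bool)
        m[2:10, 2:10, 2:6] = True
        mask = _mask_from(m, spacing=(1.0, 2.0, 2.5))
        shell = extract_skin_layer(mask, 2.2)
        expected = _brute_force_shell(m, mask.spacing_mm, 2.2)
        np.testing.assert_array_equal(shell, expected)

    def test_huge_thickness_saturates_to_mask(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[3:7, 3:7, 3:7] = True
        shell = extract_skin_layer(_mask_from(m), 1e6)
        np.testing.assert_array_equal(shell, m)

    def test_subvoxel_thickness_warns(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[1:5, 1:5, 1:5] = True
        with pytest.warns(UserWarning, match="below the voxel spacing"):
            extract_skin_layer(_mask_from(m, spacing=(2.0, 2.0, 2.0)), 1.0)


class TestSegmentTissues:
    def test_phantom_agreement_at_least_95_percent(self, small_phantom, small_params):
        volume, truth = small_phantom
        mask = _mask_from(truth.labels.labels > 0, small_params.spacing_mm)
        got = segment_tissues(volume, mask, small_params.skin_thickness_mm)
        inside = truth.labels.labels > 0
        agree = (got.labels[inside] == truth.labels.labels[inside]).mean()
        assert agree >= 0.95

    def test_two_separated_intensities_recovered_exactly(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[1:9, 1:9, 1:9] = True
        data = np.zeros((10, 10, 10))
        data[m] = 50.0
        data[4:7, 4:7, 4:7] = 220.0
        got = segment_tissues(MRIVolume(data, (1, 1, 1)), _mask_from(m), 1.0)
        interior = m & ~(got.labels == SKIN)
        assert ((got.labels == FGT_FIRST) == (interior & (data == 220.0))).all()
        assert ((got.labels == FAT) == (interior & (data == 50.0))).all()

    def test_degenerate_interior_assigned_to_fat_with_warning(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[1:7, 1:7, 1:7] = True
        data = np.where(m, 80.0, 0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            got = segment_tissues(MRIVolume(data, (1, 1, 1)), _mask_from(m), 1.0)
        assert not got.fgt_labels or (got.labels == FGT_FIRST).sum() == 0

    def test_partition_property(self, small_phantom, small_params):
        volume, truth = small_phantom
        mask = _mask_from(truth.labels.labels > 0, small_params.spacing_mm)
        got = segment_tissues(volume, mask, small_params.skin_thickness_mm)
        assert ((got.labels > 0) == mask.mask).all()


class TestSubclusterFgt:
    def test_k1_leaves_class_untouched(self, small_phantom, small_params):
        volume, truth = small_phantom
        lm = truth.labels.copy()
        out = subcluster_fgt(volume, lm, 1)
        np.testing.assert_array_equal(out.labels, lm.labels)

    def test_k8_non_empty_union_preserved(self, small_phantom):
        volume, truth = small_phantom
        out = subcluster_fgt(volume, truth.labels, 8, seed=0)
        assert len(out.fgt_labels) == 8
        before = np.isin(truth.labels.labels, truth.labels.fgt_labels)
        after = np.isin(out.labels, out.fgt_labels)
        np.testing.assert_array_equal(before, after)
        assert all((out.labels == l).any() for l in out.fgt_labels)

    def test_legend_monotone_in_cluster_mean(self, small_phantom):
        volume, truth = small_phantom
        out = subcluster_fgt(volume, truth.labels, 4, seed=0)
        stats = cluster_statistics(volume, out)
        means = [stats.mean_intensity[l] for l in out.fgt_labels]
        assert means == sorted(means)

    def test_k2_matches_exhaustive_split_on_bimodal_intensities(self):
        # 1-D 2-means equals the best threshold split; find it exhaustively
        rng = np.random.default_rng(8)
        vals = np.concatenate(
            [rng.normal(120, 5, 300), rng.normal(240, 8, 200)]
        ).round()
        m = np.zeros((vals.size, 1, 3), dtype=bool)
        m[:, 0, 1] = True
        data = np.zeros(m.shape)
        data[:, 0, 1] = vals
        labels = np.where(m, FGT_FIRST, 0).astype(np.int32)
        lm = bp.TissueLabelMap(
            labels, {0: "background", FGT_FIRST: "fgt_1"}, (1, 1, 1)
        )
        out = subcluster_fgt(MRIVolume(data, (1, 1, 1)), lm, 2, seed=0)
        low_max = data[:, 0, 1][out.labels[:, 0, 1] == FGT_FIRST].max()

        # exhaustive 1-D split search: minimise within-class sum of squares
        uniq = np.unique(vals)
        costs = []
        for split in uniq[1:]:
            lo, hi = vals[vals < split], vals[vals >= split]
            costs.append(((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum())
        best_split = uniq[1:][int(np.argmin(costs))]
        # k-means low cluster ends within one intensity bin of the optimum
        kmeans_idx = int(np.searchsorted(uniq, low_max))
        best_idx = int(np.searchsorted(uniq, best_split)) - 1
        assert abs(kmeans_idx - best_idx) <= 1

    def test_determinism_under_fixed_seed(self, small_phantom):
        volume, truth = small_phantom
        a = subcluster_fgt(volume, truth.labels, 6, seed=11)
        b = subcluster_fgt(volume, truth.labels, 6, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_k_too_large_errors(self):
        m = np.zeros((4, 1, 1), dtype=bool)
        m[:2] = True
        data = np.zeros(m.shape)
        data[m] = 100.0
        labels = np.where(m, FGT_FIRST, 0).astype(np.int32)
        lm = bp.TissueLabelMap(labels, {0: "background", FGT_FIRST: "fgt_1"}, (1, 1, 1))
        with pytest.raises(ValueError, match="K too large"):
            subcluster_fgt(MRIVolume(data, (1, 1, 1)), lm, 2)


class TestClusterStatistics:
    def test_single_voxel_cluster_mean(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[1, 1, 1] = FAT
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 42.0
        lm = bp.TissueLabelMap(labels, {0: "background", FAT: "fat"}, (1, 1, 1))
        stats = cluster_statistics(MRIVolume(data, (1, 1, 1)), lm)
        assert stats.mean_intensity[FAT] == 42.0
        assert stats.voxel_count[FAT] == 1

    def test_counts_partition_and_means_match_bruteforce(self, small_phantom):
        volume, truth = small_phantom
        stats = cluster_statistics(volume, truth.labels)
        assert sum(stats.voxel_count.values()) == volume.intensities.size
        for label in truth.labels.legend:
            sel = truth.labels.labels == label
            if sel.any():
                # naive accumulation oracle
                total, n = 0.0, 0
                for v in volume.intensities[sel].ravel():
                    total += v
                    n += 1
                assert stats.mean_intensity[label] == pytest.approx(total / n)

    def test_absent_label_reported_with_undefined_mean(self):
        labels = np.zeros((2, 2, 2), dtype=np.int32)
        lm = bp.TissueLabelMap(labels, {0: "background", SKIN: "skin"}, (1, 1, 1))
        stats = cluster_statistics(MRIVolume(np.ones((2, 2, 2)), (1, 1, 1)), lm)
        assert stats.voxel_count[SKIN] == 0
        assert np.isnan(stats.mean_intensity[SKIN])
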