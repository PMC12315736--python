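"""Contingency matrices, Hungarian matching, hemisphere harmonization."""

import itertools

import numpy as np
import pytest

from cytoseg.crf import compute_frame
from cytoseg.matching import (cross_tabulate, harmonize_hemispheres,
                              hemisphere_correspondence, kuhn_munkres_match,
                              make_layer_atlas)


class TestMakeLayerAtlas:
    def test_composite_label_count(self):
        areas = np.zeros((6, 6, 6), dtype=np.int32)
        areas[:2] = 1
        areas[2:4] = 2
        areas[4:] = 3
        depth = np.broadcast_to(np.linspace(0, 1, 6)[None, None, :],
                                (6, 6, 6)).copy()
        gm = np.ones((6, 6, 6), bool)
        atlas = make_layer_atlas(areas, depth, gm, n_layers=6)
        labels = set(np.unique(atlas)) - {0}
        assert len(labels) == 18  # 3 areas x 6 layers
        assert all(100 < l < 400 for l in labels)
        # every GM voxel of a labeled area got exactly one composite label
        assert (atlas[areas > 0] > 0).all()

    def test_equivolume_layer_balance_on_phantom(self, default_truth,
                                                 default_frame):
        """Within each area, the six composite layers have near-equal
        volumes on the shell phantom."""
        t = default_truth
        atlas = make_layer_atlas(t.area_labels, default_frame.depth,
                                 t.gm_mask & default_frame.defined_mask,
                                 n_layers=6)
        left = atlas[t.left_mask]
        for area in range(1, t.spec.n_areas + 1):
            counts = np.array([
                np.count_nonzero(left == area * 100 + lay)
                for lay in range(1, 7)
            ])
            assert np.abs(counts - counts.mean()).max() / counts.mean() < 0.10

    def test_encoding_limit(self):
        with pytest.raises(ValueError):
            make_layer_atlas(np.ones((4, 4, 4), np.int32),
                             np.zeros((4, 4, 4)), np.ones((4, 4, 4), bool),
                             n_layers=100)


class TestCrossTabulate:
    def test_identical_segmentations_are_diagonal(self):
        seg = np.zeros((60, 1, 1), dtype=np.int32)
        seg[:10] = 1
        seg[10:30] = 2
        seg[30:60] = 3
        ct = cross_tabulate(seg, seg)
        np.testing.assert_array_equal(ct.counts, np.diag([10, 20, 30]))
        np.testing.assert_array_equal(ct.row_labels, [1, 2, 3])

    def test_hand_counted_overlaps(self):
        """2x2 fixture with overlaps ((7,3),(2,8))."""
        a = np.zeros((20, 1, 1), dtype=np.int32)
        b = np.zeros((20, 1, 1), dtype=np.int32)
        a[:10] = 1
        a[10:] = 2
        b[:7] = 1
        b[7:12] = 2
        b[12:] = 1
        # a=1: b=1 on 0..6 (7), b=2 on 7..9 (3)
        # a=2: b=1 on 12..19 (8), b=2 on 10..11 (2)
        ct = cross_tabulate(a, b)
        np.testing.assert_array_equal(ct.counts, [[7, 3], [8, 2]])

    def test_total_equals_joint_coverage(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, (8, 8, 8)).astype(np.int32)
        b = rng.integers(0, 3, (8, 8, 8)).astype(np.int32)
        ct = cross_tabulate(a, b)
        assert ct.counts.sum() == np.count_nonzero((a > 0) & (b > 0))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_tabulate(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)))

    def test_permutation_invariance_of_content(self):
        """Reordering labels permutes rows/columns but not the counts."""
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, (10, 10, 10)).astype(np.int32)
        b = rng.integers(0, 5, (10, 10, 10)).astype(np.int32)
        ct = cross_tabulate(a, b)
        remap = np.array([0, 4, 3, 2, 1])
        ct2 = cross_tabulate(remap[a], b)
        for i, lab in enumerate(ct.row_labels):
            j = np.nonzero(ct2.row_labels == remap[lab])[0][0]
            np.testing.assert_array_equal(ct.counts[i], ct2.counts[j])


class TestHemisphereCorrespondence:
    def test_identical_hemispheres_diagonal_dominant(self):
        """Identical labelings with distinct atlas profiles give a Gram
        matrix whose row argmax sits on the diagonal."""
        atlas = np.zeros((12, 6, 6), dtype=np.int32)
        for q in range(4):
            atlas[3 * q:3 * (q + 1)] = q + 1
        seg = np.zeros_like(atlas)
        seg[atlas <= 2] = 1          # covers atlas {1, 2}
        seg[atlas == 3] = 2          # covers atlas {3}
        seg[atlas == 4] = 3          # covers atlas {4}
        c = cross_tabulate(atlas, seg)
        m = hemisphere_correspondence(c, c)
        assert (np.argmax(m.counts, axis=1) == np.arange(3)).all()
        assert (m.counts >= 0).all()

    def test_atlas_mismatch_raises(self):
        a = np.zeros((10, 1, 1), np.int32)
        a[:5] = 1
        a[5:] = 2
        seg = np.ones((10, 1, 1), np.int32)
        c1 = cross_tabulate(a, seg)
        a2 = a.copy()
        a2[a2 == 2] = 3
        c2 = cross_tabulate(a2, seg)
        with pytest.raises(ValueError, match="differ"):
            hemisphere_correspondence(c1, c2)


class TestKuhnMunkres:
    def test_permutation_matrix_recovered(self):
        perm = np.array([2, 0, 3, 1])
        aff = np.zeros((4, 4))
        aff[np.arange(4), perm] = 5
        res = kuhn_munkres_match(aff)
        mapping = {r - 1: c - 1 for r, c in
                   zip(res.pairs["row_label"], res.pairs["col_label"])}
        assert mapping == {i: int(perm[i]) for i in range(4)}
        assert (res.pairs["round"] == 1).all()

    def test_matches_brute_force_on_random_matrices(self):
        """Round-1 total overlap equals exhaustive-search maximum for 100
        seeded random 6x6 and 7x7 integer matrices."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = 6 + trial % 2
            aff = rng.integers(1, 50, (n, n))
            res = kuhn_munkres_match(aff)
            total = res.pairs.loc[res.pairs["round"] == 1, "overlap"].sum()
            brute = max(
                sum(aff[i, p[i]] for i in range(n))
                for p in itertools.permutations(range(n))
            )
            assert total == brute

    def test_rectangular_many_to_one_rounds(self):
        """10 rows vs 4 columns: 4 one-to-one matches in round 1, the
        remaining 6 rows attached many-to-one afterwards."""
        rng = np.random.default_rng(3)
        aff = rng.integers(1, 30, (10, 4))
        res = kuhn_munkres_match(aff)
        assert (res.pairs["round"] == 1).sum() == 4
        assert (res.pairs["round"] == 2).sum() == 6
        assert len(res.pairs) == 10
        assert not res.unmatched

    def test_zero_row_stays_unmatched(self):
        aff = np.array([[5, 0], [0, 0]])
        res = kuhn_munkres_match(aff, row_labels=[10, 20], col_labels=[1, 2])
        assert res.unmatched == [20]
        assert len(res.pairs) == 1

    def test_negative_affinity_rejected(self):
        with pytest.raises(ValueError):
            kuhn_munkres_match(np.array([[-1.0, 2.0]]))


class TestHarmonizeHemispheres:
    def _atlas_and_masks(self, truth, frame):
        atlas = make_layer_atlas(truth.area_labels, frame.depth,
                                 truth.gm_mask, n_layers=6)
        return atlas, truth.left_mask, truth.right_mask

    def test_identity_permutation_is_fixed_point(self, default_frame):
        from cytoseg.phantom import default_spec, make_phantom

        t = make_phantom(default_spec(seed=42, identity_permutation=True))
        atlas, ml, mr = self._atlas_and_masks(t, default_frame)
        left = np.where(ml, t.class_labels, 0)
        right = np.where(mr, t.class_labels, 0)
        out, assignment, _ = harmonize_hemispheres(left, right, atlas, ml, mr)
        np.testing.assert_array_equal(out, right)

    def test_permutation_recovery_and_voxel_agreement(self, default_truth,
                                                      default_frame):
        """Harmonizing the permuted mirrored hemisphere recovers the inverse
        permutation exactly: the flipped right labels equal the left labels
        voxel for voxel."""
        t = default_truth
        atlas, ml, mr = self._atlas_and_masks(t, default_frame)
        left = np.where(ml, t.class_labels, 0)
        right = np.where(mr, t.class_labels, 0)
        out, assignment, _ = harmonize_hemispheres(left, right, atlas, ml, mr)
        nx = t.spec.hemisphere_shape[0]
        flipped = out[nx + 1:][::-1]
        agreement = (flipped == left[:nx])[left[:nx] > 0].mean()
        assert agreement == 1.0

    def test_geometry_unchanged(self, default_truth, default_frame):
        """Only ids change: each relabeled right domain occupies exactly the
        voxel set of one original right label."""
        t = default_truth
        atlas, ml, mr = self._atlas_and_masks(t, default_frame)
        left = np.where(ml, t.class_labels, 0)
        right = np.where(mr, t.class_labels, 0)
        out, _, _ = harmonize_hemispheres(left, right, atlas, ml, mr)
        for lab in np.unique(right[right > 0]):
            vals = np.unique(out[right == lab])
            assert vals.size == 1

    def test_random_permutations_recovered(self, default_truth, default_frame):
        """Any random relabeling of the right hemisphere is undone (several
        seeded draws)."""
        t = default_truth
        atlas, ml, mr = self._atlas_and_masks(t, default_frame)
        left = np.where(ml, t.class_labels, 0)
        base_right = np.where(mr, t.class_labels, 0)
        n = t.spec.n_classes
        for seed in range(5):
            rng = np.random.default_rng(seed)
            perm = np.concatenate([[0], rng.permutation(n) + 1])
            right = perm[base_right]
            out, _, _ = harmonize_hemispheres(left, right, atlas, ml, mr)
            nx = t.spec.hemisphere_shape[0]
            flipped = out[nx + 1:][::-1]
            assert (flipped == left[:nx])[left[:nx] > 0].mean() == 1.0
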