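"""Overlap scores, matrices, interaction classification, clustering, OLS."""

import numpy as np
import pandas as pd
import pytest

from lhoverlap.overlap import (
    OverlapMatrix,
    axon_dendrite_relation,
    classify_interactions,
    cluster_matrix,
    directional_overlap,
    overlap_score,
    pairwise_matrix,
)
from lhoverlap.synthetic import OverlapDesign, generate_mask_pair
from lhoverlap.volumes import BinaryMask


def brute_force_overlap(a, b):
    """Independent voxel-counting oracle for P1."""
    inter = n_a = 0
    for idx in np.ndindex(*a.shape):
        if a.data[idx]:
            n_a += 1
            if b.data[idx]:
                inter += 1
    return 100.0 * inter / n_a


def nested_pair(mask_factory):
    """|a| = 10 all inside b, |b| = 40."""
    a = np.zeros((5, 5, 4), dtype=bool)
    b = np.zeros((5, 5, 4), dtype=bool)
    flat_b = np.arange(40)
    b.ravel()[flat_b] = True
    a.ravel()[flat_b[:10]] = True
    return mask_factory(a), mask_factory(b)


class TestDirectionalOverlap:
    def test_self_overlap_is_100(self, rng, mask_factory):
        m = mask_factory(rng.random((6, 6, 4)) > 0.5)
        assert directional_overlap(m, m) == 100.0

    def test_disjoint_is_zero(self, mask_factory):
        a = np.zeros((4, 4, 2), dtype=bool)
        b = np.zeros((4, 4, 2), dtype=bool)
        a[0], b[2] = True, True
        assert directional_overlap(mask_factory(a), mask_factory(b)) == 0.0

    def test_nested_pair_both_directions(self, mask_factory):
        a, b = nested_pair(mask_factory)
        assert directional_overlap(a, b) == 100.0
        assert directional_overlap(b, a) == 25.0

    def test_empty_mask_rejected(self, mask_factory, rng):
        empty = mask_factory(np.zeros((3, 3, 3)))
        other = mask_factory(rng.random((3, 3, 3)) > 0.5)
        with pytest.raises(ValueError, match="empty"):
            directional_overlap(empty, other)


class TestOverlapScore:
    def test_nested_pair_combinations(self, mask_factory):
        a, b = nested_pair(mask_factory)
        r = overlap_score(a, b)
        assert r.mean_score == 62.5
        assert r.max_score == 100.0
        assert r.min_score == 25.0

    def test_identical_masks_all_100(self, rng, mask_factory):
        m = mask_factory(rng.random((5, 5, 3)) > 0.4)
        r = overlap_score(m, m)
        assert r.mean_score == r.max_score == r.min_score == 100.0

    def test_mean_rule_symmetric_under_swap(self, rng, mask_factory):
        a = mask_factory(rng.random((6, 5, 4)) > 0.5)
        b = mask_factory(rng.random((6, 5, 4)) > 0.5)
        assert overlap_score(a, b).mean_score == overlap_score(b, a).mean_score

    def test_score_ordering_invariant(self, rng, mask_factory):
        for _ in range(5):
            a = mask_factory(rng.random((5, 5, 3)) > 0.5)
            b = mask_factory(rng.random((5, 5, 3)) > 0.5)
            if a.n_voxels == 0 or b.n_voxels == 0:
                continue
            r = overlap_score(a, b)
            assert 0 <= r.min_score <= r.mean_score <= r.max_score <= 100


class TestPairwiseMatrix:
    def test_self_matrix_symmetric_with_100_diagonal(self, rng, mask_factory):
        masks = [mask_factory(rng.random((5, 5, 4)) > 0.5, cell_type=f"t{i}")
                 for i in range(4)]
        m = pairwise_matrix(masks, masks, "mean")
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 100.0)

    def test_disjoint_families_all_zero(self, mask_factory):
        fam1, fam2 = [], []
        for i in range(3):
            a = np.zeros((6, 6, 6), dtype=bool)
            a[i] = True
            fam1.append(mask_factory(a, cell_type=f"a{i}"))
            b = np.zeros((6, 6, 6), dtype=bool)
            b[3 + i] = True
            fam2.append(mask_factory(b, cell_type=f"b{i}"))
        m = pairwise_matrix(fam1, fam2, "mean")
        assert (m.values.to_numpy() == 0).all()

    @pytest.mark.parametrize("combine", ["mean", "max", "min"])
    def test_cells_match_brute_force_oracle(self, combine, mask_factory):
        fams = []
        for i in range(3):
            a, b = generate_mask_pair(
                OverlapDesign(0.3, 60, 90, seed=i, grid_shape=(10, 10, 8))
            )
            fams.append(mask_factory(a.data, cell_type=f"x{i}"))
            fams.append(mask_factory(b.data, cell_type=f"y{i}"))
        set1, set2 = fams[:3], fams[3:]
        m = pairwise_matrix(set1, set2, combine)
        for i, a in enumerate(set1):
            for j, b in enumerate(set2):
                p1 = brute_force_overlap(a, b)
                p2 = brute_force_overlap(b, a)
                expected = {"mean": (p1 + p2) / 2, "max": max(p1, p2), "min": min(p1, p2)}
                assert m.values.iloc[i, j] == pytest.approx(expected[combine], abs=1e-12)

    def test_empty_mask_reported_by_label(self, rng, mask_factory):
        good = mask_factory(rng.random((4, 4, 2)) > 0.5, cell_type="good")
        bad = mask_factory(np.zeros((4, 4, 2)), cell_type="empty_one")
        with pytest.raises(ValueError, match="empty_one"):
            pairwise_matrix([good], [bad], "mean")


class TestClassifyInteractions:
    def test_threshold_is_strict(self):
        m = OverlapMatrix(pd.DataFrame(np.full((3, 4), 15.0),
                                       index=list("abc"), columns=list("wxyz")))
        s = classify_interactions(m, threshold=15)
        assert not s.significant.to_numpy().any()
        assert s.frac_rows_with_any == 0.0

    def test_all_zero_row_counts_as_none(self):
        vals = np.array([[20.0, 0.0], [0.0, 0.0]])
        m = OverlapMatrix(pd.DataFrame(vals, index=["hit", "miss"], columns=["u", "v"]))
        s = classify_interactions(m)
        assert s.frac_rows_with_any == 0.5
        assert s.frac_rows_with_none == 0.5

    def test_hand_counted_fraction(self, rng):
        vals = np.full((10, 4), 5.0)
        vals[[1, 4, 7], [0, 2, 3]] = 40.0  # exactly 3 rows exceed somewhere
        m = OverlapMatrix(pd.DataFrame(vals, index=[f"r{i}" for i in range(10)],
                                       columns=list("abcd")))
        s = classify_interactions(m)
        assert s.frac_rows_with_any == pytest.approx(0.3)
        assert s.frac_rows_with_any + s.frac_rows_with_none == pytest.approx(1.0)

    def test_diagonal_excluded_for_self_matrix(self):
        vals = np.full((3, 3), 5.0)
        np.fill_diagonal(vals, 100.0)
        m = OverlapMatrix(pd.DataFrame(vals, index=list("abc"), columns=list("abc")))
        s = classify_interactions(m)
        assert s.frac_rows_with_any == 0.0


def naive_complete_linkage(points):
    """O(n^3) agglomeration oracle: returns the merge heights and the final
    two-block membership for well-separated data."""
    clusters = [[i] for i in range(len(points))]
    dist = lambda c1, c2: max(
        np.linalg.norm(points[i] - points[j]) for i in c1 for j in c2
    )
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        merges.append((d, sorted(merged)))
    return merges


class TestClusterMatrix:
    def test_identical_rows_merge_at_height_zero(self):
        vals = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]])
        m = OverlapMatrix(pd.DataFrame(vals, index=list("abc"), columns=["u", "v"]))
        res = cluster_matrix(m)
        assert res.row_linkage[0, 2] == 0.0  # first merge at distance 0
        assert set(res.row_linkage[0, :2]) == {0.0, 1.0}

    def test_two_blocks_match_naive_agglomeration(self, rng):
        block1 = rng.normal(0.0, 0.5, size=(4, 6))
        block2 = rng.normal(50.0, 0.5, size=(3, 6))
        points = np.vstack([block1, block2])
        vals = np.abs(points)
        m = OverlapMatrix(pd.DataFrame(vals, index=[f"r{i}" for i in range(7)],
                                       columns=[f"c{j}" for j in range(6)]))
        res = cluster_matrix(m)
        merges = naive_complete_linkage(np.abs(points))
        # the last merge joins the two designed blocks in both algorithms
        heights = res.row_linkage[:, 2]
        assert heights[-1] == pytest.approx(merges[-1][0])
        # co-membership: cutting the implementation's tree at 2 clusters
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(res.row_linkage, 2, criterion="maxclust")
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_permutation_invariant_topology(self, rng):
        vals = rng.random((6, 5)) * 100
        labels = [f"r{i}" for i in range(6)]
        m1 = OverlapMatrix(pd.DataFrame(vals, index=labels, columns=list("abcde")))
        perm = rng.permutation(6)
        m2 = OverlapMatrix(pd.DataFrame(vals[perm], index=[labels[i] for i in perm],
                                        columns=list("abcde")))
        r1, r2 = cluster_matrix(m1), cluster_matrix(m2)
        # merge heights are permutation-invariant; exact leaf order is a
        # rendering choice and non-normative
        np.testing.assert_allclose(
            np.sort(r1.row_linkage[:, 2]), np.sort(r2.row_linkage[:, 2])
        )
        from scipy.cluster.hierarchy import fcluster

        l1 = fcluster(r1.row_linkage, 2, criterion="maxclust")
        l2 = fcluster(r2.row_linkage, 2, criterion="maxclust")
        com1 = {frozenset(np.array(labels)[l1 == k]) for k in set(l1)}
        com2 = {frozenset(np.array(m2.row_labels)[l2 == k]) for k in set(l2)}
        assert com1 == com2

    def test_single_row_rejected(self):
        m = OverlapMatrix(pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["u", "v"]))
        with pytest.raises(ValueError, match="2 rows"):
            cluster_matrix(m)


class TestAxonDendriteRelation:
    def test_identical_matrices_r2_one(self, rng):
        vals = rng.random((5, 5)) * 100
        labels = list("abcde")
        m = OverlapMatrix(pd.DataFrame(vals, index=labels, columns=labels))
        r = axon_dendrite_relation(m, m)
        assert r.r_squared == pytest.approx(1.0)

    def test_five_point_closed_form(self):
        # off-diagonal cells of 2x2 won't give 5 points; use 1x5 distinct labels
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 4.0, 5.0, 4.0, 6.0])
        ax = OverlapMatrix(pd.DataFrame([y], index=["r"], columns=list("abcde")))
        de = OverlapMatrix(pd.DataFrame([x], index=["r"], columns=list("abcde")))
        r = axon_dendrite_relation(ax, de)
        # closed-form normal equations
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        r2 = sxy**2 / (sxx * ((y - y.mean()) ** 2).sum())
        assert r.slope == pytest.approx(slope)
        assert r.intercept == pytest.approx(intercept)
        assert r.r_squared == pytest.approx(r2)

    def test_independent_matrices_r2_near_zero(self, rng):
        n = 40
        labels = [f"t{i}" for i in range(n)]
        ax = OverlapMatrix(pd.DataFrame(rng.random((n, n)) * 100, index=labels, columns=labels))
        de = OverlapMatrix(pd.DataFrame(rng.random((n, n)) * 100, index=labels, columns=labels))
        assert axon_dendrite_relation(ax, de).r_squared < 0.02

    def test_constant_predictor_warns_and_zeroes(self):
        labels = list("abc")
        ax = OverlapMatrix(pd.DataFrame(np.arange(9.0).reshape(3, 3), index=labels, columns=labels))
        de = OverlapMatrix(pd.DataFrame(np.full((3, 3), 7.0), index=labels, columns=labels))
        with pytest.warns(UserWarning, match="constant"):
            r = axon_dendrite_relation(ax, de)
        assert r.r_squared == 0.0 and r.degenerate


class TestMonotonicity:
    def test_growing_shared_region_with_fixed_sizes(self, mask_factory):
        # |a| and |b| fixed at 40; move one a-voxel at a time into b's region
        scores = []
        for k in range(0, 41, 10):
            a = np.zeros((10, 10, 1), dtype=bool)
            b = np.zeros((10, 10, 1), dtype=bool)
            b.ravel()[:40] = True
            a.ravel()[:k] = True  # k voxels shared
            a.ravel()[40 : 80 - k] = True  # remainder outside b
            r = overlap_score(mask_factory(a), mask_factory(b))
            scores.append((r.min_score, r.mean_score, r.max_score))
        for s_prev, s_next in zip(scores, scores[1:]):
            assert all(x2 >= x1 for x1, x2 in zip(s_prev, s_next))
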