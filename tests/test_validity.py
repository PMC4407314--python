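from itertools import combinations
from math import sqrt

import numpy as np
import pytest

from apconsensus import validity
from apconsensus.validity import (
    PairConfusion,
    adjusted_rand,
    contingency,
    davies_bouldin,
    dunn,
    external_report,
    minkowski_measure,
    pair_confusion,
    silhouette,
)


def brute_force_pairs(u, v):
    """All-pairs enumeration oracle for the confusion counts."""
    u, v = np.asarray(u), np.asarray(v)
    tp = fp = fn = tn = 0
    for i, j in combinations(range(u.size), 2):
        same_u, same_v = u[i] == u[j], v[i] == v[j]
        tp += same_u and same_v
        fp += same_u and not same_v
        fn += not same_u and same_v
        tn += not same_u and not same_v
    return tp, fp, fn, tn


class TestContingency:
    def test_identical_partitions_diagonal(self):
        u = [0, 0, 1, 1, 2]
        table = contingency(u, u)
        np.testing.assert_array_equal(table, np.diag([2, 2, 1]))

    def test_singletons_unit_rows(self):
        table = contingency(np.arange(4), [0, 0, 1, 1])
        np.testing.assert_array_equal(table.sum(axis=1), 1)

    def test_hand_counts(self):
        u = [1, 1, 1, 2, 2]
        v = [1, 1, 2, 2, 2]
        np.testing.assert_array_equal(contingency(u, v), [[2, 1], [0, 2]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contingency([1, 2], [1, 2, 3])


class TestAdjustedRand:
    def test_identical_partitions(self):
        assert adjusted_rand([0, 1, 1, 2], [5, 9, 9, 7]) == 1.0

    def test_hand_arithmetic_five_genes(self):
        # contingency [[2,1],[0,2]]: sum_ij C2 = 2, both margins 4,
        # expected = 16/10, max = 4 -> ARI = 0.4/2.4 = 1/6
        assert adjusted_rand([1, 1, 1, 2, 2], [1, 1, 2, 2, 2]) == pytest.approx(
            1 / 6, abs=1e-15
        )

    def test_relabeling_invariance(self, rng):
        u = rng.integers(0, 4, 30)
        v = rng.integers(0, 3, 30)
        base = adjusted_rand(u, v)
        perm = rng.permutation(4)
        assert adjusted_rand(perm[u], v) == pytest.approx(base, abs=1e-12)

    def test_chance_correction_near_zero(self, rng):
        # mean ARI of independent random labelings is ~0
        vals = [
            adjusted_rand(rng.integers(0, 5, 200), rng.integers(0, 8, 200))
            for _ in range(300)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_matches_reference_implementation(self, rng):
        from sklearn.metrics import adjusted_rand_score

        for _ in range(10):
            u = rng.integers(0, 4, 25)
            v = rng.integers(0, 3, 25)
            assert adjusted_rand(u, v) == pytest.approx(
                adjusted_rand_score(u, v), abs=1e-12
            )


class TestPairConfusion:
    def test_identical_partitions_no_disagreement(self):
        pc = pair_confusion([0, 0, 1], [5, 5, 9])
        assert pc.fp == pc.fn == 0

    def test_one_cluster_vs_singletons(self):
        pc = pair_confusion([1, 1, 1, 1], [1, 2, 3, 4])
        assert (pc.tp, pc.fp, pc.fn, pc.tn) == (0, 6, 0, 0)

    def test_total_is_all_pairs(self, rng):
        u = rng.integers(0, 3, 12)
        v = rng.integers(0, 4, 12)
        assert pair_confusion(u, v).total == 66

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 13))
            u = rng.integers(0, 4, n)
            v = rng.integers(0, 3, n)
            pc = pair_confusion(u, v)
            assert (pc.tp, pc.fp, pc.fn, pc.tn) == brute_force_pairs(u, v)

    def test_derived_indices_definitions(self, rng):
        u = rng.integers(0, 3, 10)
        v = rng.integers(0, 3, 10)
        pc = pair_confusion(u, v)
        rep = external_report(u, v)
        assert rep.sensitivity == pytest.approx(pc.tp / (pc.tp + pc.fn))
        assert rep.specificity == pytest.approx(pc.tp / (pc.tp + pc.fp))
        assert rep.jaccard == pytest.approx(pc.tp / (pc.tp + pc.fn + pc.fp))


class TestMinkowski:
    def test_perfect_agreement_zero(self):
        assert minkowski_measure(pair_confusion([0, 0, 1], [1, 1, 2])) == 0.0

    def test_closed_form_cases(self):
        # FP = FN = TP: (FP+FN)/(TP+FN) = 1
        assert minkowski_measure(PairConfusion(3, 3, 3, 1)) == pytest.approx(1.0)
        # TP = 0, FP = FN: ratio 2FN/FN
        assert minkowski_measure(PairConfusion(0, 3, 3, 1)) == pytest.approx(sqrt(2))

    def test_undefined_without_coclustered_reference(self):
        with pytest.raises(ValueError):
            minkowski_measure(PairConfusion(0, 2, 0, 4))


class TestSilhouette:
    def test_duplicated_profiles_score_one(self):
        data = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        assert silhouette(data, [1, 1, 2, 2]) == 1.0

    def test_two_singletons_zero_by_convention(self):
        assert silhouette(np.array([[0.0], [3.0]]), [1, 2]) == 0.0

    def test_hand_arithmetic_1d(self):
        # x = 0,1 | 5,6: s-values 9/11, 7/9, 7/9, 9/11 -> mean 79/99
        data = np.array([[0.0], [1.0], [5.0], [6.0]])
        assert silhouette(data, [1, 1, 2, 2]) == pytest.approx(79 / 99, abs=1e-15)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((3, 2)), [1, 1, 1])

    def test_matches_reference_implementation(self, rng):
        from sklearn.metrics import silhouette_score

        data = rng.standard_normal((20, 4))
        labels = rng.integers(0, 3, 20)
        if len(set(labels.tolist())) < 2:
            labels[0] = (labels[0] + 1) % 3
        assert silhouette(data, labels) == pytest.approx(
            silhouette_score(data, labels), abs=1e-12
        )

    def test_duplicating_a_member_never_hurts_its_cluster(self, rng):
        data = rng.standard_normal((9, 3))
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        base = silhouette(data, labels)
        grown = np.vstack([data, data[0]])
        grown_labels = np.append(labels, 1)
        assert silhouette(grown, grown_labels) >= base - 1e-9


class TestDunn:
    def test_scale_invariance(self, rng):
        data = rng.standard_normal((12, 3))
        labels = rng.integers(0, 3, 12)
        labels[:3] = [0, 1, 2]
        base = dunn(data, labels)
        assert dunn(data * 7.3, labels) == pytest.approx(base, abs=1e-10)

    def test_far_tight_clusters_large(self):
        data = np.vstack([np.zeros((3, 2)), np.full((3, 2), 10.0)])
        data += 0.01 * np.arange(6)[:, None]
        assert dunn(data, [1, 1, 1, 2, 2, 2]) > 1

    def test_matches_enumeration_oracle(self, rng):
        from scipy.spatial.distance import pdist, squareform

        data = rng.standard_normal((9, 2))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        D = squareform(pdist(data))
        diam = max(
            D[np.ix_(np.where(labels == c)[0], np.where(labels == c)[0])].max()
            for c in range(3)
        )
        sep = min(
            D[np.ix_(np.where(labels == a)[0], np.where(labels == b)[0])].min()
            for a in range(3)
            for b in range(3)
            if a != b
        )
        assert dunn(data, labels) == pytest.approx(sep / diam, abs=1e-12)


class TestDaviesBouldin:
    def test_separated_clusters_small(self):
        data = np.vstack([np.zeros((4, 2)), np.full((4, 2), 10.0)])
        data += 0.05 * np.arange(8)[:, None]
        assert davies_bouldin(data, [1] * 4 + [2] * 4) < 0.5

    def test_symmetric_two_cluster_terms_equal(self):
        data = np.array([[0.0], [1.0], [5.0], [6.0]])
        # both clusters: dispersion 0.5, separation 5 -> DBI = 1/5
        assert davies_bouldin(data, [1, 1, 2, 2]) == pytest.approx(0.2, abs=1e-15)

    def test_matches_reference_implementation(self, rng):
        from sklearn.metrics import davies_bouldin_score

        data = rng.standard_normal((20, 3))
        labels = rng.integers(0, 3, 20)
        labels[:3] = [0, 1, 2]
        assert davies_bouldin(data, labels) == pytest.approx(
            davies_bouldin_score(data, labels), abs=1e-10
        )

    def test_coincident_centroids_rejected(self):
        data = np.array([[0.0, 1], [0, -1], [1, 0], [-1, 0]])
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin(data, [1, 1, 2, 2])


class TestCorrelationMode:
    def test_correlation_dissimilarity_available(self, rng):
        t = np.arange(8.0)
        data = np.vstack([np.sin(t), np.sin(t) * 3 + 1, np.cos(t), np.cos(t) - 2])
        # affinely related profiles are identical under d = 1 - Pearson
        assert validity.silhouette(data, [1, 1, 2, 2], "correlation") == pytest.approx(
            1.0
        )
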