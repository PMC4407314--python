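import numpy as np
import pytest

from apconsensus.consensus import RelativityMatrix
from apconsensus.graph import Partition
from apconsensus.refine import classify, default_phi, refine
from apconsensus.synthetic import toy_fixture


def rel(matrix):
    m = np.asarray(matrix, dtype=float)
    np.fill_diagonal(m, 1.0)
    return RelativityMatrix(m, vote_count=1)


def uniform_relativity(n, off=0.0):
    return rel(np.full((n, n), off))


class TestClassify:
    def test_phi_one_no_subclusters(self):
        part = Partition(np.array([1, 1, 2, 3]))
        cls = classify(part, phi=1)
        assert cls.sub == []
        assert set(cls.major) == {1, 2, 3}

    def test_size_split(self):
        labels = np.array([1] * 10 + [2] * 3 + [3])
        cls = classify(Partition(labels), phi=5)
        assert cls.major == [1] and cls.sub == [2, 3]

    def test_random_partition_matches_size_comparison(self, rng):
        labels = Partition(rng.integers(1, 6, 40)).labels
        part = Partition(labels)
        phi = 7
        cls = classify(part, phi)
        sizes = part.sizes()
        for c in cls.major:
            assert sizes[c - 1] >= phi
        for c in cls.sub:
            assert sizes[c - 1] < phi

    def test_phi_too_large_rejected(self):
        with pytest.raises(ValueError):
            classify(Partition(np.array([1, 1, 2])), phi=3)


class TestDefaultPhi:
    @pytest.mark.parametrize("n,expected", [(50, 2), (100, 2), (300, 3), (1000, 10)])
    def test_scale_free_floor(self, n, expected):
        assert default_phi(n) == expected


class TestRuleOne:
    def test_low_relativity_singleton_survives(self, rng):
        # all relativities below 0.5: every singleton is terminal
        part = Partition(np.arange(1, 6))
        R = uniform_relativity(5, off=0.4)
        data = rng.standard_normal((5, 6))
        out = refine(part, R, data, phi=2)
        assert out.n_clusters == 5

    def test_high_relativity_merges_into_major(self):
        # genes 0-3 one major cluster; singleton gene 4 tied to gene 0
        m = np.full((5, 5), 0.1)
        m[:4, :4] = 0.9
        m[0, 4] = m[4, 0] = 0.8
        part = Partition(np.array([1, 1, 1, 1, 2]))
        data = np.vstack([np.sin(np.arange(6))] * 5)
        out = refine(part, rel(m), data, phi=3)
        assert out.n_clusters == 1

    def test_two_mutual_singletons_merge_but_stay_sub(self, rng):
        # relativity 0.6 between the two singletons only; merged pair has
        # size 2 < phi=3 and anticorrelated means keep it unmerged after
        t = np.arange(8, dtype=float)
        base = np.sin(2 * np.pi * t / 7)
        data = np.vstack([base, base, base, base, -base, -base])
        m = np.full((6, 6), 0.1)
        m[:4, :4] = 0.9
        m[4, 5] = m[5, 4] = 0.6
        part = Partition(np.array([1, 1, 1, 1, 2, 3]))
        out = refine(part, rel(m), data, phi=3)
        assert out.n_clusters == 2
        assert out.labels[4] == out.labels[5]
        assert out.labels[4] != out.labels[0]


class TestRuleTwo:
    def test_anticorrelated_subcluster_survives(self):
        matrix, labels = toy_fixture("rule2-anticorrelated")
        part = Partition(labels)
        R = uniform_relativity(10, off=0.2)
        out = refine(part, R, matrix.values, phi=3)
        assert out.n_clusters == 3  # the anticorrelated pair is kept

    def test_identical_mean_merges(self):
        t = np.arange(8, dtype=float)
        a = np.sin(2 * np.pi * t / 7)
        b = np.cos(2 * np.pi * t / 7)
        data = np.vstack([a] * 4 + [b] * 4 + [a, a])
        part = Partition(np.array([1] * 4 + [2] * 4 + [3, 3]))
        out = refine(part, uniform_relativity(10, 0.2), data, phi=3)
        assert out.n_clusters == 2
        assert out.labels[8] == out.labels[0]

    def test_argmax_correlation_target(self):
        # three majors with distinct means; the sub tracks the middle one
        t = np.linspace(0, 2 * np.pi, 9)
        means = [np.sin(t), np.sin(t + 2), np.sin(t + 4)]
        rows = []
        for m in means:
            rows += [m] * 4
        sub = np.sin(t + 2.1)  # closest to means[1]
        rows += [sub, sub]
        part = Partition(np.array([1] * 4 + [2] * 4 + [3] * 4 + [4, 4]))
        out = refine(part, uniform_relativity(14, 0.2), np.vstack(rows), phi=3)
        assert out.n_clusters == 3
        assert out.labels[12] == out.labels[4]

    def test_no_major_clusters_keeps_subs(self, rng):
        data = rng.standard_normal((4, 6))
        part = Partition(np.array([1, 1, 2, 2]))
        out = refine(part, uniform_relativity(4, 0.9), data, phi=3)
        assert out.n_clusters == 2  # Rule 2 presupposes a major cluster


class TestRefineContract:
    def test_no_subclusters_unchanged(self, rng):
        part = Partition(np.array([1] * 5 + [2] * 5))
        data = rng.standard_normal((10, 6))
        out = refine(part, uniform_relativity(10), data, phi=3)
        np.testing.assert_array_equal(out.labels, part.labels)

    def test_gene_conservation(self, rng):
        labels = Partition(rng.integers(1, 8, 30)).labels
        data = rng.standard_normal((30, 8))
        m = rng.random((30, 30))
        R = rel((m + m.T) / 2)
        out = refine(Partition(labels), R, data, phi=4)
        assert out.labels.size == 30
        assert np.all(out.labels >= 1)
        assert out.n_clusters == len(set(out.labels.tolist()))

    def test_majors_never_split(self, rng):
        labels = np.array([1] * 10 + [2] * 10 + [3])
        data = rng.standard_normal((21, 8))
        m = rng.random((21, 21))
        out = refine(Partition(labels), rel((m + m.T) / 2), data, phi=4)
        # genes that shared a major cluster still share a cluster
        assert len(set(out.labels[:10])) == 1
        assert len(set(out.labels[10:20])) == 1

    def test_idempotence(self, rng):
        labels = Partition(rng.integers(1, 10, 40)).labels
        data = rng.standard_normal((40, 8))
        m = rng.random((40, 40))
        R = rel((m + m.T) / 2)
        once = refine(Partition(labels), R, data, phi=4)
        twice = refine(once, R, data, phi=4)
        np.testing.assert_array_equal(once.labels, twice.labels)
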