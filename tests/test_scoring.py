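"""Unit tests for progeny sampling, co-occurrence, and the stability score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from progenyclust import (
    RunConfig,
    aggregate_cooccurrence,
    cooccurrence_matrix,
    sample_progenies,
    stability_curve,
    stability_score,
)


# ---------------------------------------------------------------- sampling
class TestSampleProgenies:
    def test_singleton_cluster_forces_replication(self, rng):
        X = np.array([[1.0, 2.0], [5.0, 5.0], [5.1, 5.2]])
        labels = np.array([0, 1, 1])
        progenies, block_of = sample_progenies(X, labels, 3, rng)
        assert progenies.shape == (6, 2)
        np.testing.assert_array_equal(progenies[:3], np.tile([1.0, 2.0], (3, 1)))
        np.testing.assert_array_equal(block_of, [0, 0, 0, 1, 1, 1])

    def test_feature_independence_frequencies(self, rng):
        # two members (0,0) and (1,1): independent feature draws must
        # produce all four corner combinations with probability 1/4 each
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        labels = np.array([0, 0])
        progenies, _ = sample_progenies(X, labels, 40_000, rng)
        combos, counts = np.unique(progenies, axis=0, return_counts=True)
        assert len(combos) == 4
        freqs = counts / counts.sum()
        np.testing.assert_allclose(freqs, 0.25, atol=0.01)

    def test_row_count_is_clusters_times_n(self, rng):
        X = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, size=30)
        labels[:3] = [0, 1, 2]  # ensure non-empty
        progenies, block_of = sample_progenies(X, labels, 10, rng)
        assert progenies.shape == (30, 3)
        # block-contiguous ordering
        np.testing.assert_array_equal(block_of, np.repeat([0, 1, 2], 10))

    def test_progeny_values_come_from_source_cluster(self, rng):
        X = rng.normal(size=(20, 4))
        labels = np.repeat([0, 1], 10)
        progenies, block_of = sample_progenies(X, labels, 25, rng)
        for k in (0, 1):
            members = X[labels == k]
            block = progenies[block_of == k]
            for j in range(X.shape[1]):
                assert set(block[:, j]) <= set(members[:, j])

    def test_invalid_inputs(self, rng):
        X = np.eye(4)
        with pytest.raises(ValueError, match="n_progenies"):
            sample_progenies(X, np.array([0, 0, 1, 1]), 0, rng)
        with pytest.raises(ValueError, match="invalid assignment"):
            sample_progenies(X, np.array([0, 0, 2, 2]), 3, rng)


# ----------------------------------------------------------- co-occurrence
class TestCooccurrence:
    def test_two_block_example(self):
        q = cooccurrence_matrix(np.array([0, 0, 1, 1]))
        expected = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]]
        )
        np.testing.assert_array_equal(q, expected)

    def test_single_cluster_gives_all_ones(self):
        q = cooccurrence_matrix(np.zeros(5, dtype=int))
        np.testing.assert_array_equal(q, np.ones((5, 5)))

    def test_relabelling_clusters_leaves_q_unchanged(self):
        labels = np.array([0, 1, 2, 1, 0, 2])
        perm = np.array([2, 0, 1])  # rename clusters
        np.testing.assert_array_equal(
            cooccurrence_matrix(labels), cooccurrence_matrix(perm[labels])
        )

    @given(st.lists(st.integers(0, 4), min_size=2, max_size=20))
    @settings(deadline=None)
    def test_symmetry_and_unit_diagonal(self, labels):
        q = cooccurrence_matrix(np.array(labels))
        np.testing.assert_array_equal(q, q.T)
        np.testing.assert_array_equal(np.diag(q), 1)

    def test_aggregate_mean_and_errors(self):
        q1 = cooccurrence_matrix(np.array([0, 0, 1, 1]))
        q2 = cooccurrence_matrix(np.array([0, 1, 1, 1]))
        np.testing.assert_array_equal(aggregate_cooccurrence([q1]), q1)
        p = aggregate_cooccurrence([q1, q2])
        assert p[0, 1] == 0.5
        assert p[2, 3] == 1.0
        np.testing.assert_array_equal(p, p.T)
        np.testing.assert_array_equal(np.diag(p), 1.0)
        assert p.min() >= 0 and p.max() <= 1
        with pytest.raises(ValueError, match="at least one"):
            aggregate_cooccurrence([])
        with pytest.raises(ValueError, match="shape"):
            aggregate_cooccurrence([q1, np.ones((3, 3))])


# ------------------------------------------------------------------- score
def naive_stability_score(P, n_clusters, n_progenies, n_repeats):
    """Independent O((Kn)^2) double-loop oracle for the stability score."""
    m = n_clusters * n_progenies
    true_sum = true_cnt = false_sum = false_cnt = 0
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            same = i // n_progenies == j // n_progenies
            if same:
                true_sum += P[i, j]
                true_cnt += 1
            else:
                false_sum += P[i, j]
                false_cnt += 1
    eps = 1.0 / (n_repeats * false_cnt)
    return (true_sum / true_cnt) / max(false_sum / false_cnt, eps)


class TestStabilityScore:
    def test_uniform_probability_scores_one(self):
        # random assignment to K clusters puts any pair together with
        # probability 1/K everywhere, so true and false means coincide
        k, n = 3, 4
        p = np.full((k * n, k * n), 1.0 / k)
        np.fill_diagonal(p, 1.0)
        assert stability_score(p, k, n, n_repeats=100) == pytest.approx(1.0)

    def test_perfect_block_diagonal_hits_epsilon_ceiling(self):
        k, n, r = 2, 3, 50
        p = np.kron(np.eye(k), np.ones((n, n)))
        n_false = (k - 1) * k * n * n
        assert stability_score(p, k, n, r) == pytest.approx(r * n_false)

    def test_explicit_two_cluster_example(self):
        # true off-diagonal entries {0.8, 0.8, 0.6, 0.6}, false entries 0.1
        p = np.array(
            [
                [1.0, 0.8, 0.1, 0.1],
                [0.8, 1.0, 0.1, 0.1],
                [0.1, 0.1, 1.0, 0.6],
                [0.1, 0.1, 0.6, 1.0],
            ]
        )
        assert stability_score(p, 2, 2, 100) == pytest.approx(7.0)

    def test_single_progeny_rejected(self):
        with pytest.raises(ValueError, match="n_progenies"):
            stability_score(np.eye(3), 3, 1, 10)

    @pytest.mark.parametrize("k,n,r", [(2, 2, 3), (3, 4, 5), (5, 6, 2), (2, 15, 4)])
    def test_matches_naive_double_loop_oracle(self, k, n, r, rng):
        # aggregate R random co-occurrence matrices, then compare the
        # vectorised score against an exhaustive per-entry computation
        qs = [
            cooccurrence_matrix(rng.integers(0, k, size=k * n)) for _ in range(r)
        ]
        p = aggregate_cooccurrence(qs)
        fast = stability_score(p, k, n, r)
        slow = naive_stability_score(p, k, n, r)
        assert fast == pytest.approx(slow, rel=1e-12)


# ------------------------------------------------------------------- curve
class TestStabilityCurve:
    def test_same_seed_gives_identical_curves(self, blobs_2d, small_config):
        X, _ = blobs_2d
        s1 = stability_curve(X, small_config, 42)
        s2 = stability_curve(X, small_config, 42)
        assert s1 == s2

    def test_curve_spans_requested_range(self, blobs_2d, small_config):
        X, _ = blobs_2d
        scores, assignments = stability_curve(
            X, small_config, 0, return_assignments=True
        )
        assert sorted(scores) == [2, 3, 4]
        assert all(s >= 0 and np.isfinite(s) for s in scores.values())
        for k, lab in assignments.items():
            assert len(np.unique(lab)) == k
            assert lab.shape == (X.shape[0],)

    def test_k_max_beyond_sample_size_rejected(self, small_config):
        X = np.eye(3)
        with pytest.raises(ValueError, match="k_max"):
            stability_curve(X, small_config, 0)
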