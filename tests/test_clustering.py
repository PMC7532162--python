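import numpy as np
import pytest

from hippoparc.clustering import (
    Partition,
    SolverConfig,
    kmeans_baseline,
    nassoc,
    objective,
    solve,
    spatial_score,
    supervision_score,
)
from hippoparc.graph import PriorLabels, RoiGraph, build_kernel, build_supervision

from conftest import (
    enumerate_partitions,
    nassoc_oracle,
    random_partition_labels,
    random_similarity,
    spatial_oracle,
    supervision_oracle,
)


def block_graph():
    """Two 3-node blocks with zero cross-block similarity."""
    A = np.zeros((6, 6))
    A[:3, :3] = 1.0
    A[3:, 3:] = 1.0
    np.fill_diagonal(A, 2.0)
    return RoiGraph(A)


class TestNassoc:
    def test_single_cluster_is_one(self):
        rng = np.random.default_rng(0)
        g = RoiGraph(random_similarity(rng, 7))
        assert nassoc(Partition(np.ones(7, dtype=int), 1), g) == pytest.approx(1.0)

    def test_block_diagonal_attains_k(self):
        g = block_graph()
        part = Partition(np.array([1, 1, 1, 2, 2, 2]), 2)
        assert nassoc(part, g) == pytest.approx(2.0)

    def test_bruteforce_maximum_identified(self):
        rng = np.random.default_rng(1)
        A = random_similarity(rng, 4)
        g = RoiGraph(A)
        values = {
            tuple(lab): nassoc(Partition(lab, 2), g)
            for lab in enumerate_partitions(4, 2)
        }
        oracle = {lab: nassoc_oracle(np.array(lab), A) for lab in values}
        for lab, v in values.items():
            assert v == pytest.approx(oracle[lab], abs=1e-12)
        assert max(values.values()) == pytest.approx(max(oracle.values()), abs=1e-12)

    def test_bounded_by_k(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(5, 12))
            k = int(rng.integers(2, 4))
            g = RoiGraph(random_similarity(rng, n))
            part = Partition(random_partition_labels(rng, n, k), k)
            assert nassoc(part, g) <= k + 1e-12


class TestSupervisionScore:
    def test_six_node_toy_matches_hand_sum(self):
        rng = np.random.default_rng(3)
        A = random_similarity(rng, 6)
        g = RoiGraph(A)
        prior_sets = [np.array([0, 1]), np.array([2, 3])]
        S = build_supervision(PriorLabels(prior_sets, 6))
        labels = np.array([1, 1, 2, 1, 2, 2])
        val = supervision_score(Partition(labels, 2), S, g)
        assert val == pytest.approx(
            supervision_oracle(labels, prior_sets, A), abs=1e-12
        )

    def test_prior_honoring_partition_non_negative(self):
        rng = np.random.default_rng(4)
        g = RoiGraph(random_similarity(rng, 6))
        S = build_supervision(PriorLabels([np.array([0, 1]), np.array([3, 4])], 6))
        honoring = Partition(np.array([1, 1, 1, 2, 2, 2]), 2)
        assert supervision_score(honoring, S, g) >= 0
        # all prior pairs split, all cross-prior pairs co-clustered
        violating = Partition(np.array([1, 2, 1, 1, 2, 2]), 2)
        assert supervision_score(violating, S, g) <= 0


class TestSpatialScore:
    def test_chain_values(self):
        A = np.full((4, 4), 1.0)
        np.fill_diagonal(A, 2.0)
        g = RoiGraph(A)
        R = np.zeros((4, 4))
        for i in range(3):
            R[i, i + 1] = R[i + 1, i] = 1.0
        one = Partition(np.ones(4, dtype=int), 1)
        assert spatial_score(one, R, g) == pytest.approx(6.0 / g.degrees.sum())
        # split every adjacent pair
        alt = Partition(np.array([1, 2, 1, 2]), 2)
        assert spatial_score(alt, R, g) == pytest.approx(0.0)

    def test_matches_oracle(self):
        rng = np.random.default_rng(5)
        A = random_similarity(rng, 8)
        R = (rng.random((8, 8)) < 0.3).astype(float)
        R = np.triu(R, 1)
        R = R + R.T
        labels = random_partition_labels(rng, 8, 3)
        val = spatial_score(Partition(labels, 3), R, RoiGraph(A))
        assert val == pytest.approx(spatial_oracle(labels, R, A), abs=1e-12)


class TestObjective:
    def test_reduces_to_nassoc_and_is_linear_in_alpha(self):
        rng = np.random.default_rng(6)
        A = random_similarity(rng, 7)
        g = RoiGraph(A)
        S = build_supervision(PriorLabels([np.array([0, 1]), np.array([4, 5])], 7))
        R = (rng.random((7, 7)) < 0.4).astype(float)
        R = np.triu(R, 1)
        R = R + R.T
        labels = random_partition_labels(rng, 7, 2)
        part = Partition(labels, 2)
        base = objective(part, g, S, R, alpha=0.0, lam=0.0)
        assert base.total == pytest.approx(base.nassoc)
        o1 = objective(part, g, S, R, alpha=1.0, lam=0.5)
        o2 = objective(part, g, S, R, alpha=2.0, lam=0.5)
        # linear in alpha at fixed partition
        assert o2.total - o1.total == pytest.approx(o1.supervision, abs=1e-12)
        assert o1.total == pytest.approx(
            o1.nassoc + 1.0 * o1.supervision + 0.5 * o1.spatial, abs=1e-12
        )


class TestSolve:
    def test_recovers_separated_blocks(self):
        g = block_graph()
        kern = build_kernel(g, None, None)
        res = solve(kern, 2, g, config=SolverConfig(n_restarts=8, rng_seed=0))
        labels = res.partition.labels
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        assert res.objective.nassoc == pytest.approx(2.0)

    def test_k_equals_n_singletons(self):
        rng = np.random.default_rng(7)
        A = random_similarity(rng, 4)
        g = RoiGraph(A)
        kern = build_kernel(g, None, None)
        res = solve(kern, 4, g, config=SolverConfig(n_restarts=20, rng_seed=0))
        assert sorted(res.partition.labels) == [1, 2, 3, 4]
        expected = sum(A[c, c] / A[c].sum() for c in range(4))
        assert res.objective.nassoc == pytest.approx(expected)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        g = RoiGraph(random_similarity(rng, 12))
        kern = build_kernel(g, None, None)
        cfg = SolverConfig(n_restarts=5, rng_seed=42)
        r1 = solve(kern, 3, g, config=cfg)
        r2 = solve(kern, 3, g, config=SolverConfig(n_restarts=5, rng_seed=42))
        np.testing.assert_array_equal(r1.partition.labels, r2.partition.labels)

    def test_k_larger_than_n_rejected(self):
        g = RoiGraph(np.array([[2.0, 1.0], [1.0, 2.0]]))
        kern = build_kernel(g, None, None)
        with pytest.raises(ValueError):
            solve(kern, 3, g)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        A = random_similarity(rng, 10)
        perm = rng.permutation(10)
        g1, g2 = RoiGraph(A), RoiGraph(A[np.ix_(perm, perm)])
        init = random_partition_labels(rng, 10, 2)
        r1 = solve(build_kernel(g1, None, None), 2, g1, init_labels=init)
        r2 = solve(build_kernel(g2, None, None), 2, g2, init_labels=init[perm])
        # the same partition up to node relabeling
        l1, l2 = r1.partition.labels, r2.partition.labels
        same1 = l1[:, None] == l1[None, :]
        same2 = l2[:, None] == l2[None, :]
        np.testing.assert_array_equal(same1[np.ix_(perm, perm)], same2)


class TestKmeansBaseline:
    def test_duplicated_row_blocks_recovered(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        np.fill_diagonal(A, 2.0)
        part = kmeans_baseline(RoiGraph(A), 2, seed=0)
        labels = part.labels
        assert len(set(labels[:3])) == 1 and labels[0] != labels[3]

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        g = RoiGraph(random_similarity(rng, 15))
        p1 = kmeans_baseline(g, 3, seed=5)
        p2 = kmeans_baseline(g, 3, seed=5)
        np.testing.assert_array_equal(p1.labels, p2.labels)
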