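"""Spectral consensus clustering: kernel, embedding, consensus, k selection."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oncomodules.spectral import (consensus_labels, consensus_modules,
                                  final_partition, gaussian_kernel, pac,
                                  select_k, select_k_coarse_fine, select_sigma,
                                  spectral_cluster, to_pseudo_distance)

from conftest import planted_block_affinity


class TestPseudoDistance:
    def test_reciprocal(self):
        W = np.array([[0.0, 2.0], [2.0, 0.0]])
        D = to_pseudo_distance(W)
        assert D[0, 1] == 0.5

    def test_absent_edge_infinite_then_zero_affinity(self):
        W = np.zeros((2, 2))
        D = to_pseudo_distance(W)
        assert np.isinf(D[0, 1])
        assert gaussian_kernel(D, 1.0)[0, 1] == 0.0

    def test_elementwise_matches_oracle(self):
        rng = np.random.default_rng(0)
        W = rng.integers(0, 5, size=(6, 6)).astype(float)
        W = np.triu(W, 1) + np.triu(W, 1).T
        D = to_pseudo_distance(W)
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert D[i, j] == 0.0
                elif W[i, j] > 0:
                    assert D[i, j] == 1.0 / W[i, j]
                else:
                    assert np.isinf(D[i, j])


class TestGaussianKernel:
    def test_unit_distance_unit_sigma(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        A = gaussian_kernel(D, 1.0)
        assert A[0, 1] == pytest.approx(np.exp(-0.5))

    def test_zero_distance_gives_one(self):
        D = np.array([[0.0, 0.0], [0.0, 0.0]])
        assert gaussian_kernel(D, 1.0)[0, 1] == 1.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.zeros((2, 2)), 0.0)

    def test_monotone_in_weight(self):
        """Larger co-regulation weight never yields smaller affinity."""
        W = np.array([[0, 1, 5], [1, 0, 2], [5, 2, 0]], dtype=float)
        A = gaussian_kernel(to_pseudo_distance(W), 0.5)
        assert A[0, 2] >= A[0, 1]
        assert A[0, 2] >= A[1, 2]


class TestSelectSigma:
    def test_degenerate_distribution(self):
        D = to_pseudo_distance(np.array([[0, 4, 4], [4, 0, 4], [4, 4, 0.0]]))
        assert select_sigma(D, 0.1) == 0.25
        assert select_sigma(D, 0.9) == 0.25

    def test_median_of_distances(self):
        D = np.full((5, 5), np.inf)
        np.fill_diagonal(D, 0.0)
        vals = [0.1, 0.2, 0.3, 0.4]
        idx = [(0, 1), (1, 2), (2, 3), (3, 4)]
        for (i, j), v in zip(idx, vals):
            D[i, j] = D[j, i] = v
        assert select_sigma(D, 0.5) == pytest.approx(np.quantile(vals, 0.5))

    def test_edgeless_graph_rejected(self):
        D = np.full((3, 3), np.inf)
        np.fill_diagonal(D, 0.0)
        with pytest.raises(ValueError, match="edgeless"):
            select_sigma(D)


class TestSpectralCluster:
    def test_two_disjoint_cliques(self):
        W = np.zeros((10, 10))
        W[:5, :5] = 3.0
        W[5:, 5:] = 3.0
        np.fill_diagonal(W, 0.0)
        A = gaussian_kernel(to_pseudo_distance(W), 1.0)
        part = spectral_cluster(A, 2, seed=0)
        assert adjusted_rand_score([0] * 5 + [1] * 5,
                                   part.labels.to_numpy()) == 1.0

    def test_saturation_each_node_own_module(self):
        rng = np.random.default_rng(1)
        A = planted_block_affinity(rng, [3, 3])
        part = spectral_cluster(A, 6, seed=0)
        assert part.labels.nunique() == 6

    def test_planted_three_blocks(self, blocks3):
        A, truth = blocks3
        part = consensus_labels(consensus_modules(A, 3, runs=50, base_seed=2), 3)
        assert adjusted_rand_score(truth, part.labels.to_numpy()) == 1.0

    def test_isolated_nodes_get_sink_module(self):
        rng = np.random.default_rng(3)
        A = planted_block_affinity(rng, [5, 5])
        B = np.zeros((12, 12))
        B[:10, :10] = A  # two isolates appended
        part = spectral_cluster(B, 2, seed=0)
        labels = part.labels.to_numpy()
        assert labels[10] == labels[11] == 3  # sink = k + 1

    def test_fixed_seed_reproducible(self, blocks3):
        A, _ = blocks3
        a = spectral_cluster(A, 3, seed=123).labels
        b = spectral_cluster(A, 3, seed=123).labels
        assert (a == b).all()

    def test_node_permutation_equivariance(self, blocks3):
        """Permuting node order permutes labels consistently."""
        A, _ = blocks3
        rng = np.random.default_rng(4)
        perm = rng.permutation(A.shape[0])
        part = spectral_cluster(A, 3, seed=9)
        part_p = spectral_cluster(A[np.ix_(perm, perm)], 3, seed=9)
        assert adjusted_rand_score(part.labels.to_numpy()[perm],
                                   part_p.labels.to_numpy()) == 1.0


class TestConsensus:
    def test_identical_runs_give_binary_entries(self, blocks3):
        A, _ = blocks3
        cons = consensus_modules(A, 3, runs=20, base_seed=0)
        assert np.all(np.isin(np.round(cons.matrix, 6), [0.0, 1.0]))

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(5)
        A = planted_block_affinity(rng, [4, 4], jitter=0.9)
        cons = consensus_modules(A, 2, runs=10, base_seed=1)
        assert np.allclose(cons.matrix, cons.matrix.T)
        assert np.allclose(np.diag(cons.matrix), 1.0)
        assert cons.matrix.min() >= 0.0 and cons.matrix.max() <= 1.0

    def test_two_runs_half_frequency(self):
        """An entry from 2 runs agreeing once is exactly 0.5."""
        rng = np.random.default_rng(6)
        # three symmetric blocks at k=2: which pair merges depends on init
        A = planted_block_affinity(rng, [4, 4, 4], jitter=0.2)
        found = False
        for base in range(30):
            cons = consensus_modules(A, 2, runs=2, base_seed=base)
            off = cons.matrix[np.triu_indices(12, 1)]
            if np.any(np.isclose(off, 0.5)):
                found = True
                break
        assert found, "no half-frequency entry over 30 seed pairs"

    def test_pac_bounds(self, blocks3):
        A, _ = blocks3
        cons = consensus_modules(A, 4, runs=20, base_seed=0)
        assert 0.0 <= pac(cons.matrix) <= 1.0


class TestSelectK:
    def test_three_blocks_selects_three(self, blocks3):
        A, _ = blocks3
        k, table = select_k(A, list(range(2, 7)), runs=40, base_seed=0)
        assert k == 3
        assert table["stability"].between(0, 1).all()

    def test_single_block_collapses_to_smallest(self):
        rng = np.random.default_rng(7)
        A = planted_block_affinity(rng, [20], jitter=0.8)
        k, _ = select_k(A, [2, 3, 4], runs=30, base_seed=0)
        assert k == 2

    def test_coarse_fine_matches_planted(self):
        rng = np.random.default_rng(8)
        A = planted_block_affinity(rng, [8] * 6)
        k, _ = select_k_coarse_fine(A, coarse_ks=(5, 10, 15), runs=30,
                                    base_seed=0)
        assert k == 6


class TestFinalPartition:
    def test_deterministic_given_seed(self, blocks3):
        A, _ = blocks3
        a = final_partition(A, 3, seed=77).labels
        b = final_partition(A, 3, seed=77).labels
        assert (a == b).all()

    def test_matches_consensus_majority_on_separated_blocks(self, blocks3):
        A, truth = blocks3
        single = final_partition(A, 3, seed=5)
        major = consensus_labels(consensus_modules(A, 3, runs=30, base_seed=5), 3)
        assert adjusted_rand_score(single.labels.to_numpy(),
                                   major.labels.to_numpy()) == 1.0
        assert adjusted_rand_score(truth, single.labels.to_numpy()) == 1.0
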