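import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from stemcortex import communities as comm
from stemcortex.exceptions import ParameterError, ShapeError

from .oracles import all_partitions, exhaustive_best_q, modularity_naive


def _signed_random(n, rng, density=0.8):
    A = rng.standard_normal((n, n)) * (rng.random((n, n)) < density)
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


def two_clique_matrix():
    """Two 3-cliques of unit weight joined by nothing."""
    W = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    W[i, j] = 1.0
    return W


class TestModularity:
    def test_two_cliques_q_half(self):
        W = two_clique_matrix()
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert comm.modularity_q(W, labels, gamma=1.0) == pytest.approx(0.5)

    def test_matches_naive_oracle_on_signed_matrices(self, rng):
        for _ in range(5):
            W = _signed_random(7, rng)
            labels = rng.integers(0, 3, 7)
            for gamma in (0.5, 1.0, 2.0):
                assert comm.modularity_q(W, labels, gamma) == pytest.approx(
                    modularity_naive(W, labels, gamma), abs=1e-12)

    def test_single_community_at_gamma1_nonneg_matrix_is_zero(self, rng):
        W = np.abs(_signed_random(6, rng))
        q = comm.modularity_q(W, np.zeros(6, dtype=int), gamma=1.0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ParameterError):
            comm.modularity_q(np.zeros((4, 4)), np.arange(4))

    def test_asymmetric_matrix_raises(self):
        W = np.triu(np.ones((4, 4)), 1)
        with pytest.raises(ShapeError):
            comm.modularity_q(W, np.arange(4))


class TestLouvain:
    def test_recovers_two_cliques(self):
        part = comm.louvain(two_clique_matrix(), gamma=1.0, seed=0)
        assert part.n_communities == 2
        assert part.labels[0] == part.labels[1] == part.labels[2]
        assert part.labels[3] == part.labels[4] == part.labels[5]
        assert part.quality == pytest.approx(0.5)

    def test_never_exceeds_exhaustive_max_small(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 7))
            W = _signed_random(n, rng)
            best = exhaustive_best_q(W, 1.0)
            part = comm.louvain(W, gamma=1.0, seed=int(rng.integers(1000)))
            assert part.quality <= best + 1e-9

    def test_deterministic_given_seed(self, rng):
        W = _signed_random(12, rng)
        a = comm.louvain(W, gamma=1.5, seed=7)
        b = comm.louvain(W, gamma=1.5, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert a.quality == b.quality

    def test_labels_canonical(self, rng):
        W = _signed_random(12, rng)
        part = comm.louvain(W, gamma=2.0, seed=3)
        seen = []
        for v in part.labels:
            if v not in seen:
                seen.append(v)
        assert seen == list(range(part.n_communities))

    def test_quality_matches_reported_partition(self, rng):
        W = _signed_random(10, rng)
        part = comm.louvain(W, gamma=1.2, seed=5)
        assert part.quality == pytest.approx(
            modularity_naive(W, part.labels, 1.2), abs=1e-12)


class TestPartitionSimilarity:
    def test_ari_matches_sklearn(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 4, 30)
            assert comm.adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12)

    def test_ari_identity_and_relabel_invariance(self, rng):
        a = rng.integers(0, 3, 20)
        assert comm.adjusted_rand_index(a, a) == pytest.approx(1.0)
        relabeled = (a + 1) % 3
        assert comm.adjusted_rand_index(a, relabeled) == pytest.approx(1.0)

    def test_zrand_symmetry_and_relabel_invariance(self, rng):
        a = rng.integers(0, 3, 25)
        b = rng.integers(0, 4, 25)
        z_ab = comm.zrand(a, b)
        assert z_ab == pytest.approx(comm.zrand(b, a), abs=1e-10)
        assert z_ab == pytest.approx(comm.zrand((a + 5) % 3 + 1, b), abs=1e-10)

    def test_zrand_self_exceeds_cross(self, rng):
        a = np.repeat([0, 1, 2], 10)
        b = rng.integers(0, 3, 30)
        assert comm.zrand(a, a) > comm.zrand(a, b)

    def test_zrand_degenerate_returns_nan_with_warning(self):
        ones = np.zeros(10, dtype=int)
        with pytest.warns(UserWarning, match="degenerate"):
            z = comm.zrand(ones, ones)
        assert np.isnan(z)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(42)
    labels = np.repeat(np.arange(3), 10)
    W = np.full((30, 30), -0.1)
    W[labels[:, None] == labels[None, :]] = 1.0
    W += 0.05 * rng.standard_normal((30, 30))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W, labels


class TestEnsembleAndConsensus:
    def test_ensemble_zrand_matches_naive_all_pairs(self, planted):
        W, _ = planted
        ens = comm.run_ensemble(W, 1.0, n_runs=12, seed=0)
        mean, var = comm.ensemble_zrand(ens)
        zs = []
        labs = [p.labels for p in ens.partitions]
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                zs.append(comm.zrand(labs[i], labs[j]))
        zs = np.asarray(zs)
        assert mean == pytest.approx(zs.mean(), abs=1e-10)
        assert var == pytest.approx(zs.var(), abs=1e-10)

    def test_consensus_recovers_planted(self, planted):
        W, labels = planted
        ens = comm.run_ensemble(W, 1.0, n_runs=20, seed=1)
        result = comm.consensus(ens, seed=1)
        assert comm.adjusted_rand_index(result.consensus.labels,
                                        labels) == pytest.approx(1.0)
        assert result.n_communities == 3

    def test_consensus_deterministic(self, planted):
        W, _ = planted
        r1 = comm.consensus(comm.run_ensemble(W, 1.0, n_runs=10, seed=2), seed=2)
        r2 = comm.consensus(comm.run_ensemble(W, 1.0, n_runs=10, seed=2), seed=2)
        assert np.array_equal(r1.consensus.labels, r2.consensus.labels)

    def test_gamma_sweep_grid_validation(self, planted):
        W, _ = planted
        with pytest.raises(ParameterError):
            comm.gamma_sweep(W, [1.0, 0.5], n_runs=2, seed=0)

    def test_default_gamma_grid(self):
        grid = comm.default_gamma_grid()
        assert grid.size == 60
        assert grid[0] == pytest.approx(0.1)
        assert grid[-1] == pytest.approx(6.0)
        assert np.allclose(np.diff(grid), 0.1)


class TestStablePlateaus:
    @staticmethod
    def _fake_sweep(ks, zvars=None):
        out = []
        for i, k in enumerate(ks):
            part = comm.Partition(np.arange(k), 0.1 * (i + 1), 0.0)
            zv = 0.0 if zvars is None else zvars[i]
            out.append(comm.ConsensusResult(part, 10.0, zv, k, 0.1 * (i + 1)))
        return out

    def test_longest_plateau_first(self):
        sweep = self._fake_sweep([2, 3, 3, 3, 3, 5, 5])
        plats = comm.stable_plateaus(sweep)
        assert plats[0].n_communities == 3
        assert plats[0].length == 4
        assert plats[0].gamma_min == pytest.approx(0.2)
        assert plats[0].gamma_max == pytest.approx(0.5)

    def test_tie_broken_by_lower_variance(self):
        sweep = self._fake_sweep([2, 2, 7, 7], zvars=[5.0, 5.0, 0.1, 0.1])
        plats = comm.stable_plateaus(sweep)
        assert plats[0].n_communities == 7

    def test_representative_is_middle_gamma(self):
        sweep = self._fake_sweep([4, 4, 4])
        plats = comm.stable_plateaus(sweep)
        assert plats[0].representative.gamma == pytest.approx(0.2)

    def test_empty_sweep_raises(self):
        with pytest.raises(ParameterError):
            comm.stable_plateaus([])


class TestCommunityDegreeMaps:
    def test_sums_match_manual(self, small_group):
        n_bs = small_group.scheme.n_brainstem
        labels = np.arange(n_bs) % 2
        part = comm.Partition(labels, 1.0, 0.0)
        maps = comm.community_degree_maps(small_group, part)
        assert len(maps) == 2
        bst = small_group.scheme.indices("brainstem")
        ctx = small_group.scheme.indices("cortex")
        manual = small_group.matrix[np.ix_(ctx, bst[labels == 0])].sum(axis=1)
        np.testing.assert_allclose(maps[0].values, manual, atol=1e-12)

    def test_partition_size_mismatch_raises(self, small_group):
        part = comm.Partition(np.zeros(3, dtype=int), 1.0, 0.0)
        with pytest.raises(ShapeError):
            comm.community_degree_maps(small_group, part)


class TestPartitionEnumeration:
    def test_bell_numbers(self):
        # sanity of the oracle itself: Bell(4) = 15, Bell(5) = 52
        assert sum(1 for _ in all_partitions(4)) == 15
        assert sum(1 for _ in all_partitions(5)) == 52
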