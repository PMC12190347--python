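"""Co-expression network, topological overlap, module detection and the
self-organizing-map refinement."""

import numpy as np
import pytest

from hepatwin.coexpress import (
    ClusterAssignment,
    CoexpressionNetwork,
    cluster_profiles,
    correlation_matrix,
    detect_modules,
    pick_soft_threshold,
    som_refine,
    tag_modules,
    tom_similarity,
)
from hepatwin.grid import default_grid
from hepatwin.synth import gen_archetypes, purity


def _profile_tensor(make, profiles):
    """Genes x times profiles for a single patient."""
    arr = np.asarray(profiles, dtype=float)[:, None, :]
    return make(arr, scale="log2fc")


def tom_brute_force(adjacency):
    """Triple-loop topological overlap, the independent oracle."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    tom = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1.0 - a[i, j])
    return tom


class TestCorrelation:
    def test_identical_and_negated_profiles(self, tensor_factory):
        base = [0.0, 1.0, 2.0, 1.0]
        t = _profile_tensor(tensor_factory, [base, base, [-x for x in base]])
        net = correlation_matrix(t)
        assert net.cor[0, 1] == pytest.approx(1.0)
        assert net.cor[0, 2] == pytest.approx(-1.0)

    def test_textbook_formula_on_four_points(self, tensor_factory):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 3.0, 6.0])
        t = _profile_tensor(tensor_factory, [x, y])
        net = correlation_matrix(t)
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert net.cor[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_dropped(self, tensor_factory):
        t = _profile_tensor(
            tensor_factory, [[0, 1, 2, 3], [1, 1, 1, 1], [3, 2, 1, 0]]
        )
        with pytest.warns(UserWarning, match="undefined correlation"):
            net = correlation_matrix(t)
        assert net.n_genes == 2
        assert "g1" not in net.genes

    def test_pairwise_complete_uses_shared_samples(self, tensor_factory):
        values = np.array([[0.0, 1.0, 2.0, 3.0], [0.0, 2.0, 4.0, 9.9]])[:, None, :]
        mask = np.ones_like(values, dtype=bool)
        mask[1, 0, 3] = False  # the discordant sample is unobserved
        t = tensor_factory(values, scale="log2fc", mask=mask)
        net = correlation_matrix(t)
        assert net.cor[0, 1] == pytest.approx(1.0)


class TestSoftThreshold:
    def test_small_network_uses_default_beta(self, tensor_factory):
        rng = np.random.default_rng(0)
        t = _profile_tensor(tensor_factory, rng.normal(size=(10, 8)))
        net = correlation_matrix(t)
        with pytest.warns(UserWarning, match="beta = 6"):
            net = pick_soft_threshold(net)
        assert net.beta == 6
        np.testing.assert_allclose(net.adjacency.diagonal(), 1.0)

    def test_fallback_to_argmax_when_target_unreached(self):
        rng = np.random.default_rng(1)
        # near-uniform |cor| never yields a scale-free degree distribution
        cor = np.clip(0.5 + 0.01 * rng.standard_normal((60, 60)), -1, 1)
        cor = (cor + cor.T) / 2
        np.fill_diagonal(cor, 1.0)
        net = CoexpressionNetwork(tuple(f"g{i}" for i in range(60)), cor)
        with pytest.warns(UserWarning, match="argmax"):
            net = pick_soft_threshold(net, r2_target=0.999)
        assert net.beta in range(1, 21)

    def test_adjacency_monotone_in_beta(self):
        rng = np.random.default_rng(2)
        cor = np.clip(rng.uniform(-1, 1, size=(12, 12)), -1, 1)
        cor = (cor + cor.T) / 2
        np.fill_diagonal(cor, 1.0)
        prev = np.abs(cor) ** 1
        for beta in range(2, 8):
            cur = np.abs(cor) ** beta
            assert np.all(cur <= prev + 1e-15)
            exact_one = np.isclose(np.abs(cor), 1.0)
            np.testing.assert_allclose(cur[exact_one], prev[exact_one])
            prev = cur


class TestTom:
    def test_two_gene_unit_adjacency(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        net = CoexpressionNetwork(("a", "b"), a, beta=1, adjacency=a)
        tom = tom_similarity(net).tom
        assert tom[0, 1] == pytest.approx(1.0)  # (0 + 1) / (1 + 1 - 1)

    def test_three_gene_complete_graph(self):
        a = np.ones((3, 3))
        net = CoexpressionNetwork(("a", "b", "c"), a, beta=1, adjacency=a)
        tom = tom_similarity(net).tom
        assert tom[0, 1] == pytest.approx(1.0)  # (1 + 1) / (2 + 1 - 1)

    def test_disconnected_genes(self):
        a = np.eye(4)
        net = CoexpressionNetwork(tuple("abcd"), a, beta=1, adjacency=a)
        tom = tom_similarity(net).tom
        off = tom[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_matches_brute_force_oracle(self):
        """Vectorized TOM equals the triple loop on random networks."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(3, 21)
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            net = CoexpressionNetwork(
                tuple(f"g{i}" for i in range(n)), a, beta=1, adjacency=a
            )
            fast = tom_similarity(net).tom
            np.testing.assert_allclose(fast, tom_brute_force(a), atol=1e-12)


class TestDetectModules:
    @staticmethod
    def _block_network(sizes, rng):
        n = sum(sizes)
        a = np.full((n, n), 0.01)
        start = 0
        for s in sizes:
            a[start:start + s, start:start + s] = 0.95 + 0.04 * rng.random((s, s))
            start += s
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        net = CoexpressionNetwork(tuple(f"g{i}" for i in range(n)), a,
                                  beta=1, adjacency=a)
        return tom_similarity(net)

    def test_two_blocks_recovered(self):
        net = self._block_network([8, 8], np.random.default_rng(4))
        groups = detect_modules(net, min_size=3)
        assert len(groups) == 2
        assert {tuple(g) for g in groups} == {tuple(range(8)), tuple(range(8, 16))}

    def test_min_size_forces_merge(self):
        net = self._block_network([5, 5], np.random.default_rng(5))
        groups = detect_modules(net, min_size=50)
        assert len(groups) == 1
        assert len(groups[0]) == 10

    def test_identical_genes_single_group(self):
        a = np.ones((6, 6))
        net = CoexpressionNetwork(tuple(f"g{i}" for i in range(6)), a,
                                  beta=1, adjacency=a)
        net = tom_similarity(net)
        groups = detect_modules(net, min_size=2)
        assert len(groups) == 1


class TestSomRefine:
    def test_noise_free_archetypes_perfect_purity(self):
        tensor, labels = gen_archetypes(3, 60, 0.0, seed=0)
        assign = som_refine(tensor, [], 3, seed=0)
        assert purity(assign.labels, labels) == 1.0
        assert assign.K == 3

    def test_same_seed_identical_assignment(self):
        tensor, _ = gen_archetypes(4, 40, 0.3, seed=1)
        a1 = som_refine(tensor, [], 4, seed=9)
        a2 = som_refine(tensor, [], 4, seed=9)
        np.testing.assert_array_equal(a1.labels, a2.labels)

    def test_codebook_vector_input_maps_to_own_unit(self, tensor_factory):
        # genes identical to a well-separated archetype land together
        tensor, labels = gen_archetypes(2, 10, 0.0, seed=2)
        assign = som_refine(tensor, [np.flatnonzero(labels == k) for k in (1, 2)],
                            2, seed=0)
        assert purity(assign.labels, labels) == 1.0

    def test_more_units_than_genes_rejected(self):
        tensor, _ = gen_archetypes(2, 4, 0.0, seed=3)
        with pytest.raises(ValueError, match="units"):
            som_refine(tensor, [], 10, seed=0)


class TestClusterProfiles:
    def test_mean_and_sample_sd(self, tensor_factory):
        values = np.array([[[1.0]], [[3.0]]])
        t = tensor_factory(values, scale="log2fc")
        assign = ClusterAssignment(t.gene_ids, np.array([1, 1]), 1)
        traj = cluster_profiles(t, assign)
        assert traj.values[0, 0, 0] == pytest.approx(2.0)
        assert traj.spread[0, 0, 0] == pytest.approx(np.sqrt(2.0))

    def test_singleton_cluster_zero_sd(self, tensor_factory):
        t = tensor_factory(np.array([[[1.5]]]), scale="log2fc")
        assign = ClusterAssignment(t.gene_ids, np.array([1]), 1)
        traj = cluster_profiles(t, assign)
        assert traj.values[0, 0, 0] == 1.5
        assert traj.spread[0, 0, 0] == 0.0

    def test_all_members_masked_cell_is_masked(self, tensor_factory):
        values = np.ones((2, 1, 2))
        mask = np.ones_like(values, dtype=bool)
        mask[:, 0, 1] = False
        t = tensor_factory(values, scale="log2fc", mask=mask)
        assign = ClusterAssignment(t.gene_ids, np.array([1, 1]), 1)
        traj = cluster_profiles(t, assign)
        assert traj.mask[0, 0, 0]
        assert not traj.mask[0, 0, 1]

    def test_permutation_invariance(self, tensor_factory):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(8, 3, 5))
        t = tensor_factory(values, scale="log2fc")
        labels = np.array([1, 1, 2, 2, 1, 2, 1, 2])
        perm = rng.permutation(8)
        t_perm = tensor_factory(
            values[perm], scale="log2fc",
            genes=tuple(f"g{i}" for i in perm),
        )
        a = ClusterAssignment(t.gene_ids, labels, 2)
        b = ClusterAssignment(t_perm.gene_ids, labels[perm], 2)
        np.testing.assert_allclose(
            cluster_profiles(t, a).values, cluster_profiles(t_perm, b).values
        )


class TestTagModules:
    @staticmethod
    def _traj_from_profiles(profiles, grid):
        arr = np.asarray(profiles, dtype=float)[:, None, :]
        from hepatwin.coexpress import ClusterTrajectory
        return ClusterTrajectory(
            arr, np.zeros_like(arr), np.ones(arr.shape, dtype=bool),
            tuple(range(1, arr.shape[0] + 1)), ("p0",),
        )

    def test_peak_timing_rules(self):
        grid = default_grid()
        hours = grid.hours_array
        early = np.exp(-((hours - 2) / 4.0) ** 2)
        prolif = np.exp(-((hours - 96) / 50.0) ** 2)
        late = hours / hours.max()
        traj = self._traj_from_profiles([early, prolif, late], grid)
        tags, ambiguous = tag_modules(traj, grid)
        assert tags[1] == "early"
        assert tags[2] == "proliferation"
        assert tags[3] == "long_term"
        assert ambiguous == ()

    def test_flat_cluster_flagged_ambiguous(self):
        grid = default_grid()
        traj = self._traj_from_profiles([np.zeros(len(grid))], grid)
        tags, ambiguous = tag_modules(traj, grid)
        assert tags[1] == "early"
        assert ambiguous == (1,)
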