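"""Graph metrics against brute-force and networkx oracles; null models;
matrix reordering."""

from itertools import permutations

import networkx as nx
import numpy as np
import pytest

import tractnet as tn


def _triangle_oracle(adj):
    """O(n^3) clustering oracle: explicit triangle enumeration."""
    n = len(adj)
    c = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        k = len(nb)
        if k < 2:
            continue
        tri = sum(
            1 for a in range(k) for b in range(a + 1, k) if adj[nb[a], nb[b]]
        )
        c[i] = 2 * tri / (k * (k - 1))
    return c


def _floyd_warshall_L(adj):
    """Mean shortest path over connected ordered pairs, Floyd-Warshall."""
    n = len(adj)
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    return d[finite].mean()


class TestEdgeDensity:
    def test_complete_graph_is_one(self):
        adj = tn.make_graph_fixture("complete", n=5).adjacency
        assert tn.edge_density(adj) == pytest.approx(1.0)

    def test_ring_of_ten(self):
        adj = tn.make_graph_fixture("ring_lattice", n=10, k=2).adjacency
        assert tn.edge_density(adj) == pytest.approx(10 / 45)

    def test_er_density_equals_direct_count(self):
        adj = tn.make_graph_fixture("erdos_renyi", n=50, p=0.1, seed=9).adjacency
        m = sum(
            int(adj[i, j]) for i in range(50) for j in range(i + 1, 50)
        )
        assert tn.edge_density(adj) == pytest.approx(m / 1225)

    def test_too_few_active_nodes_rejected(self):
        with pytest.raises(ValueError):
            tn.edge_density(np.zeros((1, 1)))


class TestClusteringAndPathLength:
    def test_complete_graph_clustering_one(self):
        adj = tn.make_graph_fixture("complete", n=5).adjacency
        _, c = tn.clustering_coefficient(adj)
        assert c == pytest.approx(1.0)

    def test_star_clustering_zero(self):
        adj = tn.make_graph_fixture("star", n_leaves=5).adjacency
        _, c = tn.clustering_coefficient(adj)
        assert c == 0.0

    def test_path_graph_L(self):
        adj = tn.make_graph_fixture("path", n=3).adjacency
        assert tn.characteristic_path_length(adj) == pytest.approx(4 / 3)

    def test_ring_of_ten_L(self):
        adj = tn.make_graph_fixture("ring_lattice", n=10, k=2).adjacency
        assert tn.characteristic_path_length(adj) == pytest.approx(25 / 9)

    def test_disconnected_pairs_excluded(self):
        """Two disjoint edges: only within-component pairs count."""
        adj = np.zeros((4, 4), int)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        L, excluded = tn.characteristic_path_length(adj, return_excluded=True)
        assert L == pytest.approx(1.0)
        assert excluded == 8

    @pytest.mark.parametrize("seed", range(15))
    def test_random_graphs_match_oracles_and_networkx(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 26))
        adj = tn.make_graph_fixture(
            "erdos_renyi", n=n, p=float(rng.uniform(0.15, 0.5)), seed=seed
        ).adjacency
        c_i, c = tn.clustering_coefficient(adj)
        np.testing.assert_allclose(c_i, _triangle_oracle(adj), atol=1e-12)
        g = nx.from_numpy_array(adj)
        np.testing.assert_allclose(
            c, np.mean(list(nx.clustering(g).values())), atol=1e-12
        )
        if adj.sum() and tn.giant_component(adj)[0] > 1:
            np.testing.assert_allclose(
                tn.characteristic_path_length(adj), _floyd_warshall_L(adj),
                atol=1e-12,
            )

    def test_no_connected_pair_rejected(self):
        with pytest.raises(ValueError):
            tn.characteristic_path_length(np.zeros((3, 3)))


class TestRewireNull:
    def test_degree_sequence_preserved(self):
        """Swapped surrogates keep each node's degree and |E| exactly."""
        from tractnet.metrics import _edge_list
        from tractnet._kernels import double_edge_swap

        adj = tn.make_graph_fixture("erdos_renyi", n=40, p=0.15, seed=1).adjacency
        k0 = tn.degrees(adj)
        u, v = _edge_list((adj != 0).astype(float))
        rng = np.random.default_rng(0)
        m = len(u)
        e1 = rng.integers(0, m, 5000)
        e2 = rng.integers(0, m, 5000)
        fl = rng.integers(0, 2, 5000)
        a2 = (adj != 0).copy()
        nswap = double_edge_swap(u.copy(), v.copy(), a2, e1, e2, fl)
        assert nswap > 0
        assert np.array_equal(a2, a2.T)
        assert np.all(np.diagonal(a2) == 0)
        np.testing.assert_array_equal(a2.sum(1), k0)
        assert a2.sum() == adj.sum()
        assert not np.array_equal(a2, adj != 0)

    def test_star_has_no_swappable_pair(self):
        """All swaps on a star create multi-edges; surrogates equal input."""
        adj = tn.make_graph_fixture("star", n_leaves=6).adjacency
        null = tn.rewire_null(adj, rewires_per_edge=50, n_networks=2, seed=0)
        _, c = tn.clustering_coefficient(adj)
        assert null.C_rand == pytest.approx(c)
        assert null.L_rand == pytest.approx(tn.characteristic_path_length(adj))

    def test_lattice_clustering_destroyed(self):
        """Rewiring a ring lattice wipes out its high clustering."""
        adj = tn.make_graph_fixture("ring_lattice", n=100, k=4).adjacency
        _, c = tn.clustering_coefficient(adj)
        null = tn.rewire_null(adj, rewires_per_edge=100, n_networks=5, seed=2)
        assert null.C_rand < c

    def test_seeded_reproducibility(self):
        adj = tn.make_graph_fixture("erdos_renyi", n=30, p=0.2, seed=3).adjacency
        a = tn.rewire_null(adj, 50, 3, seed=42)
        b = tn.rewire_null(adj, 50, 3, seed=42)
        np.testing.assert_array_equal(a.C_samples, b.C_samples)
        np.testing.assert_array_equal(a.L_samples, b.L_samples)

    def test_too_few_edges_rejected(self):
        adj = np.zeros((3, 3), int)
        adj[0, 1] = adj[1, 0] = 1
        with pytest.raises(ValueError):
            tn.rewire_null(adj)


class TestScaledMetrics:
    def test_identity_when_null_equals_input(self):
        adj = tn.make_graph_fixture("star", n_leaves=6).adjacency
        # star cannot rewire -> null equals input -> lambda = 1 (C = 0 though)
        null = tn.rewire_null(adj, 10, 2, seed=0)
        with pytest.raises(ValueError):  # C_rand = 0 is diagnosed
            tn.scaled_metrics(adj, null)

    def test_sigma_is_gamma_over_lambda(self):
        adj = tn.make_graph_fixture("watts_strogatz", n=60, k=6, p=0.1, seed=0).adjacency
        null = tn.rewire_null(adj, 100, 10, seed=1)
        gamma, lam, sigma = tn.scaled_metrics(adj, null)
        assert sigma == pytest.approx(gamma / lam, abs=1e-15)

    def test_small_world_regime_sigma_above_one(self):
        """Watts-Strogatz at p=0.1 is the canonical small-world regime."""
        sigmas = []
        for seed in range(5):
            adj = tn.make_graph_fixture(
                "watts_strogatz", n=100, k=6, p=0.1, seed=seed
            ).adjacency
            null = tn.rewire_null(adj, 200, 10, seed=seed)
            sigmas.append(tn.scaled_metrics(adj, null)[2])
        assert np.median(sigmas) > 1


class TestHistograms:
    def test_ring_degrees_all_two(self):
        adj = tn.make_graph_fixture("ring_lattice", n=10, k=2).adjacency
        counts, edges = tn.degree_distribution(adj)
        assert counts[2] == 10 and counts.sum() == 10

    def test_star_degree_histogram(self):
        adj = tn.make_graph_fixture("star", n_leaves=5).adjacency
        counts, _ = tn.degree_distribution(adj)
        assert counts[1] == 5 and counts[5] == 1

    def test_histogram_mass_conserved(self):
        adj = tn.make_graph_fixture("erdos_renyi", n=100, p=0.1, seed=0).adjacency
        counts, _ = tn.degree_distribution(adj)
        assert counts.sum() == 100

    def test_single_edge_length(self):
        adj = np.array([[0, 1], [1, 0]])
        cents = np.array([[0, 0, 0], [3, 4, 0]], float)
        lengths = tn.edge_lengths(adj, cents)
        np.testing.assert_allclose(lengths, [5.0])

    def test_triangle_lengths_hand_computed(self):
        adj = np.ones((3, 3), int) - np.eye(3, dtype=int)
        cents = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        lengths = sorted(tn.edge_lengths(adj, cents))
        np.testing.assert_allclose(lengths, [1.0, 1.0, np.sqrt(2)])

    def test_phantom_lengths_match_pairwise_recomputation(self, study_phantom):
        conn = study_phantom["conn"]
        cents = study_phantom["parc"].node_centroids_mm
        lengths = tn.edge_lengths(conn.adjacency, cents)
        iu, ju = np.nonzero(np.triu(conn.adjacency, 1))
        oracle = np.sqrt(((cents[iu] - cents[ju]) ** 2).sum(1))
        np.testing.assert_allclose(np.sort(lengths), np.sort(oracle), atol=1e-9)

    def test_missing_centroid_rejected(self):
        adj = np.array([[0, 1], [1, 0]])
        cents = np.array([[0, 0, 0], [np.nan, 0, 0]])
        with pytest.raises(ValueError):
            tn.edge_lengths(adj, cents)


class TestReorderMatrix:
    def test_trace_never_increases(self):
        adj = tn.make_graph_fixture("erdos_renyi", n=30, p=0.15, seed=5).adjacency
        _, trace = tn.reorder_matrix(adj, attempts=20_000, seed=0)
        assert np.all(np.diff(trace) <= 0)

    def test_banded_input_cannot_get_worse(self):
        adj = tn.make_graph_fixture("ring_lattice", n=12, k=2).adjacency
        _, trace = tn.reorder_matrix(adj, attempts=5_000, seed=1)
        assert trace[-1] <= trace[0]

    def test_same_seed_same_permutation(self):
        adj = tn.make_graph_fixture("erdos_renyi", n=25, p=0.2, seed=2).adjacency
        p1, _ = tn.reorder_matrix(adj, attempts=10_000, seed=7)
        p2, _ = tn.reorder_matrix(adj, attempts=10_000, seed=7)
        np.testing.assert_array_equal(p1, p2)

    def test_shuffled_ring_reaches_exhaustive_minimum(self):
        """n=6 shuffled ring: greedy search hits the global optimum."""
        n = 6
        ring = tn.make_graph_fixture("ring_lattice", n=n, k=2).adjacency
        rng = np.random.default_rng(8)
        shuffle = rng.permutation(n)
        adj = ring[np.ix_(shuffle, shuffle)]
        iu, ju = np.nonzero(np.triu(adj, 1))
        best = min(
            sum(abs(p[i] - p[j]) for i, j in zip(iu, ju))
            for p in permutations(range(n))
        )
        perm, trace = tn.reorder_matrix(adj, attempts=30_000, seed=0)
        assert trace[-1] == best
        assert sum(abs(perm[i] - perm[j]) for i, j in zip(iu, ju)) == best

    def test_objective_invariant_under_relabelling(self):
        """Composing the found order with a node relabelling leaves the
        bandwidth objective unchanged."""
        adj = tn.make_graph_fixture("erdos_renyi", n=12, p=0.3, seed=3).adjacency
        rng = np.random.default_rng(1)
        pi = rng.permutation(12)
        relabelled = adj[np.ix_(pi, pi)]  # node a of relabelled = node pi[a]
        perm, trace = tn.reorder_matrix(adj, attempts=50_000, seed=2)
        iu, ju = np.nonzero(np.triu(relabelled, 1))
        composed = perm[pi]  # position of relabelled node a = perm[pi[a]]
        f = sum(abs(composed[i] - composed[j]) for i, j in zip(iu, ju))
        assert f == trace[-1]
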