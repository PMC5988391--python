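"""Graph construction and diagnostics against brute-force oracles."""

import numpy as np
import pytest

import oracles
from oscnet import netmetrics as nm


def _random_sym(rng, n):
    a = rng.standard_normal((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


class TestThresholdDensity:
    def test_edge_count_arithmetic(self, rng):
        g = nm.threshold_density(_random_sym(rng, 5), density=0.1)
        assert g.n_edges == 1

    def test_full_density_gives_complete_graph(self, rng):
        g = nm.threshold_density(_random_sym(rng, 6), density=1.0)
        assert g.n_edges == 15
        assert np.all(g.adjacency + np.eye(6) == 1)

    def test_sparser_graph_is_nested_in_denser(self, rng):
        for _ in range(10):
            c = _random_sym(rng, 12)
            lo = nm.threshold_density(c, 0.05)
            hi = nm.threshold_density(c, 0.10)
            assert np.all(hi.adjacency[lo.adjacency == 1] == 1)

    def test_edge_counts_exact_across_sizes(self, rng):
        for n in (8, 13, 20):
            for density in (0.05, 0.1, 0.3):
                g = nm.threshold_density(_random_sym(rng, n), density)
                assert g.n_edges == int(np.floor(density * n * (n - 1) / 2))

    def test_selection_by_absolute_value(self):
        c = np.zeros((4, 4))
        c[0, 1] = c[1, 0] = -0.9
        c[2, 3] = c[3, 2] = 0.5
        g = nm.threshold_density(c, density=1 / 6)
        assert g.adjacency[0, 1] == 1 and g.adjacency[2, 3] == 0
        assert g.retained_weights.tolist() == [-0.9]

    def test_bad_density_rejected(self, rng):
        with pytest.raises(ValueError):
            nm.threshold_density(_random_sym(rng, 5), density=0.0)


class TestMeanFC:
    def test_mean_of_retained_values(self, rng):
        c = _random_sym(rng, 10)
        g = nm.threshold_density(c, 0.2)
        iu = np.triu_indices(10, 1)
        vals = c[iu]
        kept = np.sort(np.abs(vals))[::-1][: g.n_edges]
        brute = vals[np.argsort(-np.abs(vals), kind="stable")[: g.n_edges]].mean()
        assert nm.mean_fc(g) == pytest.approx(brute, abs=1e-12)


class TestEfficiencies:
    def test_complete_graph(self):
        adj = 1 - np.eye(5, dtype=np.int8)
        assert nm.global_efficiency(adj) == pytest.approx(1.0)
        per, mean = nm.local_efficiency(adj)
        assert np.allclose(per, 1.0) and mean == pytest.approx(1.0)
        assert np.allclose(nm.nodal_efficiency(adj), 1.0)

    def test_path_graph_hand_computed(self):
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1
        assert nm.global_efficiency(adj) == pytest.approx(5 / 6)

    def test_edgeless_graph_is_zero(self):
        assert nm.global_efficiency(np.zeros((4, 4), dtype=np.int8)) == 0.0

    def test_star_center_has_zero_local_efficiency(self):
        adj = np.zeros((5, 5), dtype=np.int8)
        adj[0, 1:] = adj[1:, 0] = 1
        per, _ = nm.local_efficiency(adj)
        assert per[0] == 0.0

    def test_mean_nodal_equals_global(self, rng):
        for _ in range(20):
            adj = oracles.random_binary_graph(10, 0.3, rng)
            assert nm.nodal_efficiency(adj).mean() == pytest.approx(
                nm.global_efficiency(adj), abs=1e-12
            )


class TestModularity:
    def two_cliques(self):
        adj = np.zeros((8, 8), dtype=np.int8)
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        adj[i, j] = 1
        return adj

    def test_two_disconnected_cliques(self):
        """Two 4-cliques: Louvain recovers the cliques and Q = 0.5, matching
        the exhaustive-partition optimum."""
        adj = self.two_cliques()
        labels, q = nm.modularity(adj, seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        _, q_best = oracles.best_partition_exhaustive(adj)
        assert q == pytest.approx(q_best, abs=1e-12)

    def test_complete_graph_has_zero_q(self):
        adj = 1 - np.eye(6, dtype=np.int8)
        _, q = nm.modularity(adj, seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_q_matches_formula_on_returned_partition(self, rng):
        for _ in range(20):
            adj = oracles.random_binary_graph(10, 0.3, rng)
            if adj.sum() == 0:
                continue
            labels, q = nm.modularity(adj, seed=3)
            assert q == pytest.approx(oracles.modularity_q(adj, labels), abs=1e-12)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            nm.modularity(np.zeros((4, 4), dtype=np.int8))


class TestPartitionMetrics:
    def test_equal_within_degrees_give_zero_z(self):
        adj = 1 - np.eye(4, dtype=np.int8)
        z = nm.within_module_z(adj, np.zeros(4, dtype=int))
        assert np.allclose(z, 0.0)

    def test_z_sums_to_zero_within_modules(self, rng):
        adj = oracles.random_binary_graph(12, 0.4, rng)
        labels = rng.integers(0, 3, size=12)
        z = nm.within_module_z(adj, labels)
        for m in np.unique(labels):
            assert z[labels == m].sum() == pytest.approx(0.0, abs=1e-10)

    def test_hub_z_formula(self):
        # module of 5: node 0 connected to all four others (kappa=4),
        # others only to node 0 (kappa=1): mean 1.6, sd 1.2 -> z0 = 2
        adj = np.zeros((5, 5), dtype=np.int8)
        adj[0, 1:] = adj[1:, 0] = 1
        z = nm.within_module_z(adj, np.zeros(5, dtype=int))
        assert z[0] == pytest.approx((4 - 1.6) / 1.2)

    def test_participation_all_within_is_zero(self):
        adj = 1 - np.eye(4, dtype=np.int8)
        assert np.allclose(nm.participation(adj, np.zeros(4, dtype=int)), 0.0)

    def test_participation_split_edges(self):
        # node 0 with one edge into each of two other modules
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[0, 1] = adj[1, 0] = adj[0, 2] = adj[2, 0] = 1
        p = nm.participation(adj, np.array([0, 1, 2]))
        assert p[0] == pytest.approx(0.5)

    def test_single_community_gives_zero(self, rng):
        adj = oracles.random_binary_graph(8, 0.5, rng)
        assert np.allclose(nm.participation(adj, np.zeros(8, dtype=int)), 0.0)


class TestOracleSuite:
    def test_metrics_match_brute_force_on_random_graphs(self, rng):
        """Degree-based and distance-based diagnostics equal independent
        Floyd-Warshall/formula implementations on random graphs."""
        for k in range(60):
            n = int(rng.integers(5, 13))
            adj = oracles.random_binary_graph(n, float(rng.uniform(0.15, 0.6)), rng)
            labels = rng.integers(0, 3, size=n)
            assert np.allclose(nm.strength(adj), adj.sum(1))
            assert nm.global_efficiency(adj) == pytest.approx(
                oracles.global_efficiency(adj), abs=1e-12
            )
            assert np.allclose(
                nm.nodal_efficiency(adj), oracles.nodal_efficiency(adj), atol=1e-12
            )
            assert np.allclose(
                nm.local_efficiency(adj)[0], oracles.local_efficiency(adj), atol=1e-12
            )
            assert np.allclose(
                nm.within_module_z(adj, labels),
                oracles.within_module_z(adj, labels),
                atol=1e-10,
            )
            assert np.allclose(
                nm.participation(adj, labels),
                oracles.participation(adj, labels),
                atol=1e-12,
            )


def test_network_series_columns(rng):
    stack = np.stack([_random_sym(rng, 10) for _ in range(5)])
    series = nm.network_series(stack, metrics=("mean_fc", "global_efficiency"))
    assert list(series.columns) == ["mean_fc", "global_efficiency"]
    assert len(series) == 5


def test_nodal_metrics_frame(rng):
    frame = nm.nodal_metrics(_random_sym(rng, 12), density=0.3)
    assert frame.shape == (12, 5)
    assert np.all(frame["local_efficiency"].between(0, 1))
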