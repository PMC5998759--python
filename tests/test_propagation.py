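"""RWR: normalization, convergence, affinity invariants, feature weighting."""

import networkx as nx
import numpy as np
import pytest

from rwrdti.containers import FeatureMatrix, InteractionNetwork
from rwrdti.propagation import (
    ConvergenceError,
    RWRConfig,
    affinity_matrix,
    gba_weighting,
    normalize_adjacency,
    rwr,
    rwr_closed_form,
    weight_features,
)


def random_network(rng, n_max=20, p=0.35):
    n = int(rng.integers(2, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    nodes = [f"n{i}" for i in range(n)]
    g = nx.relabel_nodes(g, dict(enumerate(nodes)))
    edges = [(a, b, float(rng.uniform(0.1, 10))) for a, b in g.edges()]
    return InteractionNetwork(nodes, edges)


class TestNormalizeAdjacency:
    def test_two_node_graph(self):
        net = InteractionNetwork(["A", "B"], [("A", "B", 1.0)])
        A = normalize_adjacency(net).toarray()
        np.testing.assert_allclose(A, [[0, 1], [1, 0]])

    def test_star_graph_hand_normalized(self):
        net = InteractionNetwork(
            ["c", "l1", "l2", "l3"],
            [("c", "l1", 1.0), ("c", "l2", 1.0), ("c", "l3", 1.0)],
        )
        A = normalize_adjacency(net).toarray()
        # each leaf column sends all mass to the center;
        # the center column splits 1/3 to each leaf
        expected = np.array(
            [
                [0, 1, 1, 1],
                [1 / 3, 0, 0, 0],
                [1 / 3, 0, 0, 0],
                [1 / 3, 0, 0, 0],
            ]
        )
        np.testing.assert_allclose(A, expected)

    def test_isolated_node_zero_column(self):
        net = InteractionNetwork(["A", "B", "C"], [("A", "B", 2.0)])
        A = normalize_adjacency(net).toarray()
        assert np.all(A[:, 2] == 0)
        np.testing.assert_allclose(A.sum(axis=0)[:2], 1)

    def test_symmetric_mode(self):
        net = InteractionNetwork(["A", "B"], [("A", "B", 4.0)])
        A = normalize_adjacency(net, mode="symmetric").toarray()
        np.testing.assert_allclose(A, [[0, 1], [1, 0]])


class TestRWR:
    def test_isolated_seed_point_mass(self):
        net = InteractionNetwork(["A", "B", "C"], [("B", "C", 1.0)])
        r = rwr(net, "A", RWRConfig(restart_c=0.3))
        np.testing.assert_array_equal(r, [1, 0, 0])

    def test_c_equal_one_returns_restart_vector(self):
        net = InteractionNetwork(["A", "B"], [("A", "B", 1.0)])
        r = rwr(net, "A", RWRConfig(restart_c=1.0))
        np.testing.assert_allclose(r, [1, 0], atol=1e-12)

    def test_two_node_worked_example(self):
        """Seed A on A-B at c = 0.5 converges to (2/3, 1/3)."""
        net = InteractionNetwork(["A", "B"], [("A", "B", 1.0)])
        r = rwr(net, "A", RWRConfig(restart_c=0.5))
        np.testing.assert_allclose(r, [2 / 3, 1 / 3], atol=1e-9)

    def test_iterative_matches_closed_form(self, rng):
        """Power iteration agrees with c(I-(1-c)A)^-1 q on random graphs."""
        for _ in range(25):
            net = random_network(rng)
            seed = net.node_ids[int(rng.integers(0, net.n_nodes))]
            c = float(rng.uniform(0.05, 0.95))
            got = rwr(net, seed, RWRConfig(restart_c=c))
            want = rwr_closed_form(net, seed, restart_c=c)
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_component_mass_and_support(self, rng):
        """Affinity sums to 1 within the seed's component, 0 outside."""
        net = InteractionNetwork(
            ["a", "b", "c", "x", "y"],
            [("a", "b", 1.0), ("b", "c", 2.0), ("x", "y", 1.0)],
        )
        r = rwr(net, "a", RWRConfig(restart_c=0.25))
        assert r[:3].sum() == pytest.approx(1, abs=1e-6)
        assert np.all(r[3:] == 0)

    def test_seed_self_affinity_at_least_c(self, rng):
        for c in (0.1, 0.3, 0.5, 0.7, 0.9):
            net = random_network(rng)
            seed = net.node_ids[0]
            r = rwr(net, seed, RWRConfig(restart_c=c))
            assert r[0] >= c - 1e-9

    def test_self_affinity_monotone_in_c(self, rng):
        for _ in range(5):
            net = random_network(rng)
            seed = net.node_ids[0]
            vals = [
                rwr(net, seed, RWRConfig(restart_c=c))[0]
                for c in np.linspace(0.1, 0.9, 9)
            ]
            assert np.all(np.diff(vals) >= -1e-9)

    def test_non_convergence_reports_residual(self):
        net = InteractionNetwork(
            ["A", "B", "C"], [("A", "B", 1.0), ("B", "C", 1.0)]
        )
        with pytest.raises(ConvergenceError, match="residual"):
            rwr(net, "A", RWRConfig(restart_c=0.01, tolerance=1e-14, max_iter=2))

    def test_unknown_seed(self):
        net = InteractionNetwork(["A"], [])
        with pytest.raises(KeyError):
            rwr(net, "Z")


class TestAffinityMatrix:
    def test_symmetric_graph_symmetric_matrix(self):
        net = InteractionNetwork(["A", "B"], [("A", "B", 1.0)])
        W = affinity_matrix(net, RWRConfig(restart_c=0.4))
        np.testing.assert_allclose(W.values, W.values.T, atol=1e-9)

    def test_rows_sum_to_one(self, rng):
        for c in (0.1, 0.25, 0.5, 0.9):
            net = random_network(rng)
            W = affinity_matrix(net, RWRConfig(restart_c=c))
            np.testing.assert_allclose(W.values.sum(axis=1), 1, atol=1e-6)
            assert np.all(W.values >= -1e-12)
            assert np.all(np.diag(W.values) >= c - 1e-9)

    def test_c_one_identity(self, rng):
        net = random_network(rng)
        W = affinity_matrix(net, RWRConfig(restart_c=1.0))
        np.testing.assert_allclose(W.values, np.eye(net.n_nodes), atol=1e-10)

    def test_rows_match_per_seed_rwr(self, rng):
        net = random_network(rng, n_max=12)
        cfg = RWRConfig(restart_c=0.25)
        W = affinity_matrix(net, cfg)
        for i, node in enumerate(net.node_ids):
            np.testing.assert_allclose(W.values[i], rwr(net, node, cfg), atol=1e-8)


class TestWeighting:
    def make_features(self, net, rng):
        return FeatureMatrix(
            net.node_ids, rng.random((net.n_nodes, 6)),
        )

    def test_identity_weighting_preserves_features(self, rng):
        net = random_network(rng)
        F = self.make_features(net, rng)
        W = affinity_matrix(net, RWRConfig(restart_c=1.0))
        out = weight_features(W, F)
        np.testing.assert_allclose(out.values, F.values, atol=1e-9)

    def test_two_node_closed_form_mixture(self):
        net = InteractionNetwork(["A", "B"], [("A", "B", 1.0)])
        F = FeatureMatrix(["A", "B"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        W = affinity_matrix(net, RWRConfig(restart_c=0.5))
        out = weight_features(W, F)
        np.testing.assert_allclose(out.row("A"), [2 / 3, 1 / 3], atol=1e-8)

    def test_convex_combination_bounds(self, rng):
        net = random_network(rng)
        F = self.make_features(net, rng)
        W = affinity_matrix(net, RWRConfig(restart_c=0.25))
        out = weight_features(W, F)
        assert np.all(out.values <= F.values.max(axis=0) + 1e-9)
        assert np.all(out.values >= F.values.min(axis=0) - 1e-9)

    def test_missing_entity_listed(self, rng):
        net = InteractionNetwork(["A", "B"], [("A", "B", 1.0)])
        F = FeatureMatrix(["A"], np.ones((1, 3)))
        W = affinity_matrix(net)
        with pytest.raises(KeyError, match="B"):
            weight_features(W, F)

    def test_weighting_contracts_adjacent_distances(self, rng):
        """Low-c weighting pulls neighbors together in feature space."""
        from rwrdti.synthetic import generate_world

        world = generate_world(
            n_modules=3, proteins_per_module=12, drugs_per_module=3,
            fp_bits=64, seq_len_range=(40, 60), rng_seed=3,
        )
        F = FeatureMatrix(
            world.ppi.node_ids, rng.random((world.ppi.n_nodes, 8))
        )
        W = affinity_matrix(world.ppi, RWRConfig(restart_c=0.25))
        out = weight_features(W, F)
        before, after = [], []
        for a, b, _ in world.ppi.edges():
            before.append(np.linalg.norm(F.row(a) - F.row(b)))
            after.append(np.linalg.norm(out.row(a) - out.row(b)))
        assert np.mean(after) < np.mean(before)


class TestGBA:
    def test_isolated_node_unchanged(self, rng):
        net = InteractionNetwork(["A", "B", "C"], [("A", "B", 1.0)])
        F = FeatureMatrix(["A", "B", "C"], rng.random((3, 4)))
        out = gba_weighting(net, F)
        np.testing.assert_allclose(out.row("C"), F.row("C"))

    def test_single_neighbor_unit_selfweight_is_mean(self, rng):
        net = InteractionNetwork(["A", "B"], [("A", "B", 1.0)])
        F = FeatureMatrix(["A", "B"], rng.random((2, 4)))
        out = gba_weighting(net, F, include_self_weight=1.0)
        np.testing.assert_allclose(out.row("A"), (F.row("A") + F.row("B")) / 2)

    def test_star_graph_mixture(self):
        net = InteractionNetwork(
            ["c", "l1", "l2", "l3"],
            [("c", "l1", 1.0), ("c", "l2", 2.0), ("c", "l3", 1.0)],
        )
        F = FeatureMatrix(["c", "l1", "l2", "l3"], np.eye(4))
        out = gba_weighting(net, F, include_self_weight=1.0)
        # center: self 1 + neighbors (1, 2, 1), total 5
        np.testing.assert_allclose(out.row("c"), [1 / 5, 1 / 5, 2 / 5, 1 / 5])
        # leaf l2: self 1 + center 2, total 3
        np.testing.assert_allclose(out.row("l2"), [2 / 3, 0, 1 / 3, 0])

    def test_mixing_weights_sum_to_one(self, rng):
        net = random_network(rng)
        F = FeatureMatrix(net.node_ids, np.ones((net.n_nodes, 2)))
        out = gba_weighting(net, F, include_self_weight=0.5)
        np.testing.assert_allclose(out.values, 1, atol=1e-9)
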