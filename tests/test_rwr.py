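import numpy as np
import networkx as nx
import pytest

from mplexembed import (
    LayerGraph,
    Multiplex,
    MultilayerNetwork,
    RWRConfig,
    build_transition_operator,
    build_restart_vector,
    rwr_stationary,
    aggregate_to_nodes,
    similarity_matrix,
)
from mplexembed.network_model import ValidationError
from mplexembed.rwr import DegenerateOperatorError, ReplicaIndex
from conftest import random_multilayer


def solve_oracle(op, s, r):
    """Direct linear solve x = r (I - (1-r) M)^-1 s for the RWR fixed point."""
    M = op.materialize(s)
    n = M.shape[0]
    return np.linalg.solve(np.eye(n) - (1 - r) * M, r * s)


class TestTransitionOperator:
    @pytest.mark.parametrize("seed", range(6))
    def test_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        net = random_multilayer(rng)
        cfg = RWRConfig.defaults(net)
        op = build_transition_operator(net, cfg)
        s = build_restart_vector(net, cfg, net.nodes[0], op)
        M = op.materialize(s)
        assert np.allclose(M.sum(axis=0), 1.0, atol=1e-12)

    def test_path_monoplex_operator_swaps_masses(self, path_monoplex):
        cfg = RWRConfig.defaults(path_monoplex)
        op = build_transition_operator(path_monoplex, cfg)
        s = build_restart_vector(path_monoplex, cfg, "m::a", op)
        M = op.materialize(s)
        assert np.allclose(M, [[0.0, 1.0], [1.0, 0.0]])

    def test_fully_isolated_node_column_equals_restart(self):
        layer = LayerGraph(edges=[("m::a", "m::b", 1.0)])
        m = Multiplex(name="m", node_ids=["m::a", "m::b", "m::c"], layers=[layer])
        net = MultilayerNetwork(multiplexes=[m])
        cfg = RWRConfig.defaults(net)
        op = build_transition_operator(net, cfg)
        s = build_restart_vector(net, cfg, "m::a", op)
        M = op.materialize(s)
        np.testing.assert_allclose(M[:, 2], s)

    def test_empty_network_raises(self):
        m = Multiplex(name="m", node_ids=["m::a"], layers=[LayerGraph()])
        net = MultilayerNetwork(multiplexes=[m])
        with pytest.raises(DegenerateOperatorError):
            build_transition_operator(net, RWRConfig.defaults(net))

    def test_missing_bipartite_neighbour_mass_reassigned_to_stay(self):
        # two multiplexes, only one left node has a bipartite edge: the
        # other's inter-multiplex mass must stay within its own multiplex
        from mplexembed import Bipartite
        m1 = Multiplex(name="m1", node_ids=["m1::a", "m1::b"],
                       layers=[LayerGraph(edges=[("m1::a", "m1::b", 1.0)])])
        m2 = Multiplex(name="m2", node_ids=["m2::x", "m2::y"],
                       layers=[LayerGraph(edges=[("m2::x", "m2::y", 1.0)])])
        bp = Bipartite(name="b", left="m1", right="m2", edges=[("m1::a", "m2::x", 1.0)])
        net = MultilayerNetwork(multiplexes=[m1, m2], bipartites=[bp])
        cfg = RWRConfig.defaults(net)
        op = build_transition_operator(net, cfg)
        M = op.materialize(build_restart_vector(net, cfg, "m1::a", op))
        col_a = M[:, 0]  # m1::a has a bipartite route: half mass crosses
        col_b = M[:, 1]  # m1::b has none: all mass stays in m1
        assert col_a[2:].sum() == pytest.approx(0.5)
        assert col_b[2:].sum() == pytest.approx(0.0)
        assert col_b[:2].sum() == pytest.approx(1.0)


class TestRestartVector:
    def test_three_layer_uniform_tau(self):
        ids = [f"m::{i}" for i in range(4)]
        layers = [LayerGraph(edges=[(ids[0], ids[1], 1.0)]) for _ in range(3)]
        net = MultilayerNetwork(multiplexes=[Multiplex("m", ids, layers)])
        cfg = RWRConfig.defaults(net)
        s = build_restart_vector(net, cfg, ids[0])
        assert s.sum() == pytest.approx(1.0)
        nz = np.flatnonzero(s)
        assert len(nz) == 3
        assert np.allclose(s[nz], 1 / 3)

    def test_monoplex_all_mass_on_single_replica(self, path_monoplex):
        cfg = RWRConfig.defaults(path_monoplex)
        s = build_restart_vector(path_monoplex, cfg, "m::b")
        assert s.tolist() == [0.0, 1.0]

    def test_unknown_seed_raises(self, path_monoplex):
        cfg = RWRConfig.defaults(path_monoplex)
        with pytest.raises(KeyError):
            build_restart_vector(path_monoplex, cfg, "nope")


class TestStationary:
    def test_restart_only_limit_returns_seed(self, path_monoplex):
        cfg = RWRConfig.defaults(path_monoplex)
        op = build_transition_operator(path_monoplex, cfg)
        s = build_restart_vector(path_monoplex, cfg, "m::a", op)
        x = rwr_stationary(op, s, r=1.0)
        np.testing.assert_allclose(x, s)

    def test_path_half_restart_two_thirds_one_third(self, path_monoplex):
        cfg = RWRConfig.defaults(path_monoplex)
        op = build_transition_operator(path_monoplex, cfg)
        s = build_restart_vector(path_monoplex, cfg, "m::a", op)
        x = rwr_stationary(op, s, r=0.5, tol=1e-14, max_iter=5000)
        nodes = aggregate_to_nodes(x, op.index)
        np.testing.assert_allclose(nodes, [2 / 3, 1 / 3], atol=1e-10)

    def test_mass_conserved_every_iteration(self):
        rng = np.random.default_rng(3)
        net = random_multilayer(rng)
        cfg = RWRConfig.defaults(net)
        op = build_transition_operator(net, cfg)
        s = build_restart_vector(net, cfg, net.nodes[0], op)
        masses = []
        rwr_stationary(op, s, r=0.7, on_iterate=lambda x: masses.append(x.sum()))
        assert masses
        assert np.all(np.abs(np.array(masses) - 1.0) < 1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_power_iteration_matches_linear_solve(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_multilayer(rng)
        cfg = RWRConfig.defaults(net)
        op = build_transition_operator(net, cfg)
        s = build_restart_vector(net, cfg, net.nodes[1], op)
        x = rwr_stationary(op, s, r=0.7, tol=1e-12, max_iter=5000)
        np.testing.assert_allclose(np.abs(x - solve_oracle(op, s, 0.7)).sum(),
                                   0.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_monoplex_reduction_equals_personalized_pagerank(self, seed):
        """One multiplex, one layer: the walk is personalized PageRank with
        damping 1-r, independently computed by networkx."""
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(5, 12))
        ids = [f"m::{i}" for i in range(n)]
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    edges.append((ids[i], ids[j], float(rng.uniform(0.5, 3.0))))
        if not edges:
            edges = [(ids[0], ids[1], 1.0)]
        net = MultilayerNetwork(
            multiplexes=[Multiplex("m", ids, [LayerGraph(edges=edges)])]
        )
        r = 0.7
        cfg = RWRConfig.defaults(net)
        op = build_transition_operator(net, cfg)
        s = build_restart_vector(net, cfg, ids[0], op)
        x = aggregate_to_nodes(rwr_stationary(op, s, r=r, tol=1e-14, max_iter=10000),
                               op.index)
        G = nx.Graph()
        G.add_nodes_from(ids)
        G.add_weighted_edges_from(edges)
        pr = nx.pagerank(G, alpha=1 - r, personalization={ids[0]: 1.0},
                         weight="weight", tol=1e-14, max_iter=10000)
        ref = np.array([pr[i] for i in ids])
        assert np.abs(x - ref).sum() < 1e-8


class TestSimilarityMatrix:
    def test_restart_only_gives_identity(self):
        rng = np.random.default_rng(5)
        net = random_multilayer(rng)
        cfg = RWRConfig.defaults(net)
        cfg.r = 1.0
        sim = similarity_matrix(net, cfg)
        np.testing.assert_allclose(sim.matrix, np.eye(net.n_nodes), atol=1e-12)

    def test_rows_are_distributions_and_match_oracle(self):
        rng = np.random.default_rng(6)
        net = random_multilayer(rng)
        cfg = RWRConfig.defaults(net)
        cfg.tol = 1e-12
        sim = similarity_matrix(net, cfg)
        assert np.allclose(sim.matrix.sum(axis=1), 1.0, atol=1e-8)
        op = build_transition_operator(net, cfg)
        idx = op.index
        for seed_node in net.nodes[:4]:
            s = build_restart_vector(net, cfg, seed_node, op)
            ref = aggregate_to_nodes(solve_oracle(op, s, cfg.r), idx)
            assert np.abs(sim.row(seed_node) - ref).sum() < 1e-6

    def test_result_independent_of_batch_composition(self):
        rng = np.random.default_rng(7)
        net = random_multilayer(rng)
        cfg = RWRConfig.defaults(net)
        a = similarity_matrix(net, cfg, batch_size=3)
        b = similarity_matrix(net, cfg, batch_size=1000)
        np.testing.assert_array_equal(a.matrix, b.matrix)


class TestConfigValidation:
    def test_bad_eta_rejected(self, path_monoplex):
        cfg = RWRConfig.defaults(path_monoplex)
        cfg.eta = np.array([0.5])
        with pytest.raises(ValidationError):
            cfg.validate(path_monoplex)

    def test_bad_lam_row_rejected(self, path_monoplex):
        cfg = RWRConfig.defaults(path_monoplex)
        cfg.lam = np.array([[0.5]])
        with pytest.raises(ValidationError):
            cfg.validate(path_monoplex)

    def test_bad_r_rejected(self, path_monoplex):
        cfg = RWRConfig.defaults(path_monoplex)
        cfg.r = 0.0
        with pytest.raises(ValidationError):
            cfg.validate(path_monoplex)

    def test_replica_index_layout(self, bench_net):
        net, _ = bench_net
        idx = ReplicaIndex(net)
        assert idx.n_nodes == 450
        assert idx.n_replicas == 200 * 3 + 100 * 2 + 150 * 4
        agg = idx.aggregation_matrix()
        assert agg.shape == (450, idx.n_replicas)
        assert np.all(np.asarray(agg.sum(axis=0)).ravel() == 1.0)
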