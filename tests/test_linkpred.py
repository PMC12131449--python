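import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from mplexembed import (
    Bipartite,
    EmbeddingMatrix,
    LayerGraph,
    Multiplex,
    MultilayerNetwork,
    MultiplexSpec,
    BipartiteSpec,
    PlantedSpec,
    RWRConfig,
    TrainParams,
    edge_features,
    evaluate_link_prediction,
    generate_planted_network,
    sample_nonedges,
    split_bipartite_edges,
)
from mplexembed.linkpred import EDGE_OPERATORS, DEFAULT_REPETITIONS, DEFAULT_FRACTION
from mplexembed.network_model import ValidationError


def emb_of(vectors: dict) -> EmbeddingMatrix:
    ids = list(vectors)
    return EmbeddingMatrix(ids, np.array([vectors[i] for i in ids], dtype=float))


class TestOperators:
    def test_hadamard(self):
        e = emb_of({"u": [1, 2], "v": [3, 4]})
        assert edge_features(e, [("u", "v")], "hadamard").tolist() == [[3, 8]]

    def test_average(self):
        e = emb_of({"u": [1, 2], "v": [3, 4]})
        assert edge_features(e, [("u", "v")], "average").tolist() == [[2, 3]]

    def test_weighted_l1(self):
        e = emb_of({"u": [1, 2], "v": [3, 0]})
        assert edge_features(e, [("u", "v")], "weighted_l1").tolist() == [[2, 2]]

    def test_weighted_l2(self):
        e = emb_of({"u": [1, 2], "v": [3, 0]})
        assert edge_features(e, [("u", "v")], "weighted_l2").tolist() == [[4, 4]]

    def test_cosine_orthogonal_is_zero(self):
        e = emb_of({"u": [1, 0], "v": [0, 1]})
        assert edge_features(e, [("u", "v")], "cosine").tolist() == [[0]]

    def test_cosine_zero_vector_is_zero(self):
        e = emb_of({"u": [0, 0], "v": [1, 1]})
        assert edge_features(e, [("u", "v")], "cosine").tolist() == [[0]]

    def test_unknown_operator_rejected(self):
        e = emb_of({"u": [1, 0], "v": [0, 1]})
        with pytest.raises(ValidationError):
            edge_features(e, [("u", "v")], "concat")

    @given(hnp.arrays(np.float64, (2, 6), elements=st.floats(-5, 5)))
    def test_all_operators_symmetric(self, pair):
        e = emb_of({"u": pair[0], "v": pair[1]})
        for op in EDGE_OPERATORS:
            f_uv = edge_features(e, [("u", "v")], op)
            f_vu = edge_features(e, [("v", "u")], op)
            np.testing.assert_allclose(f_uv, f_vu, atol=1e-12)


@pytest.fixture
def ten_edge_net():
    left_ids = [f"L::{i}" for i in range(5)]
    right_ids = [f"R::{i}" for i in range(5)]
    ml = Multiplex("L", left_ids, [LayerGraph(
        edges=[(left_ids[i], left_ids[i + 1], 1.0) for i in range(4)])])
    mr = Multiplex("R", right_ids, [LayerGraph(
        edges=[(right_ids[i], right_ids[i + 1], 1.0) for i in range(4)])])
    edges = [(left_ids[i], right_ids[j], 1.0) for i in range(5) for j in range(2)]
    bp = Bipartite("b", "L", "R", edges)
    return MultilayerNetwork([ml, mr], [bp])


class TestSplit:
    def test_ten_edges_fraction_03_gives_3_test(self, ten_edge_net):
        split = split_bipartite_edges(ten_edge_net, 0.3, np.random.default_rng(0))
        assert len(split.test_positives["b"]) == 3
        assert len(split.train_network.bipartite("b").edges) == 7

    def test_fraction_zero_keeps_everything(self, ten_edge_net):
        split = split_bipartite_edges(ten_edge_net, 0.0, np.random.default_rng(0))
        assert split.test_positives["b"] == []
        assert len(split.train_network.bipartite("b").edges) == 10

    def test_partition_reassembles_original(self, ten_edge_net):
        split = split_bipartite_edges(ten_edge_net, 0.3, np.random.default_rng(1))
        train = split.train_network.bipartite("b").edge_set
        test = set(split.test_positives["b"])
        assert train | test == ten_edge_net.bipartite("b").edge_set
        assert not (train & test)

    def test_multiplex_layers_untouched(self, ten_edge_net):
        split = split_bipartite_edges(ten_edge_net, 0.3, np.random.default_rng(2))
        assert split.train_network.multiplexes is ten_edge_net.multiplexes

    def test_bad_fraction_rejected(self, ten_edge_net):
        with pytest.raises(ValidationError):
            split_bipartite_edges(ten_edge_net, 1.0, np.random.default_rng(0))


class TestNonedges:
    def test_complete_bipartite_has_no_nonedges(self):
        left = ["L::a"]
        right = ["R::b"]
        net = MultilayerNetwork(
            [Multiplex("L", left, [LayerGraph()]), Multiplex("R", right, [LayerGraph()])],
            [Bipartite("b", "L", "R", [("L::a", "R::b", 1.0)])],
        )
        with pytest.raises(ValidationError):
            sample_nonedges(net, "b", 1, np.random.default_rng(0))

    def test_disjoint_from_edges_exact_count_no_duplicates(self, ten_edge_net):
        pairs = sample_nonedges(ten_edge_net, "b", 12, np.random.default_rng(3))
        assert len(pairs) == 12
        assert len(set(pairs)) == 12
        assert not (set(pairs) & ten_edge_net.bipartite("b").edge_set)

    def test_exclusion_respected(self, ten_edge_net):
        rng = np.random.default_rng(4)
        first = sample_nonedges(ten_edge_net, "b", 7, rng)
        second = sample_nonedges(ten_edge_net, "b", 8, rng, exclude=set(first))
        assert not (set(first) & set(second))


class TestClassifierStage:
    def test_perfectly_separable_embedding_gives_auc_one(self):
        rng = np.random.default_rng(0)
        pos = [(f"p{i}a", f"p{i}b") for i in range(50)]
        neg = [(f"n{i}a", f"n{i}b") for i in range(50)]
        vectors = {}
        for u, v in pos:
            vectors[u] = np.r_[1.0, rng.normal(scale=0.01, size=3)]
            vectors[v] = np.r_[1.0, rng.normal(scale=0.01, size=3)]
        for u, v in neg:
            vectors[u] = np.r_[-1.0, rng.normal(scale=0.01, size=3)]
            vectors[v] = np.r_[-1.0, rng.normal(scale=0.01, size=3)]
        e = emb_of(vectors)
        X = np.vstack([edge_features(e, pos, "average"),
                       edge_features(e, neg, "average")])
        y = np.r_[np.ones(50), np.zeros(50)]
        clf = RandomForestClassifier(100, random_state=0).fit(X, y)
        assert roc_auc_score(y, clf.predict_proba(X)[:, 1]) == 1.0

    def test_random_labels_give_null_auc(self):
        rng = np.random.default_rng(1)
        X_train = rng.normal(size=(200, 8))
        y_train = rng.integers(0, 2, size=200)
        X_test = rng.normal(size=(400, 8))
        y_test = rng.integers(0, 2, size=400)
        clf = RandomForestClassifier(100, random_state=0).fit(X_train, y_train)
        auc = roc_auc_score(y_test, clf.predict_proba(X_test)[:, 1])
        assert 0.4 <= auc <= 0.6


@pytest.fixture(scope="module")
def small_planted():
    spec = PlantedSpec(
        multiplexes=[MultiplexSpec("g", 40, 2, 0.3, 0.02),
                     MultiplexSpec("d", 30, 1, 0.3, 0.02)],
        bipartites=[BipartiteSpec("gd", "g", "d", 0.3, 0.02)],
        communities=2,
    )
    net, _ = generate_planted_network(spec, seed=5)
    return net


class TestEvaluateProtocol:
    def test_result_structure_and_ranges(self, small_planted):
        cfg = RWRConfig.defaults(small_planted)
        res = evaluate_link_prediction(
            small_planted, cfg, TrainParams(d=8, steps=20_000),
            repetitions=2, seed=0,
        )
        assert res.repetitions == 2
        assert set(res.operators) == set(EDGE_OPERATORS)
        assert res.bipartites == ["gd"]
        for key, aucs in res.scores.items():
            assert len(aucs) == 2
            assert all(0.0 <= a <= 1.0 for a in aucs)
            assert res.std(*key) >= 0.0
        frame = res.to_frame()
        assert list(frame.columns) == ["gd"]
        assert len(frame) == len(EDGE_OPERATORS)

    def test_protocol_defaults(self):
        assert DEFAULT_REPETITIONS == 10
        assert DEFAULT_FRACTION == 0.3
        import inspect
        sig = inspect.signature(evaluate_link_prediction)
        assert sig.parameters["repetitions"].default == 10
        assert sig.parameters["fraction"].default == 0.3

    def test_tiny_bipartite_skipped_with_warning(self, small_planted):
        tiny = Bipartite("tiny", "g", "d",
                         [(small_planted.multiplex("g").node_ids[0],
                           small_planted.multiplex("d").node_ids[0], 1.0)])
        net = MultilayerNetwork(small_planted.multiplexes,
                                small_planted.bipartites + [tiny])
        cfg = RWRConfig.defaults(net)
        with pytest.warns(UserWarning, match="tiny"):
            res = evaluate_link_prediction(
                net, cfg, TrainParams(d=8, steps=5_000),
                repetitions=1, seed=0, operators=["average"],
            )
        assert all(b != "tiny" for b, _ in res.scores)
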