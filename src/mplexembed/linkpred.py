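"""Link-prediction evaluation of embeddings on held-out bipartite edges.

Protocol: remove a fraction (default 30%) of each bipartite's edges to
form a training network; embed the training network only; featurize node
pairs with an edge operator; train a binary classifier on training-edge
positives versus an equal number of sampled non-edges; score ROC-AUC on
the held-out positives versus fresh non-edges.  Repeat (default 10
times) and report mean +/- std per bipartite and operator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .network_model import (
    Bipartite,
    EmbeddingMatrix,
    MultilayerNetwork,
    ValidationError,
)
from .rwr import RWRConfig, similarity_matrix
from .embedding import TrainParams, train_embedding

logger = logging.getLogger(__name__)

DEFAULT_FRACTION = 0.3
DEFAULT_REPETITIONS = 10
MIN_BIPARTITE_EDGES = 4


# ---------------------------------------------------------------------------
# edge operators


def _hadamard(U, V):
    return U * V


def _weighted_l1(U, V):
    return np.abs(U - V)


def _weighted_l2(U, V):
    return (U - V) ** 2


def _average(U, V):
    return (U + V) / 2.0


def _cosine(U, V):
    nu = np.linalg.norm(U, axis=1)
    nv = np.linalg.norm(V, axis=1)
    denom = nu * nv
    out = np.zeros(len(U))
    ok = denom > 0
    out[ok] = np.einsum("ij,ij->i", U[ok], V[ok]) / denom[ok]
    return out[:, None]


EDGE_OPERATORS = {
    "hadamard": _hadamard,
    "weighted_l1": _weighted_l1,
    "weighted_l2": _weighted_l2,
    "average": _average,
    "cosine": _cosine,
}


def edge_features(emb: EmbeddingMatrix, pairs, operator: str) -> np.ndarray:
    """Pair feature matrix under one edge operator.

    hadamard / weighted_l1 / weighted_l2 / average map two d-vectors to a
    d-vector elementwise; cosine yields one scalar per pair (0 when
    either vector has zero norm).
    """
    if operator not in EDGE_OPERATORS:
        raise ValidationError(
            f"unknown edge operator {operator!r}; valid: {sorted(EDGE_OPERATORS)}"
        )
    idx = emb.index
    pairs = list(pairs)
    U = emb.vectors[[idx[u] for u, _ in pairs]]
    V = emb.vectors[[idx[v] for _, v in pairs]]
    return np.atleast_2d(EDGE_OPERATORS[operator](U, V))


# ---------------------------------------------------------------------------
# splitting and negative sampling


@dataclass
class SplitResult:
    """A train/test partition of every bipartite's edge set."""

    train_network: MultilayerNetwork
    test_positives: dict[str, list[tuple[str, str]]]
    fraction: float


def split_bipartite_edges(net: MultilayerNetwork, fraction: float,
                          rng: np.random.Generator) -> SplitResult:
    """Hold out ``round(fraction * |edges|)`` edges of each bipartite,
    uniformly without replacement.  Multiplex layers are untouched."""
    if not (0 <= fraction < 1):
        raise ValidationError(f"fraction {fraction} outside [0, 1)")
    train_bips: list[Bipartite] = []
    test: dict[str, list[tuple[str, str]]] = {}
    for b in net.bipartites:
        n_test = int(round(fraction * len(b.edges)))
        picks = rng.choice(len(b.edges), size=n_test, replace=False)
        mask = np.zeros(len(b.edges), dtype=bool)
        mask[picks] = True
        test[b.name] = [(b.edges[i][0], b.edges[i][1]) for i in np.flatnonzero(mask)]
        train_edges = [b.edges[i] for i in np.flatnonzero(~mask)]
        train_bips.append(Bipartite(b.name, b.left, b.right, train_edges))
    train_net = MultilayerNetwork(multiplexes=net.multiplexes, bipartites=train_bips)
    return SplitResult(train_network=train_net, test_positives=test, fraction=fraction)


def sample_nonedges(net: MultilayerNetwork, bipartite_name: str, count: int,
                    rng: np.random.Generator,
                    exclude: set[tuple[str, str]] | None = None) -> list[tuple[str, str]]:
    """Uniform distinct (left, right) pairs absent from the FULL bipartite
    edge set (and from ``exclude``, if given)."""
    b = net.bipartite(bipartite_name)
    left = net.multiplex(b.left).node_ids
    right = net.multiplex(b.right).node_ids
    forbidden = b.edge_set
    if exclude:
        forbidden = forbidden | set(exclude)
    capacity = len(left) * len(right) - len(forbidden)
    if count > capacity:
        raise ValidationError(
            f"requested {count} non-edges but only {capacity} exist in "
            f"bipartite {bipartite_name!r}"
        )
    chosen: dict[tuple[str, str], None] = {}
    while len(chosen) < count:
        k = count - len(chosen)
        li = rng.integers(0, len(left), size=2 * k + 8)
        ri = rng.integers(0, len(right), size=2 * k + 8)
        for a, c in zip(li, ri):
            pair = (left[a], right[c])
            if pair in forbidden or pair in chosen:
                continue
            chosen[pair] = None
            if len(chosen) == count:
                break
    return list(chosen)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class LinkPredictionResult:
    """ROC-AUC mean and std per (bipartite, operator) over repetitions."""

    scores: dict[tuple[str, str], list[float]]
    repetitions: int
    operators: list[str]
    bipartites: list[str]

    def mean(self, bipartite: str, operator: str) -> float:
        return float(np.mean(self.scores[(bipartite, operator)]))

    def std(self, bipartite: str, operator: str) -> float:
        return float(np.std(self.scores[(bipartite, operator)]))

    def to_frame(self) -> pd.DataFrame:
        """Table with operators as rows and bipartites as columns,
        cells formatted ``mean+/-std``."""
        data = {
            b: [f"{self.mean(b, op):.3f}±{self.std(b, op):.3f}"
                for op in self.operators]
            for b in self.bipartites
        }
        return pd.DataFrame(data, index=self.operators)


def default_classifier(seed: int):
    return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)


def evaluate_link_prediction(net: MultilayerNetwork, rwr_cfg: RWRConfig,
                             train_params: TrainParams,
                             repetitions: int = DEFAULT_REPETITIONS,
                             fraction: float = DEFAULT_FRACTION,
                             seed: int = 0,
                             operators=None,
                             classifier_factory=default_classifier) -> LinkPredictionResult:
    """Run the full hold-out evaluation protocol.

    Per repetition: split each bipartite, embed the training network
    only, then per bipartite and operator fit a binary classifier
    (default random forest, 100 trees) on balanced positives/non-edges
    and score ROC-AUC on the held-out edges versus fresh non-edges
    disjoint from the training negatives.
    """
    if not net.bipartites:
        raise ValidationError("network has no bipartite to evaluate")
    operators = list(operators) if operators is not None else list(EDGE_OPERATORS)
    eligible = [b.name for b in net.bipartites if len(b.edges) >= MIN_BIPARTITE_EDGES]
    for b in net.bipartites:
        if b.name not in eligible:
            warnings.warn(f"bipartite {b.name!r} has < {MIN_BIPARTITE_EDGES} edges; skipped")
    scores: dict[tuple[str, str], list[float]] = {
        (b, op): [] for b in eligible for op in operators
    }
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(repetitions)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(rep_seed)
        split = split_bipartite_edges(net, fraction, rng)
        # leakage guard: held-out positives must be absent from the train net
        for bname, pos in split.test_positives.items():
            train_set = split.train_network.bipartite(bname).edge_set
            assert not (set(pos) & train_set), "test positives leaked into training"
        simmat = similarity_matrix(split.train_network, rwr_cfg)
        params = TrainParams(**{**train_params.__dict__, "seed": rep_seed})
        emb, _ = train_embedding(simmat, params)
        for bname in eligible:
            train_pos = [(u, v) for u, v, _ in split.train_network.bipartite(bname).edges]
            test_pos = split.test_positives[bname]
            if not test_pos or not train_pos:
                continue
            train_neg = sample_nonedges(net, bname, len(train_pos), rng)
            test_neg = sample_nonedges(net, bname, len(test_pos), rng,
                                       exclude=set(train_neg))
            y_train = np.r_[np.ones(len(train_pos)), np.zeros(len(train_neg))]
            y_test = np.r_[np.ones(len(test_pos)), np.zeros(len(test_neg))]
            for op in operators:
                X_train = np.vstack([
                    edge_features(emb, train_pos, op),
                    edge_features(emb, train_neg, op),
                ])
                X_test = np.vstack([
                    edge_features(emb, test_pos, op),
                    edge_features(emb, test_neg, op),
                ])
                clf = classifier_factory(rep_seed)
                clf.fit(X_train, y_train)
                prob = clf.predict_proba(X_test)[:, 1]
                scores[(bname, op)].append(float(roc_auc_score(y_test, prob)))
        logger.info("link-prediction repetition %d/%d done", rep + 1, repetitions)
    return LinkPredictionResult(scores=scores, repetitions=repetitions,
                                operators=operators, bipartites=eligible)
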