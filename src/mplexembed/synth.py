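"""Synthetic multiplex-heterogeneous networks with planted communities.

Each multiplex is a stack of independent planted-partition (stochastic
block model) layers over its node set: edge probability ``p_in`` within
a community, ``p_out`` across.  Communities are aligned one-to-one
across node types (gene community c <-> disease community c <-> drug
community c), and bipartite edges appear with probability ``q_in`` for
label-matched pairs and ``q_out`` otherwise -- this cross-type alignment
is what makes held-out bipartite edges predictable from the multiplex
structure, the statistical premise behind the link-prediction benchmark.

The null generator keeps the same shape and expected density but uses a
single Bernoulli rate everywhere (the planted mixture mean), removing
all community signal.

The default benchmark fixture mirrors the composition of a real
drug-gene-disease knowledge network: a gene multiplex with 3 layers, a
disease multiplex with 2, a drug multiplex with 4, joined by
gene-disease, drug-target (drug-gene) and drug-disease bipartites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_model import (
    Bipartite,
    LayerGraph,
    MultilayerNetwork,
    Multiplex,
    ValidationError,
    namespace_id,
)


@dataclass
class MultiplexSpec:
    name: str
    n: int
    layers: int
    p_in: float
    p_out: float


@dataclass
class BipartiteSpec:
    name: str
    left: str
    right: str
    q_in: float
    q_out: float


@dataclass
class PlantedSpec:
    """Shape and edge-probability parameters of the planted generator."""

    multiplexes: list[MultiplexSpec]
    bipartites: list[BipartiteSpec]
    communities: int

    def validate(self) -> None:
        if self.communities < 2:
            raise ValidationError("need at least 2 communities")
        names = {m.name for m in self.multiplexes}
        for m in self.multiplexes:
            if m.n < self.communities:
                raise ValidationError(
                    f"multiplex {m.name!r} has fewer nodes than communities"
                )
            if not (0 <= m.p_out < m.p_in <= 1):
                raise ValidationError(
                    f"multiplex {m.name!r} requires 0 <= p_out < p_in <= 1"
                )
            if m.layers < 1:
                raise ValidationError(f"multiplex {m.name!r} needs >= 1 layer")
        for b in self.bipartites:
            if b.left not in names or b.right not in names:
                raise ValidationError(f"bipartite {b.name!r} references unknown multiplex")
            if not (0 <= b.q_out < b.q_in <= 1):
                raise ValidationError(
                    f"bipartite {b.name!r} requires 0 <= q_out < q_in <= 1"
                )


def benchmark_shape_spec(n_gene: int = 200, n_disease: int = 100, n_drug: int = 150,
                     communities: int = 5,
                     p_in: float = 0.15, p_out: float = 0.01,
                     q_in: float = 0.10, q_out: float = 0.005) -> PlantedSpec:
    """Default fixture shaped like a drug-gene-disease knowledge network:
    gene multiplex (3 layers), disease multiplex (2), drug multiplex (4),
    three bipartites."""
    return PlantedSpec(
        multiplexes=[
            MultiplexSpec("gene", n_gene, 3, p_in, p_out),
            MultiplexSpec("disease", n_disease, 2, p_in, p_out),
            MultiplexSpec("drug", n_drug, 4, p_in, p_out),
        ],
        bipartites=[
            BipartiteSpec("gene_disease", "gene", "disease", q_in, q_out),
            BipartiteSpec("drug_target", "drug", "gene", q_in, q_out),
            BipartiteSpec("drug_disease", "drug", "disease", q_in, q_out),
        ],
        communities=communities,
    )


def _node_ids(mspec: MultiplexSpec) -> list[str]:
    width = max(4, len(str(mspec.n - 1)))
    return [namespace_id(mspec.name, f"n{i:0{width}d}") for i in range(mspec.n)]


def _labels(n: int, C: int) -> np.ndarray:
    """Balanced round-robin community labels (remainder spread evenly)."""
    return np.arange(n) % C


def _planted_layer(ids: list[str], labels: np.ndarray, p_in: float, p_out: float,
                   rng: np.random.Generator) -> LayerGraph:
    n = len(ids)
    same = labels[:, None] == labels[None, :]
    P = np.where(same, p_in, p_out)
    draws = rng.random((n, n))
    iu, ju = np.triu_indices(n, k=1)
    hit = draws[iu, ju] < P[iu, ju]
    edges = [(ids[i], ids[j], 1.0) for i, j in zip(iu[hit], ju[hit])]
    return LayerGraph(edges=edges, directed=False)


def _planted_bipartite(bspec: BipartiteSpec, left_ids, left_lab, right_ids, right_lab,
                       q_in: float, q_out: float, rng: np.random.Generator) -> Bipartite:
    same = left_lab[:, None] == right_lab[None, :]
    P = np.where(same, q_in, q_out)
    hit = rng.random(P.shape) < P
    li, ri = np.nonzero(hit)
    edges = [(left_ids[i], right_ids[j], 1.0) for i, j in zip(li, ri)]
    return Bipartite(bspec.name, bspec.left, bspec.right, edges)


def _generate(spec: PlantedSpec, seed: int, p_override=None, q_override=None):
    spec.validate()
    root = np.random.SeedSequence(seed)
    labels: dict[str, np.ndarray] = {}
    ids: dict[str, list[str]] = {}
    multiplexes: list[Multiplex] = []
    streams = iter(root.spawn(len(spec.multiplexes) * max(m.layers for m in spec.multiplexes)
                              + len(spec.bipartites) + 8))
    for mspec in spec.multiplexes:
        mids = _node_ids(mspec)
        mlab = _labels(mspec.n, spec.communities)
        ids[mspec.name] = mids
        labels[mspec.name] = mlab
        p_in, p_out = (p_override[mspec.name] if p_override else (mspec.p_in, mspec.p_out))
        layers = [
            _planted_layer(mids, mlab, p_in, p_out, np.random.default_rng(next(streams)))
            for _ in range(mspec.layers)
        ]
        # isolated nodes must still exist in the multiplex node set
        multiplexes.append(Multiplex(name=mspec.name, node_ids=mids, layers=layers))
    bipartites = []
    for bspec in spec.bipartites:
        q_in, q_out = (q_override[bspec.name] if q_override else (bspec.q_in, bspec.q_out))
        bipartites.append(
            _planted_bipartite(bspec, ids[bspec.left], labels[bspec.left],
                               ids[bspec.right], labels[bspec.right],
                               q_in, q_out, np.random.default_rng(next(streams)))
        )
    net = MultilayerNetwork(multiplexes=multiplexes, bipartites=bipartites)
    label_map = {
        nid: int(lab)
        for name in ids for nid, lab in zip(ids[name], labels[name])
    }
    return net, label_map


def generate_planted_network(spec: PlantedSpec, seed: int) -> tuple[MultilayerNetwork, dict[str, int]]:
    """Planted network plus ground-truth community label per node.
    Deterministic per seed (byte-identical edge lists)."""
    return _generate(spec, seed)


def _intra_pair_fraction(labels: np.ndarray) -> float:
    n = len(labels)
    same = int(((labels[:, None] == labels[None, :]).sum() - n) // 2)
    return same / (n * (n - 1) / 2)


def generate_null_network(spec: PlantedSpec, seed: int) -> MultilayerNetwork:
    """Same shape and expected density as the planted network, but a single
    edge probability everywhere (the planted mixture mean): no community
    signal survives."""
    spec.validate()
    p_override = {}
    for m in spec.multiplexes:
        lab = _labels(m.n, spec.communities)
        f = _intra_pair_fraction(lab)
        pbar = f * m.p_in + (1 - f) * m.p_out
        p_override[m.name] = (pbar, pbar)
    q_override = {}
    by_name = {m.name: m for m in spec.multiplexes}
    for b in spec.bipartites:
        ll = _labels(by_name[b.left].n, spec.communities)
        rl = _labels(by_name[b.right].n, spec.communities)
        f = float((ll[:, None] == rl[None, :]).mean())
        qbar = f * b.q_in + (1 - f) * b.q_out
        q_override[b.name] = (qbar, qbar)
    net, _ = _generate(spec, seed, p_override=p_override, q_override=q_override)
    return net


def write_network_files(net: MultilayerNetwork, labels: dict[str, int] | None,
                        outdir, rwr_overrides: dict | None = None) -> str:
    """Write layer/bipartite TSVs, a YAML config, and ground-truth labels.

    Returns the config path.  File ids are the raw (un-namespaced) ids;
    loading the config reproduces the namespaced network.
    """
    import yaml
    from pathlib import Path
    from .network_model import display_id

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg: dict = {"multiplexes": {}, "bipartites": {}}
    for m in net.multiplexes:
        files = []
        for li, layer in enumerate(m.layers):
            fname = f"{m.name}_layer{li}.tsv"
            with open(outdir / fname, "w") as fh:
                fh.write(f"# {m.name} layer {li}\n")
                for u, v, w in layer.edges:
                    fh.write(f"{display_id(u)}\t{display_id(v)}\t{w:g}\n")
            files.append(fname)
        nodes_file = f"{m.name}_nodes.txt"
        with open(outdir / nodes_file, "w") as fh:
            for nid in m.node_ids:
                fh.write(display_id(nid) + "\n")
        cfg["multiplexes"][m.name] = {"layers": files, "weighted": True,
                                      "nodes": nodes_file}
    for b in net.bipartites:
        fname = f"{b.name}.tsv"
        with open(outdir / fname, "w") as fh:
            for u, v, w in b.edges:
                fh.write(f"{display_id(u)}\t{display_id(v)}\t{w:g}\n")
        cfg["bipartites"][b.name] = {"left": b.left, "right": b.right,
                                     "file": fname, "weighted": True}
    if rwr_overrides:
        cfg["rwr"] = rwr_overrides
    cfg_path = outdir / "network.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    if labels is not None:
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("node\tcommunity\n")
            for nid, lab in labels.items():
                fh.write(f"{nid}\t{lab}\n")
    return str(cfg_path)
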