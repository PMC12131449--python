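"""Data model and I/O for multiplex-heterogeneous networks and embeddings.

A *multiplex* is an ordered stack of edge layers over one shared node set
(one node type); a *bipartite* links the node sets of two multiplexes.
The full multiplex-heterogeneous network is the collection of multiplexes
plus bipartites.  Node ids are opaque strings; globally unique ids are
guaranteed by namespacing file-loaded ids as ``multiplexname::rawid``.
Internally nodes receive contiguous integer indices in first-appearance
order, which is stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
import yaml

logger = logging.getLogger(__name__)

Edge = tuple[str, str, float]


class ParseError(ValueError):
    """A malformed line in an edge-list file."""


class ConfigError(ValueError):
    """A structurally invalid network configuration."""


class ValidationError(ValueError):
    """Data violating a network invariant."""


class FormatError(ValueError):
    """A malformed embedding file."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class LayerGraph:
    """One layer of a multiplex: an edge list over string node ids.

    Undirected layers store each edge once (canonical order of first
    appearance); adjacency queries via :meth:`to_adjacency` return both
    directions.  Weights are strictly positive; self-loops are never
    stored.
    """

    edges: list[Edge] = field(default_factory=list)
    directed: bool = False

    def __post_init__(self) -> None:
        for u, v, w in self.edges:
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            if not (w > 0):
                raise ValidationError(f"non-positive weight {w} on edge ({u}, {v})")

    @property
    def node_ids(self) -> list[str]:
        """Endpoint ids in first-appearance order."""
        seen: dict[str, None] = {}
        for u, v, _ in self.edges:
            seen.setdefault(u)
            seen.setdefault(v)
        return list(seen)

    def to_adjacency(self, index: dict[str, int], n: int) -> sp.csr_matrix:
        """Weighted adjacency A with A[j, i] = w(i -> j) over ``n`` nodes.

        Columns are sources so that column-normalizing yields the
        walk-step distribution.  Undirected edges contribute both
        directions.
        """
        rows, cols, vals = [], [], []
        for u, v, w in self.edges:
            iu, iv = index[u], index[v]
            rows.append(iv)
            cols.append(iu)
            vals.append(w)
            if not self.directed:
                rows.append(iu)
                cols.append(iv)
                vals.append(w)
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


@dataclass
class Multiplex:
    """Named stack of layers over one node set.

    ``node_ids`` is the ordered union of all layer endpoints; a node may
    be isolated (absent) in individual layers.
    """

    name: str
    node_ids: list[str]
    layers: list[LayerGraph]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError(f"multiplex {self.name!r} has no layers")
        idset = set(self.node_ids)
        if len(idset) != len(self.node_ids):
            raise ValidationError(f"duplicate node ids in multiplex {self.name!r}")
        for li, layer in enumerate(self.layers):
            missing = [n for n in layer.node_ids if n not in idset]
            if missing:
                raise ValidationError(
                    f"layer {li} of multiplex {self.name!r} has endpoints "
                    f"outside the node set: {missing[:5]}"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @classmethod
    def from_layers(cls, name: str, layers: Sequence[LayerGraph]) -> "Multiplex":
        """Node set = union of layer endpoints, first-appearance order."""
        seen: dict[str, None] = {}
        for layer in layers:
            for nid in layer.node_ids:
                seen.setdefault(nid)
        return cls(name=name, node_ids=list(seen), layers=list(layers))


@dataclass
class Bipartite:
    """Edges between the node sets of two distinct multiplexes."""

    name: str
    left: str
    right: str
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise ValidationError(
                f"bipartite {self.name!r} links multiplex {self.left!r} to itself"
            )
        for _, _, w in self.edges:
            if not (w > 0):
                raise ValidationError(f"non-positive weight in bipartite {self.name!r}")

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v, _ in self.edges}


@dataclass
class MultilayerNetwork:
    """The multiplex-heterogeneous network: multiplexes joined by bipartites."""

    multiplexes: list[Multiplex]
    bipartites: list[Bipartite] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.multiplexes]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate multiplex names: {names}")
        seen: set[str] = set()
        for m in self.multiplexes:
            overlap = seen & set(m.node_ids)
            if overlap:
                raise ValidationError(
                    f"node ids shared between multiplexes: {sorted(overlap)[:5]}"
                )
            seen |= set(m.node_ids)
        if not seen:
            raise ValidationError("network has no nodes")
        by_name = {m.name: m for m in self.multiplexes}
        for b in self.bipartites:
            for side, mult in ((0, b.left), (1, b.right)):
                if mult not in by_name:
                    raise ConfigError(
                        f"bipartite {b.name!r} references unknown multiplex {mult!r}"
                    )
                ids = set(by_name[mult].node_ids)
                bad = sorted({e[side] for e in b.edges} - ids)
                if bad:
                    raise ValidationError(
                        f"bipartite {b.name!r} endpoints absent from multiplex "
                        f"{mult!r}: {bad[:10]}"
                    )

    @property
    def multiplex_names(self) -> list[str]:
        return [m.name for m in self.multiplexes]

    def multiplex(self, name: str) -> Multiplex:
        for m in self.multiplexes:
            if m.name == name:
                return m
        raise KeyError(name)

    def bipartite(self, name: str) -> Bipartite:
        for b in self.bipartites:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def nodes(self) -> list[str]:
        """All nodes of V_MH, multiplex by multiplex, in stable order."""
        out: list[str] = []
        for m in self.multiplexes:
            out.extend(m.node_ids)
        return out

    @property
    def node_index(self) -> dict[str, int]:
        return {nid: i for i, nid in enumerate(self.nodes)}

    @property
    def node_multiplex(self) -> dict[str, str]:
        return {nid: m.name for m in self.multiplexes for nid in m.node_ids}

    @property
    def n_nodes(self) -> int:
        return sum(m.n_nodes for m in self.multiplexes)

    @property
    def n_edges(self) -> int:
        return sum(len(l.edges) for m in self.multiplexes for l in m.layers) + sum(
            len(b.edges) for b in self.bipartites
        )


@dataclass
class EmbeddingMatrix:
    """One d-vector per node, row order given by ``ids``."""

    ids: list[str]
    vectors: np.ndarray  # shape (n, d)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValidationError("embedding matrix shape does not match node count")
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("non-finite embedding entries")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate node ids in embedding")

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {nid: i for i, nid in enumerate(self.ids)}

    def __getitem__(self, node_id: str) -> np.ndarray:
        return self.vectors[self.index[node_id]]

    def subset(self, ids: Iterable[str]) -> "EmbeddingMatrix":
        idx = self.index
        ids = list(ids)
        return EmbeddingMatrix(ids, self.vectors[[idx[i] for i in ids]])


# ---------------------------------------------------------------------------
# namespacing helpers


def namespace_id(multiplex: str, raw_id: str) -> str:
    return f"{multiplex}::{raw_id}"


def display_id(node_id: str) -> str:
    """The un-namespaced id, for reporting."""
    _, sep, raw = node_id.partition("::")
    return raw if sep else node_id


# ---------------------------------------------------------------------------
# edge-list I/O


def read_edge_list(path: str | Path, directed: bool = False,
                   weighted: bool = False) -> LayerGraph:
    """Read a 2- or 3-column (tab/space separated) edge list.

    Lines starting with ``#`` are comments.  Self-loops are dropped and
    duplicate edges collapsed by summing their weights; both events are
    logged with counts.
    """
    edges = _read_edge_file(path, directed=directed, weighted=weighted,
                            drop_self_loops=True)
    return LayerGraph(edges=edges, directed=directed)


def _read_edge_file(path: str | Path, directed: bool, weighted: bool,
                    drop_self_loops: bool) -> list[Edge]:
    path = Path(path)
    acc: dict[tuple[str, str], float] = {}
    self_loops = 0
    duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            want = 3 if weighted else 2
            if len(fields) != want:
                raise ParseError(
                    f"{path}:{lineno}: expected {want} fields, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            if weighted:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad weight {fields[2]!r}") from exc
                if not (w > 0):
                    raise ValidationError(
                        f"{path}:{lineno}: non-positive weight {w}"
                    )
            else:
                w = 1.0
            if u == v and drop_self_loops:
                self_loops += 1
                continue
            key = (u, v) if directed else (min(u, v), max(u, v))
            if key in acc:
                duplicates += 1
                acc[key] += w
            else:
                acc[key] = w
    if self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, self_loops)
    if duplicates:
        logger.info("%s: collapsed %d duplicate edge(s)", path, duplicates)
    return [(u, v, w) for (u, v), w in acc.items()]


# ---------------------------------------------------------------------------
# config loading


def load_multilayer_config(path: str | Path):
    """Load a YAML network config into a validated network plus walk config.

    Returns ``(MultilayerNetwork, RWRConfig)``.  Layer and bipartite file
    paths are resolved relative to the config file.  Node ids from layer
    files are namespaced ``multiplexname::id`` so that ids are globally
    unique.  Walk parameters omitted from the ``rwr:`` block fall back to
    the standard defaults (r=0.7, uniform eta/lam/tau, delta=0.5).
    """
    from .rwr import RWRConfig  # local import avoids a module cycle

    path = Path(path)
    base = path.parent
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "multiplexes" not in raw:
        raise ConfigError(f"{path}: config must declare a 'multiplexes' block")

    multiplexes: list[Multiplex] = []
    for name, block in raw["multiplexes"].items():
        if not isinstance(block, dict) or not block.get("layers"):
            raise ConfigError(f"multiplex {name!r} must declare at least one layer")
        directed = block.get("directed", False)
        weighted = block.get("weighted", False)
        layer_files = block["layers"]
        directed_flags = (
            directed if isinstance(directed, list) else [directed] * len(layer_files)
        )
        layers = []
        for lf, dflag in zip(layer_files, directed_flags):
            lg = read_edge_list(base / lf, directed=bool(dflag), weighted=bool(weighted))
            layers.append(
                LayerGraph(
                    edges=[(namespace_id(name, u), namespace_id(name, v), w)
                           for u, v, w in lg.edges],
                    directed=lg.directed,
                )
            )
        mult = Multiplex.from_layers(name, layers)
        if block.get("nodes"):
            # optional explicit node list: keeps nodes isolated in every layer
            listed: dict[str, None] = {}
            with open(base / block["nodes"]) as fh:
                for line in fh:
                    line = line.strip()
                    if line and not line.startswith("#"):
                        listed.setdefault(namespace_id(name, line.split()[0]))
            for nid in mult.node_ids:
                listed.setdefault(nid)
            mult = Multiplex(name=name, node_ids=list(listed), layers=layers)
        multiplexes.append(mult)

    names = {m.name for m in multiplexes}
    bipartites: list[Bipartite] = []
    for bname, block in (raw.get("bipartites") or {}).items():
        if not isinstance(block, dict) or "left" not in block or "right" not in block:
            raise ConfigError(f"bipartite {bname!r} must declare 'left' and 'right'")
        left, right = block["left"], block["right"]
        if left not in names or right not in names:
            missing = left if left not in names else right
            raise ConfigError(
                f"bipartite {bname!r} references unknown multiplex {missing!r}"
            )
        # bipartite columns are positional (left, right): read as directed
        # so duplicate-collapsing never swaps the sides, and keep pairs
        # whose raw ids coincide (distinct nodes once namespaced)
        raw_edges = _read_edge_file(base / block["file"], directed=True,
                                    weighted=bool(block.get("weighted", False)),
                                    drop_self_loops=False)
        edges = [(namespace_id(left, u), namespace_id(right, v), w)
                 for u, v, w in raw_edges]
        bipartites.append(Bipartite(name=bname, left=left, right=right, edges=edges))

    net = MultilayerNetwork(multiplexes=multiplexes, bipartites=bipartites)
    cfg = RWRConfig.from_mapping(net, raw.get("rwr") or {})
    return net, cfg


# ---------------------------------------------------------------------------
# embedding I/O (word2vec-style text format)


def write_embeddings(emb: EmbeddingMatrix, path: str | Path) -> None:
    """Write ``n d`` header then one ``id v1 ... vd`` line per node."""
    with open(path, "w") as fh:
        fh.write(f"{emb.n_nodes} {emb.dimension}\n")
        for nid, vec in zip(emb.ids, emb.vectors):
            fh.write(nid + " " + " ".join(f"{x:.12g}" for x in vec) + "\n")


def read_embeddings(path: str | Path) -> EmbeddingMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: header must be 'n d'")
        try:
            n, d = int(header[0]), int(header[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer header") from exc
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != d + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {d + 1} fields, got {len(fields)}"
                )
            ids.append(fields[0])
            rows.append([float(x) for x in fields[1:]])
    if len(ids) != n:
        raise FormatError(f"{path}: header declares {n} rows, found {len(ids)}")
    return EmbeddingMatrix(ids, np.array(rows, dtype=np.float64))
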