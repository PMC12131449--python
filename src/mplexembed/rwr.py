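"""Random walk with restart on multiplex-heterogeneous networks.

The walker lives on *replicas* ``(multiplex, layer, node)``.  One step
from replica ``(k, a, i)`` splits its mass as follows:

* inter-multiplex: for each other multiplex ``j``, mass ``lam[k][j]``
  crosses a bipartite edge from node ``i`` into ``j`` (uniform over i's
  bipartite neighbours there), landing in a layer of ``j`` drawn from
  ``tau[j]``.  If ``i`` has no bipartite neighbour in ``j``, that mass is
  reassigned to the stay-in-``k`` branch.
* within-multiplex: the stay mass walks to a weight-proportional
  neighbour of ``i`` -- in the current layer with probability
  ``1 - delta_k``, or in a uniformly chosen other layer (same node) with
  probability ``delta_k``.  Mass that would step from an isolated layer
  copy is redirected to the restart distribution (dangling rule), which
  keeps every column of the operator stochastic.

The restart state mixes back with probability ``r`` per step; the
stationary distribution of the walk, aggregated over layer replicas,
defines the graph similarity sim_G(v, .) -- a probability distribution
over all nodes for each seed v.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .network_model import MultilayerNetwork, ValidationError

DEFAULT_RESTART = 0.7
DEFAULT_DELTA = 0.5
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000


class DegenerateOperatorError(ValueError):
    """The network has no edges anywhere: no walk is defined."""


class ConvergenceWarning(UserWarning):
    """Power iteration hit the iteration cap before reaching tolerance."""


@dataclass
class RWRConfig:
    """Walk parameters for the universal random walk with restart.

    r : global restart probability in (0, 1].
    eta : restart allocation across multiplexes (sums to 1).  With a
        single seed node all restart mass is renormalized onto the
        seed's own multiplex, so eta only matters for multi-seed runs.
    lam : row-stochastic inter-multiplex jump matrix.
    delta : per-multiplex probability of switching layer before a step.
    tau : per-multiplex restart allocation over its layers (each sums
        to 1).
    """

    r: float = DEFAULT_RESTART
    eta: np.ndarray = None
    lam: np.ndarray = None
    delta: np.ndarray = None
    tau: list[np.ndarray] = None
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER

    def validate(self, net: MultilayerNetwork) -> None:
        M = len(net.multiplexes)
        if not (0 < self.r <= 1):
            raise ValidationError(f"restart probability r={self.r} outside (0, 1]")
        if self.eta.shape != (M,) or abs(self.eta.sum() - 1) > 1e-9 or (self.eta < 0).any():
            raise ValidationError("eta must be a nonnegative vector over multiplexes summing to 1")
        if self.lam.shape != (M, M) or (self.lam < 0).any():
            raise ValidationError("lam must be a nonnegative MxM matrix")
        if not np.allclose(self.lam.sum(axis=1), 1, atol=1e-9):
            raise ValidationError("each row of lam must sum to 1")
        if self.delta.shape != (M,) or ((self.delta < 0) | (self.delta > 1)).any():
            raise ValidationError("delta entries must lie in [0, 1]")
        if len(self.tau) != M:
            raise ValidationError("tau must give one vector per multiplex")
        for m, t in zip(net.multiplexes, self.tau):
            if t.shape != (m.n_layers,) or abs(t.sum() - 1) > 1e-9 or (t < 0).any():
                raise ValidationError(
                    f"tau for multiplex {m.name!r} must be a nonnegative "
                    f"length-{m.n_layers} vector summing to 1"
                )
        if not (self.tol > 0):
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")

    @classmethod
    def defaults(cls, net: MultilayerNetwork) -> "RWRConfig":
        """Standard defaults: r=0.7, uniform eta/lam/tau, delta=0.5."""
        M = len(net.multiplexes)
        cfg = cls(
            r=DEFAULT_RESTART,
            eta=np.full(M, 1.0 / M),
            lam=np.full((M, M), 1.0 / M),
            delta=np.full(M, DEFAULT_DELTA),
            tau=[np.full(m.n_layers, 1.0 / m.n_layers) for m in net.multiplexes],
        )
        cfg.validate(net)
        return cfg

    @classmethod
    def from_mapping(cls, net: MultilayerNetwork, raw: Mapping) -> "RWRConfig":
        """Fill a config from a (possibly partial) mapping, defaulting the rest."""
        cfg = cls.defaults(net)
        if "r" in raw:
            cfg.r = float(raw["r"])
        if "tol" in raw:
            cfg.tol = float(raw["tol"])
        if "max_iter" in raw:
            cfg.max_iter = int(raw["max_iter"])
        if "eta" in raw:
            cfg.eta = np.asarray(raw["eta"], dtype=float)
        if "lam" in raw:
            cfg.lam = np.asarray(raw["lam"], dtype=float)
        if "delta" in raw:
            d = raw["delta"]
            cfg.delta = (
                np.full(len(net.multiplexes), float(d))
                if np.isscalar(d) else np.asarray(d, dtype=float)
            )
        if "tau" in raw:
            t = raw["tau"]
            if isinstance(t, Mapping):
                cfg.tau = [
                    np.asarray(t.get(m.name, cfg.tau[k]), dtype=float)
                    for k, m in enumerate(net.multiplexes)
                ]
            else:
                cfg.tau = [np.asarray(v, dtype=float) for v in t]
        cfg.validate(net)
        return cfg


class ReplicaIndex:
    """Bookkeeping for the (multiplex, layer, node) replica state space.

    Replicas of multiplex ``k`` occupy a contiguous block, layer-major:
    ``replica(k, l, i) = offset[k] + l * n_k + i`` with ``i`` the node's
    local index.  Global node order is the concatenation of multiplex
    node lists, matching :attr:`MultilayerNetwork.nodes`.
    """

    def __init__(self, net: MultilayerNetwork):
        self.net = net
        self.n_per_mult = [m.n_nodes for m in net.multiplexes]
        self.layers_per_mult = [m.n_layers for m in net.multiplexes]
        self.replica_offset = np.concatenate(
            ([0], np.cumsum([n * L for n, L in zip(self.n_per_mult, self.layers_per_mult)]))
        )
        self.node_offset = np.concatenate(([0], np.cumsum(self.n_per_mult)))
        self.n_replicas = int(self.replica_offset[-1])
        self.n_nodes = int(self.node_offset[-1])
        self.local_index = [
            {nid: i for i, nid in enumerate(m.node_ids)} for m in net.multiplexes
        ]
        self.mult_of_node = {
            nid: k for k, m in enumerate(net.multiplexes) for nid in m.node_ids
        }

    def replica(self, k: int, layer: int, local: int) -> int:
        return int(self.replica_offset[k]) + layer * self.n_per_mult[k] + local

    def locate(self, node_id: str) -> tuple[int, int]:
        """(multiplex index, local node index) of a node id."""
        try:
            k = self.mult_of_node[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None
        return k, self.local_index[k][node_id]

    def aggregation_matrix(self) -> sp.csr_matrix:
        """Sparse (n_nodes x n_replicas) summing layer replicas per node."""
        rows, cols = [], []
        for k, (n, L) in enumerate(zip(self.n_per_mult, self.layers_per_mult)):
            for layer in range(L):
                for i in range(n):
                    rows.append(int(self.node_offset[k]) + i)
                    cols.append(self.replica(k, layer, i))
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n_nodes, self.n_replicas))


@dataclass
class TransitionOperator:
    """Column-stochastic one-step operator, split into a fixed sparse part
    and a dangling component that re-enters through the restart vector.

    The implied matrix for restart distribution ``s`` is
    ``M = M0 + outer(s, dangling)``; every column sums to 1.
    """

    M0: sp.csr_matrix
    dangling: np.ndarray
    index: ReplicaIndex

    def apply(self, X: np.ndarray, S: np.ndarray) -> np.ndarray:
        """One walk step on column vectors/matrices X with restart columns S."""
        lost = self.dangling @ X
        return self.M0 @ X + S * lost

    def materialize(self, restart: np.ndarray) -> np.ndarray:
        """Dense matrix of the operator for one restart distribution."""
        return self.M0.toarray() + np.outer(restart, self.dangling)


def _normalize_columns(A: sp.csr_matrix) -> tuple[sp.csr_matrix, np.ndarray]:
    """Column-stochastic rescale; zero columns (isolated nodes) left zero."""
    colsum = np.asarray(A.sum(axis=0)).ravel()
    inv = np.zeros_like(colsum)
    nz = colsum > 0
    inv[nz] = 1.0 / colsum[nz]
    return (A @ sp.diags(inv)).tocsr(), nz


def build_transition_operator(net: MultilayerNetwork, cfg: RWRConfig) -> TransitionOperator:
    """Assemble the replica-space transition operator for a network."""
    cfg.validate(net)
    if net.n_edges == 0:
        raise DegenerateOperatorError("network has no edges in any layer or bipartite")
    idx = ReplicaIndex(net)
    M = len(net.multiplexes)

    # per-layer column-normalized adjacency (local node indexing)
    layer_T: list[list[sp.csr_matrix]] = []
    for k, m in enumerate(net.multiplexes):
        mats = []
        for layer in m.layers:
            A = layer.to_adjacency(idx.local_index[k], m.n_nodes)
            T, _ = _normalize_columns(A)
            mats.append(T)
        layer_T.append(mats)

    # bipartite hop operators k -> j: uniform over bipartite neighbours
    bip_T: dict[tuple[int, int], sp.csr_matrix] = {}
    has_nb: dict[tuple[int, int], np.ndarray] = {}
    name_to_k = {m.name: k for k, m in enumerate(net.multiplexes)}
    for k in range(M):
        for j in range(M):
            if j == k:
                continue
            nk, nj = idx.n_per_mult[k], idx.n_per_mult[j]
            rows, cols = [], []
            for b in net.bipartites:
                lk, rk = name_to_k[b.left], name_to_k[b.right]
                if (lk, rk) == (k, j):
                    pairs = ((u, v) for u, v, _ in b.edges)
                elif (lk, rk) == (j, k):
                    pairs = ((v, u) for u, v, _ in b.edges)
                else:
                    continue
                for src, dst in pairs:
                    cols.append(idx.local_index[k][src])
                    rows.append(idx.local_index[j][dst])
            A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(nj, nk))
            T, nz = _normalize_columns(A)
            bip_T[(k, j)] = T
            has_nb[(k, j)] = nz

    # stay mass per source node: lam[k,k] plus inter mass with no bipartite route
    stay: list[np.ndarray] = []
    for k in range(M):
        s = np.full(idx.n_per_mult[k], cfg.lam[k, k])
        for j in range(M):
            if j != k:
                s += cfg.lam[k, j] * (~has_nb[(k, j)])
        stay.append(s)

    # assemble the block grid over (multiplex, layer) cells
    cells = [(k, a) for k in range(M) for a in range(idx.layers_per_mult[k])]
    cell_pos = {c: t for t, c in enumerate(cells)}
    grid: list[list[sp.spmatrix | None]] = [
        [None] * len(cells) for _ in range(len(cells))
    ]
    for k in range(M):
        L = idx.layers_per_mult[k]
        delta_eff = cfg.delta[k] if L > 1 else 0.0
        for a in range(L):
            col_cell = cell_pos[(k, a)]
            for b_layer in range(L):
                coef = (1.0 - delta_eff) if b_layer == a else delta_eff / (L - 1)
                if coef == 0.0:
                    continue
                block = layer_T[k][b_layer] @ sp.diags(coef * stay[k])
                grid[cell_pos[(k, b_layer)]][col_cell] = block
            for j in range(M):
                if j == k or cfg.lam[k, j] == 0.0:
                    continue
                for lj in range(idx.layers_per_mult[j]):
                    coef = cfg.lam[k, j] * cfg.tau[j][lj]
                    if coef == 0.0:
                        continue
                    tgt = cell_pos[(j, lj)]
                    block = coef * bip_T[(k, j)]
                    grid[tgt][col_cell] = (
                        block if grid[tgt][col_cell] is None
                        else grid[tgt][col_cell] + block
                    )
    M0 = sp.bmat(grid, format="csr")
    dangling = 1.0 - np.asarray(M0.sum(axis=0)).ravel()
    dangling[np.abs(dangling) < 1e-14] = 0.0
    return TransitionOperator(M0=M0, dangling=dangling, index=idx)


def build_restart_vector(net: MultilayerNetwork, cfg: RWRConfig,
                         seed: str, op: TransitionOperator | None = None) -> np.ndarray:
    """Restart distribution for one seed node.

    With a single seed the restart mass eta would allocate to other
    multiplexes has no node to land on, so it is renormalized onto the
    seed's own multiplex: replica ``(k(seed), l, seed)`` receives
    ``tau[k(seed)][l]``, total mass 1.
    """
    idx = op.index if op is not None else ReplicaIndex(net)
    k, local = idx.locate(seed)
    s = np.zeros(idx.n_replicas)
    for layer in range(idx.layers_per_mult[k]):
        s[idx.replica(k, layer, local)] = cfg.tau[k][layer]
    return s


def rwr_stationary(op: TransitionOperator, s: np.ndarray, r: float,
                   tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                   on_iterate=None) -> np.ndarray:
    """Fixed point of ``x <- (1-r) M x + r s`` by power iteration from x0=s.

    ``on_iterate(x)``, if given, is called with each new iterate (used by
    diagnostics to watch mass conservation).  Emits a
    :class:`ConvergenceWarning` carrying the final L1 residual if the
    iteration cap is reached.
    """
    if not (0 < r <= 1):
        raise ValidationError(f"restart probability r={r} outside (0, 1]")
    x = s.astype(np.float64).copy()
    for _ in range(max_iter):
        x_new = (1.0 - r) * op.apply(x, s) + r * s
        if on_iterate is not None:
            on_iterate(x_new)
        resid = float(np.abs(x_new - x).sum())
        x = x_new
        if resid < tol:
            return x
    warnings.warn(
        f"RWR power iteration did not reach tol={tol} in {max_iter} "
        f"iterations (final L1 residual {resid:.3e})",
        ConvergenceWarning,
    )
    return x


def aggregate_to_nodes(x: np.ndarray, idx: ReplicaIndex) -> np.ndarray:
    """Collapse a replica distribution to node scores (sum over layers)."""
    out = np.zeros(idx.n_nodes)
    for k, (n, L) in enumerate(zip(idx.n_per_mult, idx.layers_per_mult)):
        base = int(idx.replica_offset[k])
        block = x[base:base + n * L].reshape(L, n)
        out[int(idx.node_offset[k]):int(idx.node_offset[k]) + n] = block.sum(axis=0)
    return out


@dataclass
class SimilarityMatrix:
    """sim_G rows: ``matrix[i]`` is the distribution of ``seed_ids[i]``
    over all nodes (column order = ``node_ids``)."""

    seed_ids: list[str]
    node_ids: list[str]
    matrix: np.ndarray  # shape (n_seeds, n_nodes)

    def row(self, seed: str) -> np.ndarray:
        return self.matrix[self.seed_ids.index(seed)]


def similarity_matrix(net: MultilayerNetwork, cfg: RWRConfig,
                      seeds: Sequence[str] | None = None,
                      batch_size: int = 256) -> SimilarityMatrix:
    """One RWR per seed node (default: every node of the network).

    Seeds are independent, so they are run as batched power iterations;
    results do not depend on batch composition or order.
    """
    cfg.validate(net)
    op = build_transition_operator(net, cfg)
    idx = op.index
    node_ids = net.nodes
    if seeds is None:
        seeds = node_ids
    seeds = list(seeds)
    agg = idx.aggregation_matrix()
    rows = np.empty((len(seeds), idx.n_nodes))
    for start in range(0, len(seeds), batch_size):
        chunk = seeds[start:start + batch_size]
        S = np.column_stack(
            [build_restart_vector(net, cfg, s, op) for s in chunk]
        )
        X = S.copy()
        # per-column freezing: each seed's trajectory is identical no
        # matter how seeds are batched together
        active = np.arange(X.shape[1])
        for _ in range(cfg.max_iter):
            Xa, Sa = X[:, active], S[:, active]
            X_new = (1.0 - cfg.r) * op.apply(Xa, Sa) + cfg.r * Sa
            resid = np.abs(X_new - Xa).sum(axis=0)
            X[:, active] = X_new
            active = active[resid >= cfg.tol]
            if len(active) == 0:
                break
        if len(active):
            warnings.warn(
                f"similarity batch: {len(active)} seed(s) did not converge",
                ConvergenceWarning,
            )
        rows[start:start + len(chunk)] = (agg @ X).T
    return SimilarityMatrix(seed_ids=seeds, node_ids=node_ids, matrix=rows)
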