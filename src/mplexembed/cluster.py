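"""Spherical k-means on embeddings and extraction of mixed-type modules.

Spherical k-means clusters unit-normalized vectors by cosine similarity:
each point joins the centroid with maximal cosine, and each centroid is
the normalized mean direction of its members.  Applied to embeddings of
a gene-disease-drug network it yields mixed modules whose induced
subnetwork (intra-layer plus bipartite edges) can be exported for
inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network_model import EmbeddingMatrix, MultilayerNetwork, ValidationError

DEFAULT_MAX_ITER = 300


@dataclass
class ClusterAssignment:
    k: int
    labels: dict[str, int]
    centroids: np.ndarray  # (k, d), unit rows (empty clusters flagged)
    seed: int
    empty_clusters: list[int]
    objective: float  # sum of member-centroid cosines
    history: list[float] = None  # objective after each iteration

    def members(self, cluster_id: int) -> list[str]:
        return [n for n, c in self.labels.items() if c == cluster_id]


def _normalize_rows(X: np.ndarray, ids) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        raise ValidationError(f"zero embedding vector for node {ids[zero[0]]!r}")
    return X / norms[:, None]


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding with squared cosine distance 1 - cos."""
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    best = 1.0 - X @ centroids[0]
    for j in range(1, k):
        w = np.maximum(best, 0.0) ** 2
        total = w.sum()
        if total <= 0:
            pick = rng.integers(n)
        else:
            pick = rng.choice(n, p=w / total)
        centroids[j] = X[pick]
        best = np.minimum(best, 1.0 - X @ centroids[j])
    return centroids


def spherical_kmeans(emb: EmbeddingMatrix, k: int, seed: int = 0,
                     max_iter: int = DEFAULT_MAX_ITER, tol: float = 0.0) -> ClusterAssignment:
    """Cluster embedding vectors on the unit sphere.

    Assignments go to the centroid of maximal cosine similarity (ties
    broken toward the lowest centroid index); centroids are renormalized
    mean directions.  Empty clusters are re-seeded from the point with
    the worst similarity to its own centroid.  The objective (sum of
    member-centroid cosines) is non-decreasing across iterations.
    """
    n = emb.n_nodes
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} must satisfy 1 <= k <= n={n}")
    X = _normalize_rows(np.asarray(emb.vectors, dtype=float), emb.ids)
    rng = np.random.default_rng(seed)
    C = _kmeanspp_init(X, k, rng)
    labels = np.full(n, -1)
    prev_obj = -np.inf
    history: list[float] = []
    for _ in range(max_iter):
        sims = X @ C.T
        new_labels = np.argmax(sims, axis=1)  # argmax takes lowest index on ties
        fit = sims[np.arange(n), new_labels]
        # re-seed empty clusters from the worst-fitting point
        for j in range(k):
            if not np.any(new_labels == j):
                worst = int(np.argmin(fit))
                new_labels[worst] = j
                fit[worst] = 1.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if len(members):
                mean = members.mean(axis=0)
                norm = np.linalg.norm(mean)
                if norm > 0:
                    C[j] = mean / norm
        obj = float((X * C[labels]).sum())
        history.append(obj)
        if obj < prev_obj - 1e-9 and tol == 0.0:
            # cannot happen for exact spherical k-means; guard stays for safety
            warnings.warn("spherical k-means objective decreased")
        if abs(obj - prev_obj) <= tol and tol > 0:
            prev_obj = obj
            break
        prev_obj = obj
    sims = X @ C.T
    labels = np.argmax(sims, axis=1)
    empty = [j for j in range(k) if not np.any(labels == j)]
    obj = float((X * C[labels]).sum())
    return ClusterAssignment(
        k=k,
        labels={nid: int(c) for nid, c in zip(emb.ids, labels)},
        centroids=C,
        seed=seed,
        empty_clusters=empty,
        objective=obj,
        history=history,
    )


@dataclass
class ModuleSubnetwork:
    """Induced subnetwork of one cluster, edges tagged by source network."""

    cluster_id: int
    nodes: list[str]
    edges: list[tuple[str, str, float, str]]  # (u, v, weight, source_network)


def extract_cluster_module(net: MultilayerNetwork, assignment: ClusterAssignment,
                           cluster_id: int) -> ModuleSubnetwork:
    """Induced mixed-type subnetwork over one cluster's nodes.

    Includes every intra-layer edge of every multiplex layer and every
    bipartite edge with BOTH endpoints in the cluster; each edge carries
    a ``source_network`` tag (``multiplex/layer<i>`` or bipartite name).
    """
    if not (0 <= cluster_id < assignment.k):
        raise ValidationError(f"cluster id {cluster_id} outside [0, {assignment.k})")
    members = {n for n, c in assignment.labels.items() if c == cluster_id}
    if not members:
        warnings.warn(f"cluster {cluster_id} is empty")
    edges: list[tuple[str, str, float, str]] = []
    for m in net.multiplexes:
        for li, layer in enumerate(m.layers):
            tag = f"{m.name}/layer{li}"
            for u, v, w in layer.edges:
                if u in members and v in members:
                    edges.append((u, v, w, tag))
    for b in net.bipartites:
        for u, v, w in b.edges:
            if u in members and v in members:
                edges.append((u, v, w, b.name))
    ordered = [n for n in net.nodes if n in members]
    return ModuleSubnetwork(cluster_id=cluster_id, nodes=ordered, edges=edges)
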