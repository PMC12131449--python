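"""Node embeddings approximating the RWR similarity distribution.

The embedding similarity of nodes u, v is the dot product ``w_u . w_v``;
its softmax over all nodes defines a distribution sim_Emb(v, .).  Training
minimizes KL(sim_G || sim_Emb) summed over seed nodes.  The softmax
normalizer is never materialized during training: noise-contrastive
estimation (NCE) trains a logistic discriminator between positive pairs
``(u, v)`` with u ~ P (uniform) and v ~ sim_G(u, .), and ``s`` noise pairs
with v drawn from Q (uniform), using the unnormalized dot product as the
discriminator logit.  A single shared embedding matrix is used -- no
separate context vectors -- so sim_Emb is symmetric in form.

The per-sample update is plain SGD with a linearly decaying learning
rate.  The inner loop is compiled with numba when available; the pure
Python path computes identical updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_model import EmbeddingMatrix, ValidationError
from .rwr import SimilarityMatrix

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

DEFAULT_DIM = 128
DEFAULT_NEGATIVES = 3
DEFAULT_LR = 0.025
DEFAULT_LR_MIN = 0.0001
STEPS_PER_NODE = 1400


@dataclass
class TrainParams:
    """SGD hyperparameters.

    ``steps`` defaults to 1400 samples per node when left as None.
    Source distribution P and noise distribution Q are both uniform over
    the node set.
    """

    d: int = DEFAULT_DIM
    steps: int | None = None
    lr: float = DEFAULT_LR
    lr_min: float = DEFAULT_LR_MIN
    s: int = DEFAULT_NEGATIVES
    seed: int = 0
    n_checkpoints: int = 10
    probe_size: int = 500

    def resolve_steps(self, n_nodes: int) -> int:
        return self.steps if self.steps is not None else STEPS_PER_NODE * n_nodes

    def validate(self, n_nodes: int) -> None:
        if self.d < 2:
            raise ValidationError("embedding dimension d must be >= 2")
        if not (1 <= self.s < n_nodes):
            raise ValidationError(f"negative-sample count s={self.s} must satisfy 1 <= s < n")
        if self.lr <= 0:
            raise ValidationError("learning rate must be positive")
        if self.resolve_steps(n_nodes) < 1:
            raise ValidationError("steps must be >= 1")


@dataclass
class TrainReport:
    """Probe-loss trajectory: estimated NCE loss on a fixed Monte-Carlo
    probe set at each checkpoint step."""

    checkpoint_steps: list[int] = field(default_factory=list)
    probe_losses: list[float] = field(default_factory=list)


def init_embedding(n: int, d: int, seed: int) -> np.ndarray:
    """Entries i.i.d. uniform in [-0.5/d, 0.5/d]; deterministic per seed."""
    if n < 1:
        raise ValidationError("need at least one node")
    rng = np.random.default_rng(seed)
    return rng.uniform(-0.5 / d, 0.5 / d, size=(n, d))


def sample_positive(row: np.ndarray, rng: np.random.Generator) -> int:
    """Draw a node index from a normalized similarity row."""
    row = np.asarray(row, dtype=float)
    if abs(row.sum() - 1.0) > 1e-6:
        raise ValidationError(f"similarity row sums to {row.sum():.6g}, not 1")
    cum = np.cumsum(row)
    return int(min(np.searchsorted(cum, rng.random(), side="right"), len(row) - 1))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def nce_update(W: np.ndarray, u: int, v_pos: int, v_negs, lr: float) -> float:
    """One NCE gradient-ascent step on
    ``log sigma(w_u.w_pos) + sum log(1 - sigma(w_u.w_neg))``.

    All gradients are evaluated at the incoming matrix and applied
    together; both endpoints of every pair are updated.  Returns the
    pre-update sampled loss (negative log-likelihood of the sample).
    """
    wu = W[u].copy()
    grad = np.zeros((len(v_negs) + 2, W.shape[1]))
    g_pos = 1.0 - _sigmoid(wu @ W[v_pos])
    loss = -np.log1p(-g_pos) if g_pos < 1 else np.inf  # -log sigma(pos)
    grad[0] = g_pos * W[v_pos]
    grad[1] = g_pos * wu
    for i, vn in enumerate(v_negs):
        s_neg = _sigmoid(wu @ W[vn])
        loss -= np.log1p(-s_neg) if s_neg < 1 else -np.inf
        grad[0] -= s_neg * W[vn]
        grad[i + 2] = -s_neg * wu
    W[u] += lr * grad[0]
    W[v_pos] += lr * grad[1]
    for i, vn in enumerate(v_negs):
        W[vn] += lr * grad[i + 2]
    return float(loss)


@njit(cache=False)
def _sgd_chunk(W, cum, u_arr, rpos_arr, neg_arr, lr_arr):  # pragma: no cover - jit
    n, d = W.shape
    steps = u_arr.shape[0]
    s = neg_arr.shape[1]
    wu_in = np.empty(d)
    gu = np.empty(d)
    sg = np.empty(s)
    for t in range(steps):
        u = u_arr[t]
        lr = lr_arr[t]
        v = np.searchsorted(cum[u], rpos_arr[t])
        if v >= n:
            v = n - 1
        for c in range(d):
            wu_in[c] = W[u, c]
        dot = 0.0
        for c in range(d):
            dot += wu_in[c] * W[v, c]
        g = 1.0 - 1.0 / (1.0 + np.exp(-dot))
        # all gradients below are evaluated at the incoming matrix
        for c in range(d):
            gu[c] = g * W[v, c]
        for q in range(s):
            vn = neg_arr[t, q]
            dot = 0.0
            for c in range(d):
                dot += wu_in[c] * W[vn, c]
            sg[q] = 1.0 / (1.0 + np.exp(-dot))
            for c in range(d):
                gu[c] -= sg[q] * W[vn, c]
        for c in range(d):
            W[v, c] += lr * g * wu_in[c]
        for q in range(s):
            vn = neg_arr[t, q]
            for c in range(d):
                W[vn, c] -= lr * sg[q] * wu_in[c]
        for c in range(d):
            W[u, c] += lr * gu[c]


def _probe_loss(W: np.ndarray, probe_u, probe_v, probe_negs) -> float:
    """NCE loss (Monte-Carlo estimate) on a fixed probe set."""
    total = 0.0
    for u, v, negs in zip(probe_u, probe_v, probe_negs):
        pos = _sigmoid(W[u] @ W[v])
        total -= np.log(max(pos, 1e-300))
        for vn in negs:
            total -= np.log(max(1.0 - _sigmoid(W[u] @ W[vn]), 1e-300))
    return total / len(probe_u)


def train_embedding(simmat: SimilarityMatrix, params: TrainParams) -> tuple[EmbeddingMatrix, TrainReport]:
    """Learn embeddings for every node covered by the similarity matrix.

    Deterministic for a fixed ``params.seed``: all sampling is drawn up
    front from one seeded generator, then consumed by the update loop.
    """
    if simmat.seed_ids != simmat.node_ids:
        raise ValidationError("similarity matrix must have one row per network node")
    n = len(simmat.node_ids)
    params.validate(n)
    steps = params.resolve_steps(n)
    rng = np.random.default_rng(params.seed)
    W = init_embedding(n, params.d, params.seed)
    cum = np.cumsum(simmat.matrix, axis=1)

    probe_rng = np.random.default_rng(params.seed + 1)
    m = min(params.probe_size, max(steps, 1))
    probe_u = probe_rng.integers(0, n, size=m)
    probe_v = np.array([
        min(np.searchsorted(cum[u], probe_rng.random(), side="right"), n - 1)
        for u in probe_u
    ])
    probe_negs = probe_rng.integers(0, n, size=(m, params.s))

    u_arr = rng.integers(0, n, size=steps)
    rpos_arr = rng.random(steps)
    neg_arr = rng.integers(0, n, size=(steps, params.s))
    lr_arr = params.lr + (params.lr_min - params.lr) * (
        np.arange(steps) / max(steps - 1, 1)
    )

    report = TrainReport()
    report.checkpoint_steps.append(0)
    report.probe_losses.append(_probe_loss(W, probe_u, probe_v, probe_negs))
    n_ck = max(1, min(params.n_checkpoints, steps))
    bounds = np.linspace(0, steps, n_ck + 1).astype(np.int64)
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if b1 == b0:
            continue
        _sgd_chunk(W, cum, u_arr[b0:b1], rpos_arr[b0:b1],
                   neg_arr[b0:b1], lr_arr[b0:b1])
        report.checkpoint_steps.append(int(b1))
        report.probe_losses.append(_probe_loss(W, probe_u, probe_v, probe_negs))
    if not all(np.isfinite(report.probe_losses)):
        raise ValidationError("non-finite probe loss during training")
    return EmbeddingMatrix(list(simmat.node_ids), W), report


def embedding_similarity(W: np.ndarray) -> np.ndarray:
    """Exhaustive sim_Emb: row-wise softmax of the dot-product matrix."""
    logits = W @ W.T
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def embedding_kl_divergence(simmat: SimilarityMatrix, W: np.ndarray) -> float:
    """Sum over seeds v of KL(sim_G(v,.) || sim_Emb(v,.)), exhaustively.

    Intended as a diagnostic / oracle on small networks; cost is O(n^2 d).
    """
    P = simmat.matrix
    Q = embedding_similarity(W)
    mask = P > 0
    return float(np.sum(P[mask] * (np.log(P[mask]) - np.log(Q[mask]))))
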