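# Methods

## The multiplex-heterogeneous network model

A *multiplex* is an ordered list of layers — edge sets over one shared node
set, each layer one interaction type. A *multiplex-heterogeneous network*
joins several multiplexes with different node types through bipartite edge
sets. Node ids are namespaced `multiplex::id` on load so that ids are
globally unique; un-namespaced ids are kept for reporting. All layers and
bipartites are undirected by default (directed layers are supported; walks
then use out-edges, with sink nodes handled by the dangling rule below).
Self-loops are dropped on load and duplicate edges collapse by summing
weights.

## Random walk with restart on the replica space

The walk state space is the set of replicas $(k, \alpha, i)$. One step from
a replica splits its mass:

1. **Inter-multiplex.** For each other multiplex $j$, mass
   $\lambda_{kj}$ crosses a bipartite edge from node $i$ into $j$,
   uniformly over $i$'s bipartite neighbours there, entering a layer of
   $j$ drawn from $\tau_j$. If $i$ has no bipartite neighbour in $j$,
   that mass is reassigned to the stay branch — this keeps the operator
   stochastic without inflating unrelated nodes.
2. **Within-multiplex.** The stay mass ($\lambda_{kk}$ plus any
   reassigned inter mass) walks to a weight-proportional neighbour: in
   the current layer with probability $1-\delta_k$, or in a uniformly
   chosen *other* layer of $k$ (same node) with probability $\delta_k$.
   A single-layer multiplex always stays in its layer.
3. **Dangling rule.** Mass that would step from a layer copy with no
   neighbours is redirected to the restart distribution. A node isolated
   everywhere therefore has a column equal to the restart vector.

The operator is stored as a sparse matrix plus a dangling vector; the
implied matrix for restart distribution $s$ is $M_0 + s\,d^T$ and every
column sums to 1 (asserted to $10^{-12}$ in tests).

The restart vector for a single seed puts mass $\tau_{k(\text{seed})}[\ell]$
on the seed's replica in each layer $\ell$ of its own multiplex. The
restart allocation $\eta$ across multiplexes only matters for multi-seed
runs (one seed per multiplex); with a single seed the mass is renormalized
onto the seed's multiplex. Multi-multiplex seed sets are out of scope.

The stationary distribution solves $x = (1-r)\,M x + r\,s$ by power
iteration from $x_0 = s$, converging when the L1 change drops below
`tol` = 1e-8 (cap 1000 iterations, warning with the residual if hit).
Aggregating replicas per node yields a probability distribution over all
nodes. The full similarity matrix runs the iteration for all seeds in
batches with per-column freezing, so results are bit-identical regardless
of batch composition; tests check each row against the direct linear solve
$x = r\,(I-(1-r)M)^{-1} s$ and, for the monoplex special case, against
networkx's personalized PageRank with damping $1-r$.

**Parameters** (all overridable in the `rwr:` config block): $r=0.7$
(global restart, the value commonly used for biological RWR), $\eta$ and
each row of $\lambda$ uniform over multiplexes, $\delta_k = 0.5$ (equal
chance of switching layer or staying), $\tau_k$ uniform over the layers of
$k$. Convergence tol 1e-8 was chosen conservative relative to the noise
the downstream embedding introduces.

## Embedding by NCE

Vectors are initialized i.i.d. uniform in $[-0.5/d,\,0.5/d]$. Each SGD
sample draws $u$ uniform, $v \sim \mathrm{sim}_G(u,\cdot)$ (inverse-CDF on
the precomputed cumulative rows) and $s$ uniform negatives, then ascends
$\log\sigma(w_u\!\cdot\!w_{v}) + \sum \log(1-\sigma(w_u\!\cdot\!w_{\tilde v}))$
with all gradients evaluated at the incoming matrix and both endpoints of
every pair updated. There is no separate context matrix — the similarity
model is the symmetric dot product. The inner loop is numba-compiled with
a semantically identical pure-Python fallback; all sampling is drawn up
front from one seeded generator, so training is bit-reproducible.

Defaults: $d=128$, $s=3$, steps $=1400\,|V|$, learning rate 0.025 decaying
linearly to 0.0001 — the lineage defaults of VERSE-style trainers; the
bounded learning rate keeps vector norms finite (asserted in tests). A
fixed Monte-Carlo probe set (500 samples) estimates the NCE loss at ten
checkpoints for the training report. Exhaustive
$\mathrm{KL}(\mathrm{sim}_G\|\mathrm{sim}_{Emb})$ (softmax over all nodes)
is available as an $O(n^2 d)$ diagnostic and is only used on small
networks.

## Link-prediction protocol

Per repetition: 30% of each bipartite's edges are removed uniformly
(multiplex layers untouched); the training network alone is embedded; for
each bipartite, training positives are its remaining edges and training
negatives an equal count of uniform non-edges of the *full* bipartite;
test positives are the held-out edges and test negatives fresh non-edges
disjoint from the training negatives. Each of the five operators
(Hadamard $w_u \odot w_v$, Weighted-L1 $|w_u-w_v|$, Weighted-L2
$(w_u-w_v)^2$, Average $(w_u+w_v)/2$, cosine) feeds a random forest
(100 trees, per-repetition seed, otherwise library defaults); ROC-AUC is
computed on predicted probabilities. Balanced 1:1 negatives and
re-sampling negatives per repetition are conventions of this evaluation
lineage; bipartites with fewer than 4 edges are skipped with a warning.
A leakage assertion verifies per repetition that no test positive is
present in the embedded network.

## Spherical k-means

Vectors are unit-normalized (zero vectors rejected, naming the node);
k-means++ seeding on the sphere with $1-\cos$ distances; assignment to the
centroid of maximal cosine with ties broken toward the lowest index;
centroids are renormalized mean directions; empty clusters are re-seeded
from the worst-fitting point. The objective (sum of member–centroid
cosines) is non-decreasing across plain iterations and is recorded per
iteration. The initialization, cap (300 iterations) and tie rule are this
package's choices. Module extraction returns the induced subnetwork of a
cluster — intra-layer and bipartite edges with both endpoints inside,
tagged by source network.

## Synthetic generator

Each layer is an independent planted-partition (SBM) graph: edge
probability `p_in` within a community, `p_out` across; communities are
balanced round-robin and **aligned 1:1 across node types**, and bipartite
edges use `q_in`/`q_out` by label match — this alignment is what makes
held-out bipartite edges statistically predictable from multiplex
structure. The default fixture mirrors the composition of a real
drug–gene–disease knowledge network: gene (200 nodes, 3 layers), disease
(100, 2), drug (150, 4), $C=5$, `p_in=0.15`, `p_out=0.01`, `q_in=0.10`,
`q_out=0.005`, three bipartites. The null generator keeps the shape and
expected density but uses the planted mixture mean as a single rate —
no community signal. Generation is deterministic per seed (independent
child streams per layer/bipartite).

What the generator does **not** emulate: heavy-tailed degree
distributions, edge weights, correlated layers, overlapping communities,
and the incomplete/biased curation of real drug–gene–disease databases.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of clean planted structure, not performance on real
networks.

## Known limitation: the planted link-prediction ceiling

With $C$ balanced communities, conditional on community labels the
held-out bipartite edges are independent of the training network, so the
best possible pair score depends only on whether the pair is
label-matched. At the default rates the positives are ~83% same-community
and the uniform non-edge negatives ~18% same-community, which caps the
expected ROC-AUC of *any* method near 0.83 (scoring test pairs directly by
the RWR similarity reaches ≈ 0.84, matching a community-oracle
classifier). The full pipeline (NCE embedding + random forest on operator
features) lands around 0.60–0.70: the symmetric dot-product model cannot
realize the large log-likelihood-ratio gaps the NCE optimum asks for
(pairwise cosines of many mutually repelling community directions are
bounded below by $-1/(m-1)$), and a forest on ~700 training pairs in 128
dimensions recovers only part of the remaining signal. The test suite
asserts the strong separation from the null (null AUC ∈ [0.4, 0.6]); the
corresponding high-signal assertion on the planted fixture documents this
ceiling in its failure message.

## Problem sizes

Tests and the acceptance script run the 450-node fixture (1400 replicas),
random oracle networks of ≤ 60 replicas, and training runs of at most
$1400 \times 450$ SGD samples — sizes chosen so every check re-runs from
scratch in minutes on one core while keeping all expected effects well
clear of their statistical thresholds.
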