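"""Discover mixed gene/disease/drug modules with spherical k-means.

Embeddings are unit-normalized and clustered by cosine similarity.  On
the planted fixture, k = 5 clusters should recover the five aligned
communities across all three node types; each cluster's induced
subnetwork (intra-layer plus bipartite edges, tagged by source network)
is the module a biologist would inspect.
"""

from collections import Counter

from mplexembed import (
    RWRConfig,
    TrainParams,
    extract_cluster_module,
    generate_planted_network,
    benchmark_shape_spec,
    similarity_matrix,
    spherical_kmeans,
    train_embedding,
)

net, labels = generate_planted_network(benchmark_shape_spec(), seed=1)
sim = similarity_matrix(net, RWRConfig.defaults(net))
emb, _ = train_embedding(sim, TrainParams(seed=0))

assignment = spherical_kmeans(emb, k=5, seed=0)
print(f"objective (sum of member-centroid cosines): {assignment.objective:.2f}")

for c in range(5):
    members = assignment.members(c)
    types = Counter(n.split("::")[0] for n in members)
    communities = Counter(labels[n] for n in members)
    top = communities.most_common(1)[0]
    print(f"cluster {c}: {len(members):>3} nodes {dict(types)}; "
          f"{top[1]} of them from planted community {top[0]}")

module = extract_cluster_module(net, assignment, 0)
sources = Counter(tag for *_, tag in module.edges)
print(f"module 0 induced subnetwork: {len(module.nodes)} nodes, "
      f"{len(module.edges)} edges by source: {dict(sources)}")
# A clean recovery shows each cluster dominated by one planted community
# and containing genes, diseases AND drugs -- a mixed-type module.
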