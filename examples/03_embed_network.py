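"""Train node embeddings whose dot-product similarity approximates the
RWR similarity distribution.

Noise-contrastive estimation draws positive pairs (u, v) with v sampled
from sim_G(u, .) and contrasts each against s=3 uniform noise pairs; the
logistic discriminator's logit is the embedding dot product.  The probe
loss is the NCE objective estimated on a fixed Monte-Carlo probe set --
it should fall as the embedding absorbs the similarity structure.
"""

from mplexembed import (
    RWRConfig,
    TrainParams,
    generate_planted_network,
    benchmark_shape_spec,
    similarity_matrix,
    train_embedding,
    write_embeddings,
)

net, labels = generate_planted_network(benchmark_shape_spec(), seed=1)
sim = similarity_matrix(net, RWRConfig.defaults(net))

params = TrainParams(d=128, seed=0)  # steps default to 1400 per node
emb, report = train_embedding(sim, params)

print(f"embedded {emb.n_nodes} nodes in d={emb.dimension}")
print("probe NCE loss by checkpoint:")
for step, loss in zip(report.checkpoint_steps, report.probe_losses):
    print(f"  step {step:>7}: {loss:.4f}")

write_embeddings(emb, "scratch_embedding.txt")
print("wrote scratch_embedding.txt (word2vec-style text format)")
# A falling probe loss means sigma(w_u . w_v) increasingly separates
# similarity-sampled pairs from uniform noise pairs.
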