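import numpy as np
import pytest
from hypothesis import settings

from mplexembed import (
    LayerGraph,
    Multiplex,
    Bipartite,
    MultilayerNetwork,
    RWRConfig,
    benchmark_shape_spec,
    generate_planted_network,
)

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("suite")


def random_multilayer(rng: np.random.Generator, max_replicas: int = 60) -> MultilayerNetwork:
    """Small random multiplex-heterogeneous network for oracle tests.

    Sizes are drawn so the replica count (sum of n_k * L_k) stays small
    enough to materialize the transition operator densely.
    """
    while True:
        n_mult = int(rng.integers(1, 4))
        sizes = rng.integers(3, 7, size=n_mult)
        layer_counts = rng.integers(1, 4, size=n_mult)
        if int((sizes * layer_counts).sum()) <= max_replicas:
            break
    multiplexes = []
    for k in range(n_mult):
        n = int(sizes[k])
        ids = [f"m{k}::v{i}" for i in range(n)]
        layers = []
        for _ in range(int(layer_counts[k])):
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        edges.append((ids[i], ids[j], float(rng.uniform(0.5, 2.0))))
            layers.append(LayerGraph(edges=edges, directed=False))
        multiplexes.append(Multiplex(name=f"m{k}", node_ids=ids, layers=layers))
    bipartites = []
    for k in range(n_mult):
        for j in range(k + 1, n_mult):
            edges = []
            for u in multiplexes[k].node_ids:
                for v in multiplexes[j].node_ids:
                    if rng.random() < 0.3:
                        edges.append((u, v, 1.0))
            if edges:
                bipartites.append(
                    Bipartite(name=f"b{k}{j}", left=f"m{k}", right=f"m{j}", edges=edges)
                )
    net = MultilayerNetwork(multiplexes=multiplexes, bipartites=bipartites)
    if net.n_edges == 0:
        # guarantee at least one edge so the operator is defined
        ids = multiplexes[0].node_ids
        multiplexes[0].layers[0].edges.append((ids[0], ids[1], 1.0))
    return net


@pytest.fixture(scope="session")
def bench_net():
    """The default planted fixture: gene(200 nodes, 3 layers),
    disease(100, 2), drug(150, 4), C=5 aligned communities, 3 bipartites."""
    net, labels = generate_planted_network(benchmark_shape_spec(), seed=1)
    return net, labels


@pytest.fixture(scope="session")
def bench_cfg(bench_net):
    net, _ = bench_net
    return RWRConfig.defaults(net)


@pytest.fixture
def path_monoplex():
    """Single multiplex, single layer, undirected path a-b."""
    layer = LayerGraph(edges=[("m::a", "m::b", 1.0)], directed=False)
    m = Multiplex(name="m", node_ids=["m::a", "m::b"], layers=[layer])
    return MultilayerNetwork(multiplexes=[m])
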