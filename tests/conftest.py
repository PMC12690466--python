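"""Shared fixtures: small synthetic datasets sized for fast unit tests."""

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from esssubgraph import (
    GeneGraph,
    ModelConfig,
    SyntheticConfig,
    make_reference_dataset,
)

TINY = SyntheticConfig(
    n_nodes=300,
    n_edges=1_200,
    essential_fraction=0.10,
    hub_bias=1.0,
    n_samples=40,
    feature_effect_size=1.5,
    neighbor_correlation=0.3,
    n_lines=30,
    effect_separation=1.0,
    n_components=20,
)

FAST_MODEL = dict(hidden_dims=(16, 16, 16), batch_size=256, max_epochs=80)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 300-node analogue of the reference experiment, for fast training tests."""
    return make_reference_dataset(seed=11, config=TINY)


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(**FAST_MODEL)


@pytest.fixture
def path_graph():
    """a—b—c path."""
    return GeneGraph(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gene_graph(n, p, seed):
    """Erdős–Rényi helper used by oracle-equivalence tests."""
    import networkx as nx

    g = nx.gnp_random_graph(n, p, seed=seed)
    names = [f"g{i:02d}" for i in range(n)]
    return GeneGraph(names, [(names[a], names[b]) for a, b in g.edges])


def dense_reference_forward(params, graph, X, targets):
    """Brute-force layer-wise evaluation over full neighborhoods — no
    sampling machinery.  Independent oracle for the sampled forward pass."""
    h = X.copy()
    for W in params.layer_weights:
        new = np.zeros((graph.n_nodes, W.shape[0]))
        for i, name in enumerate(graph.nodes):
            nbrs = [graph.node_index[u] for u in graph.neighbors(name)]
            mean = h[nbrs].mean(axis=0) if nbrs else np.zeros(h.shape[1])
            new[i] = np.maximum(W @ np.concatenate([h[i], mean]), 0.0)
        h = new
    idx = [graph.node_index[t] for t in targets]
    return h[idx] @ params.output_weight + params.output_bias
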