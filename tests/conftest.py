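import numpy as np
import pandas as pd
import pytest

from pathcarc.enrichment import ExpressionMatrix
from pathcarc.pathways import PathwayNetwork, node_weights, pairwise_distances


@pytest.fixture
def chain_net():
    """Three-gene signalling chain A -> B -> C (C is the terminus)."""
    return PathwayNetwork("chain", "mouse", frozenset("ABC"), frozenset([("A", "B"), ("B", "C")]))


@pytest.fixture
def chain_weights(chain_net):
    return node_weights(chain_net, lam=1.0)


@pytest.fixture
def chain_dist(chain_net):
    return pairwise_distances(chain_net)


def random_network(rng, n_nodes, p_edge=0.35, directed=True, pathway_id="R", prefix=""):
    """Random pathway graph with string node ids (no self-loops)."""
    names = [f"{prefix}n{i}" for i in range(n_nodes)]
    edges = set()
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < p_edge:
                if directed:
                    edges.add((names[i], names[j]))
                elif i < j:
                    edges.add((names[i], names[j]))
                    edges.add((names[j], names[i]))
    return PathwayNetwork(pathway_id, "mouse", frozenset(names), frozenset(edges))


def make_expression(rng, n_genes=30, n_treat=3, n_control=3, shift_genes=(), shift=0.0):
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"t{i}" for i in range(n_treat)] + [f"c{i}" for i in range(n_control)]
    values = rng.normal(7.0, 1.0, size=(n_genes, n_treat + n_control))
    for g in shift_genes:
        values[genes.index(g), :n_treat] += shift
    groups = pd.Series(["treated"] * n_treat + ["control"] * n_control, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), groups)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
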