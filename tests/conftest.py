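import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from netprio import GeneSet, GeneSetPartition, InteractionNetwork, generate_network
from netprio.topo_features import build_feature_matrix


@pytest.fixture
def path3():
    """P3: A - B - C."""
    return InteractionNetwork([("A", "B"), ("B", "C")])


@pytest.fixture
def star5():
    """K1,4: center 'hub' with four leaves."""
    return InteractionNetwork([("hub", f"L{i}") for i in range(4)])


@pytest.fixture(scope="session")
def planted():
    """Small planted benchmark shared across the suite (session-scoped)."""
    net, truth = generate_network(
        n_background=400, n_disease=30, n_hidden=15,
        attach_m=3, module_p=0.3, cross_p=0.01, seed=42,
    )
    return net, truth


@pytest.fixture(scope="session")
def planted_matrix(planted):
    net, truth = planted
    return build_feature_matrix(net, sorted(net.nodes), truth.seed_disease)


@pytest.fixture(scope="session")
def planted_partition(planted):
    net, truth = planted
    nodes = net.nodes
    pos = truth.seed_disease.members
    test = truth.hidden_disease.members
    return GeneSetPartition(
        positive=GeneSet("positive", pos),
        negative=GeneSet("negative", nodes - pos - test),
        test=GeneSet("test", test),
    )


def random_graph(rng: np.random.Generator, n: int, p: float):
    """Edge-list Erdos-Renyi graph as plain python structures."""
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges
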