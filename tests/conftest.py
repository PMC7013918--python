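import itertools

import networkx as nx
import pytest

from gliomanet.simulate import GeneratorConfig, generate


def make_graph(edges, isolated=(), **graph_attrs):
    """Small undirected test graph; nodes are strings."""
    g = nx.Graph(**graph_attrs)
    g.add_edges_from(edges)
    g.add_nodes_from(isolated)
    return g


def clique(prefix, m):
    nodes = [f"{prefix}{i}" for i in range(m)]
    return list(itertools.combinations(nodes, 2)), nodes


@pytest.fixture(scope="session")
def default_dataset():
    """One in-memory synthetic universe shared by read-only tests."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def dataset_paths(default_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synthetic")
    return default_dataset.write(outdir)
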