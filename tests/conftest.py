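import numpy as np
import networkx as nx
import pytest

from benthicnet.transect import (
    BenthicNetwork,
    TransectRecord,
    network_from_record,
    run_length_encode,
    build_network,
)


@pytest.fixture
def worked_record() -> TransectRecord:
    """The canonical worked example: AAAAABBBBCCAA."""
    return TransectRecord(
        survey_id="T1", site="S1", depth=7.0, aspect="photophilous",
        codes=tuple("AAAAABBBBCCAA"),
    )


@pytest.fixture
def worked_network(worked_record) -> BenthicNetwork:
    return network_from_record(worked_record)


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from("ABC")
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "A")])
    for node, (size, count) in zip("ABC", [(1, 1), (2, 1), (3, 2)]):
        g.nodes[node]["size"] = size
        g.nodes[node]["count"] = count
    return g


def random_attr_graph(n: int, p: float, seed: int) -> nx.Graph:
    """A random simple graph with size/count/phylum vertex attributes."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, lambda k: f"v{k:02d}")
    for node in g.nodes:
        g.nodes[node]["size"] = float(rng.integers(1, 50))
        g.nodes[node]["count"] = float(rng.integers(1, 12))
        g.nodes[node]["phylum"] = ["P", "Q", "R"][int(rng.integers(3))]
    return g
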