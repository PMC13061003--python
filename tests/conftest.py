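import warnings

import networkx as nx
import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from netpharm.networks import DrugTargetNetwork, GeneSet


@pytest.fixture
def path_graph():
    """A - B - C - D."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D")])
    return g


@pytest.fixture
def two_component_graph():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("X", "Y")])
    return g


@pytest.fixture
def toy_dtn():
    dtn = DrugTargetNetwork()
    for drug, gene in [("d1", "A"), ("d1", "C"), ("d2", "D"), ("d3", "B")]:
        dtn.pairs.add((drug, gene))
        dtn.mean_pactivity[(drug, gene)] = 6.0
    return dtn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gene_set(name, genes):
    return GeneSet(name=name, genes=frozenset(genes))
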