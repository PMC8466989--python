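import networkx as nx
import numpy as np
import pytest

from cryonet.io_model import (
    CooccurrenceNetwork,
    SampleMetadata,
    TaxonomyTable,
    TraitsTable,
    ZOTUTable,
)

import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [5, 0, 2, 7],
            [1, 1, 1, 1],
            [0, 9, 0, 3],
        ]
    )
    return ZOTUTable(["t1", "t2", "t3"], ["s1", "s2", "s3", "s4"], counts)


@pytest.fixture
def small_metadata():
    frame = pd.DataFrame(
        {
            "horizon": ["topsoil", "topsoil", "cryoOM", "subsoil"],
            "site": [1, 2, 1, 2],
            "moisture": [70.0, 55.0, 50.0, 30.0],
            "pH": [6.0, 6.5, 7.0, 5.8],
            "DOC": [700.0, 400.0, 300.0, 200.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return SampleMetadata(frame)


@pytest.fixture
def small_taxonomy():
    return TaxonomyTable(
        {
            "t1": ("Fungi", "Mortierellomycota", "", "", "", "Mortierella", "Mortierella antarctica"),
            "t2": ("Fungi",),
            "t3": ("Fungi", "Ascomycota", "", "", "", "Penicillium", "unidentified"),
        }
    )


@pytest.fixture
def small_traits():
    return TraitsTable(
        {
            "Mortierella": ("Soil_Saprotroph", "saprotroph"),
            "Penicillium": ("unspecified_Saprotroph", "saprotroph"),
        }
    )


def make_network(edges):
    """Build a CooccurrenceNetwork from (u, v, rho) triples."""
    g = nx.Graph()
    for u, v, rho in edges:
        g.add_edge(u, v, rho=rho, sign="+" if rho >= 0 else "-")
    return CooccurrenceNetwork(g)


@pytest.fixture
def triangle():
    return make_network([("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.7)])


@pytest.fixture
def path3():
    return make_network([("a", "b", 0.9), ("b", "c", 0.8)])


@pytest.fixture
def two_cliques():
    """Two K4 cliques joined by a single bridge edge (8 nodes, 13 edges)."""
    edges = []
    for group in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((group[i], group[j], 0.8))
    edges.append(("a1", "b1", 0.7))
    return make_network(edges)


def random_zotu_table(rng, n_taxa=8, n_samples=6, max_count=50):
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    counts[:, counts.sum(axis=0) == 0] += 1  # no all-zero samples
    taxa = [f"t{i}" for i in range(n_taxa)]
    samples = [f"s{j}" for j in range(n_samples)]
    return ZOTUTable(taxa, samples, counts)
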