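import networkx as nx
import pytest

from revpheno import load_knowledge_base, load_ontology


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture(scope="session")
def ontology():
    return load_ontology()


@pytest.fixture()
def toy_dag():
    """Tiny is-a graph in obonet orientation (edges child -> parent)."""
    g = nx.MultiDiGraph()
    edges = [
        ("HP:A1", "HP:ROOT"),
        ("HP:A2", "HP:ROOT"),
        ("HP:A11", "HP:A1"),
        ("HP:SHARED", "HP:A1"),
        ("HP:SHARED", "HP:A2"),  # diamond: shared descendant of A1 and A2
        ("HP:LEAF", "HP:ROOT"),
    ]
    g.add_edges_from(edges)
    return g
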