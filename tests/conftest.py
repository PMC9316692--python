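import networkx as nx
import pandas as pd
import pytest

from relapsegrn.containers import CountMatrix, DEGSet, RegulatoryDB
from relapsegrn.ontology import GoDag


@pytest.fixture
def tiny_counts() -> CountMatrix:
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 5, 100],
            "s2": [12, 1, 7, 90],
            "s3": [40, 0, 6, 110],
            "s4": [38, 2, 8, 95],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene"),
    )
    groups = pd.Series(
        ["A", "A", "B", "B"], index=["s1", "s2", "s3", "s4"], name="group"
    )
    return CountMatrix(counts=counts, groups=groups)


@pytest.fixture
def small_dag() -> GoDag:
    """Hand-built DAG:

        root
        / \\
       a   b
      / \\   \\
     c   d   e
     and f -part_of-> a
    """
    g = nx.DiGraph()
    for child, parent, rel in [
        ("a", "root", "is_a"),
        ("b", "root", "is_a"),
        ("c", "a", "is_a"),
        ("d", "a", "is_a"),
        ("e", "b", "is_a"),
        ("f", "a", "part_of"),
    ]:
        g.add_edge(child, parent, relation=rel)
    for node in g:
        g.nodes[node]["namespace"] = "biological_process"
    return GoDag(graph=g)


@pytest.fixture
def tiny_regdb() -> RegulatoryDB:
    df = pd.DataFrame(
        [
            ("m1", "g1", "mirna", "gene", "experimental"),
            ("m1", "g2", "mirna", "gene", "experimental"),
            ("g1", "g2", "tf", "gene", "experimental"),
            ("m2", "g1", "mirna", "gene", "predicted"),
            ("g3", "m1", "tf", "mirna", "experimental"),
        ],
        columns=["source", "target", "source_type", "target_type", "evidence"],
    )
    return RegulatoryDB(interactions=df)


@pytest.fixture
def degs_g123() -> DEGSet:
    return DEGSet(
        genes={"g1", "g2", "g3"}, direction={"g1": 1, "g2": -1, "g3": 1}
    )
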