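import networkx as nx
import pytest

from slinet.ortholog_map import IdBridge, OrthologCluster


@pytest.fixture
def fbxw7_fixture():
    """Tiny ortholog resource bridging MET30 -> FBXW7 plus distractors.

    Contains the one-to-one MET30/FBXW7 cluster, a one-to-many cluster
    (CDC53 -> two human cullins) and a 2x2 cluster, with consistent
    gene<->protein bridges. CDC4 (the FBXW7 synonym) deliberately has no
    human entry anywhere.
    """
    clusters = [
        OrthologCluster("c_met30", (("P_MET30", 1.0),), (("Q_FBXW7", 1.0),)),
        OrthologCluster(
            "c_cul", (("P_CDC53", 1.0),), (("Q_CUL1", 1.0), ("Q_CUL2", 0.6))
        ),
        OrthologCluster(
            "c_2x2",
            (("P_YTWOA", 1.0), ("P_YTWOB", 0.8)),
            (("Q_HTWOA", 1.0), ("Q_HTWOB", 0.7)),
        ),
    ]
    bridge = IdBridge(
        yeast_gene_to_protein={
            "MET30": "P_MET30",
            "CDC53": "P_CDC53",
            "YTWOA": "P_YTWOA",
            "YTWOB": "P_YTWOB",
        },
        human_protein_to_gene={
            "Q_FBXW7": "FBXW7",
            "Q_CUL1": "CUL1",
            "Q_CUL2": "CUL2",
            "Q_HTWOA": "HTWOA",
            "Q_HTWOB": "HTWOB",
        },
    )
    return clusters, bridge


@pytest.fixture
def star_network():
    """Star graph: center C with leaves L1..L4, SL edge attributes attached."""
    net = nx.Graph()
    for i, leaf in enumerate(["L1", "L2", "L3", "L4"]):
        net.add_edge("C", leaf, epsilon=-0.3 - 0.01 * i, p_value=0.01)
    return net
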