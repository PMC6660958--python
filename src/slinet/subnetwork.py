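"""Disease-specific subnetwork: down-regulated seed genes plus incident SL edges.

Given the humanized SL network and the list of genes found down-regulated in
a tumor cohort, the disease subnetwork keeps every network edge with at
least one down-regulated ("seed") endpoint. Seed-seed edges are retained
and counted once; seeds with no incident edge in the parent network are
dropped (the parent is a simple graph with no isolated nodes). The non-seed
endpoints are the SL "partners" — the druggable side of each predicted pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

__all__ = ["DiseaseSubnetwork", "extract_subnetwork", "seed_degree"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseaseSubnetwork:
    """Seed genes, their SL partners, and the induced incident-edge graph."""

    graph: nx.Graph
    seeds: frozenset[str]
    partners: frozenset[str]

    def __post_init__(self) -> None:
        if self.seeds & self.partners:
            raise ValueError("seeds and partners must be disjoint")
        if set(self.graph.nodes) != self.seeds | self.partners:
            raise ValueError("graph nodes must equal seeds | partners")
        for u, v in self.graph.edges:
            if u not in self.seeds and v not in self.seeds:
                raise ValueError(f"edge ({u}, {v}) has no seed endpoint")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def extract_subnetwork(net: nx.Graph, down_genes: Iterable[str]) -> DiseaseSubnetwork:
    """Extract seeds (down genes present in the network) and all incident edges.

    Down genes absent from the network are silently ignored (logged). Each
    qualifying edge is counted once, including seed-seed edges, and carries
    the attributes it had in the parent network. Seeds left without any
    incident edge are excluded from the node set.
    """
    down = set(down_genes)
    absent = down - set(net.nodes)
    if absent:
        logger.info("extract_subnetwork: %d down genes absent from network", len(absent))
    candidates = down & set(net.nodes)
    sub = nx.Graph()
    for u, v, attrs in net.edges(data=True):
        if u in candidates or v in candidates:
            sub.add_edge(u, v, **attrs)
    seeds = frozenset(n for n in sub.nodes if n in candidates)
    partners = frozenset(sub.nodes) - seeds
    return DiseaseSubnetwork(graph=sub, seeds=seeds, partners=partners)


def seed_degree(sub: DiseaseSubnetwork, gene: str) -> tuple[int, list[str]]:
    """Degree and sorted neighbor list of a gene within the subnetwork."""
    if gene not in sub.graph:
        raise KeyError(f"gene {gene!r} not in subnetwork")
    neighbors = sorted(sub.graph.neighbors(gene))
    return len(neighbors), neighbors
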