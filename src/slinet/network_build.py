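"""Build the humanized synthetic-lethal interaction network.

Yeast double-mutant (SGA) screens assign each gene pair a quantitative
genetic-interaction score epsilon and a significance P-value. Strong negative
interactions (epsilon < -0.2, P < 0.05, both strict) are treated as
synthetic-lethal-like. Each surviving record's endpoints are translated to
human gene symbols through the strict one-to-one ortholog map; records with
any unresolvable endpoint are dropped, and reciprocal screens (the same pair
measured with query/array roles swapped) collapse to a single undirected
edge.

The result is a simple undirected graph of predicted human synthetic-lethal
interactions, with edge attributes recording the supporting yeast
measurement.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional

import math

import networkx as nx

__all__ = [
    "GeneticInteractionRecord",
    "filter_interactions",
    "humanize_network",
    "network_summary",
    "annotate_go_slim",
    "category_pair_counts",
]

logger = logging.getLogger(__name__)

#: Default strong-negative-interaction cutoffs (both strict).
EPS_MAX = -0.2
P_MAX = 0.05

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GeneticInteractionRecord:
    """One yeast screen measurement: gene pair, epsilon score, P-value."""

    query_gene: str
    array_gene: str
    epsilon: float
    p_value: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "query_gene", self.query_gene.strip().upper())
        object.__setattr__(self, "array_gene", self.array_gene.strip().upper())
        if self.query_gene == self.array_gene:
            raise ValueError(f"self-interaction record for {self.query_gene!r}")
        if not math.isfinite(self.epsilon):
            raise ValueError("epsilon must be finite")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")

    @property
    def canonical_pair(self) -> tuple[str, str]:
        """Lexicographically sorted gene pair (the undirected edge key)."""
        a, b = sorted((self.query_gene, self.array_gene))
        return a, b


def filter_interactions(
    records: Iterable[GeneticInteractionRecord],
    eps_max: float = EPS_MAX,
    p_max: float = P_MAX,
) -> list[GeneticInteractionRecord]:
    """Keep records with epsilon strictly below eps_max AND P strictly below p_max.

    Both comparisons are strict: a record exactly at either boundary is
    dropped. Input order is preserved.
    """
    if not (math.isfinite(eps_max) and math.isfinite(p_max)):
        raise ValueError("thresholds must be finite")
    return [r for r in records if r.epsilon < eps_max and r.p_value < p_max]


def humanize_network(
    records: Iterable[GeneticInteractionRecord],
    translator: Callable[[str], Optional[str]],
) -> nx.Graph:
    """Translate record endpoints to human symbols and emit the deduplicated graph.

    Records with any unresolvable endpoint are dropped, as are pairs whose
    two endpoints translate to one and the same symbol (self-loop after
    humanization). Duplicate and reciprocal records for one human pair
    collapse to a single undirected edge that keeps the attributes of the
    record with the most negative epsilon (ties broken by smaller P, then
    first occurrence), so the attribute choice is independent of record
    order up to exact ties.

    Edge attributes: ``epsilon``, ``p_value``,
    ``source_yeast_pair`` (query, array of the retained record).
    """
    net: nx.Graph = nx.Graph()
    n_unresolved = 0
    n_self = 0
    for rec in records:
        a = translator(rec.query_gene)
        b = translator(rec.array_gene)
        if a is None or b is None:
            n_unresolved += 1
            continue
        if a == b:
            n_self += 1
            continue
        u, v = sorted((a, b))
        attrs = {
            "epsilon": rec.epsilon,
            "p_value": rec.p_value,
            "source_yeast_pair": (rec.query_gene, rec.array_gene),
        }
        if net.has_edge(u, v):
            cur = net.edges[u, v]
            if (rec.epsilon, rec.p_value) < (cur["epsilon"], cur["p_value"]):
                cur.update(attrs)
        else:
            net.add_edge(u, v, **attrs)
    logger.info(
        "humanize_network: %d edges, %d nodes (%d records unresolved, %d self-loops dropped)",
        net.number_of_edges(), net.number_of_nodes(), n_unresolved, n_self,
    )
    return net


def network_summary(net: nx.Graph) -> dict:
    """Node/edge counts, degree distribution and per-category tallies.

    ``degree_distribution`` maps degree -> number of nodes with that degree.
    ``go_slim_counts`` is present only when at least one node carries a
    ``go_slim`` annotation.
    """
    summary: dict = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "degree_distribution": dict(Counter(d for _, d in net.degree())),
    }
    categories = nx.get_node_attributes(net, "go_slim")
    if categories:
        summary["go_slim_counts"] = dict(Counter(categories.values()))
    return summary


def annotate_go_slim(
    net: nx.Graph,
    annotation_table: Mapping[str, str] | Iterable[tuple[str, str]],
) -> nx.Graph:
    """Attach a GO-slim category label to every node (in place).

    The table maps gene symbol -> category. Genes absent from the table are
    labeled ``"unassigned"``. An iterable of pairs may repeat a gene only
    with an identical label; conflicting duplicates raise ``ValueError``.
    """
    if isinstance(annotation_table, Mapping):
        table = dict(annotation_table)
    else:
        table = {}
        for gene, category in annotation_table:
            if gene in table and table[gene] != category:
                raise ValueError(
                    f"conflicting GO-slim annotations for {gene!r}: "
                    f"{table[gene]!r} vs {category!r}"
                )
            table[gene] = category
    for node in net.nodes:
        net.nodes[node]["go_slim"] = table.get(node, UNASSIGNED)
    return net


def category_pair_counts(net: nx.Graph) -> dict[tuple[str, str], int]:
    """Edge counts between GO-slim category pairs (sorted category-pair keys).

    Requires :func:`annotate_go_slim` to have run; unannotated nodes count
    as ``"unassigned"``. Within-category edges land on the diagonal key
    ``(c, c)``.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for u, v in net.edges:
        cu = net.nodes[u].get("go_slim", UNASSIGNED)
        cv = net.nodes[v].get("go_slim", UNASSIGNED)
        counts[tuple(sorted((cu, cv)))] += 1
    return dict(counts)
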