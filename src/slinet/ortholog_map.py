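"""Strict one-to-one yeast-human ortholog mapping and identifier translation.

Ortholog resources (InParanoid-style clusters) group yeast and human proteins
that descend from a single ancestral gene. A cluster may contain several
members per species (inparalogs). To translate a yeast genetic-interaction
network into human gene space without ambiguity, only clusters with exactly
one yeast and exactly one human member are used; everything else
(one-to-many, many-to-one, many-to-many) is discarded.

Translation of a yeast gene to a human gene symbol runs in three stages:
yeast gene name -> yeast protein accession (UniProt-style bridge), yeast
protein -> human protein (the one-to-one ortholog map), human protein ->
human gene symbol (second bridge). Failure at any stage yields ``None``
rather than an error: most yeast genes simply have no unambiguous human
counterpart.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional

__all__ = [
    "OrthologCluster",
    "IdBridge",
    "OneToOneMap",
    "Translator",
    "filter_one_to_one",
    "translate_gene",
    "query_orthologs",
]


@dataclass(frozen=True)
class OrthologCluster:
    """One ortholog cluster: yeast and human members with inparalog scores.

    Scores are confidences in [0, 1] that a member belongs to the cluster's
    seed lineage. They are carried for inspection but do not affect
    one-to-one filtering, which is a multiplicity criterion only.
    """

    cluster_id: str
    yeast_members: tuple[tuple[str, float], ...]
    human_members: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.yeast_members or not self.human_members:
            raise ValueError(
                f"cluster {self.cluster_id!r}: both species sides must be non-empty"
            )
        for acc, score in (*self.yeast_members, *self.human_members):
            if not acc:
                raise ValueError(f"cluster {self.cluster_id!r}: empty protein accession")
            if not (0.0 <= score <= 1.0):
                raise ValueError(
                    f"cluster {self.cluster_id!r}: inparalog score {score} outside [0, 1]"
                )

    @property
    def is_one_to_one(self) -> bool:
        return len(self.yeast_members) == 1 and len(self.human_members) == 1


@dataclass
class IdBridge:
    """Gene<->protein identifier bridges for the two translation end stages.

    Both maps are functions: a yeast gene resolves to at most one protein
    accession and a human protein to at most one gene symbol. Readers that
    encounter conflicting duplicates must drop the key before constructing
    the bridge (strictness: an ambiguous identifier is unresolvable).
    """

    yeast_gene_to_protein: dict[str, str]
    human_protein_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        for mapping, name in (
            (self.yeast_gene_to_protein, "yeast_gene_to_protein"),
            (self.human_protein_to_gene, "human_protein_to_gene"),
        ):
            for k, v in mapping.items():
                if not k or not v:
                    raise ValueError(f"{name}: empty identifier in ({k!r}, {v!r})")

    # Inverse (possibly one-to-many) views, used by symbol-level queries.
    def human_gene_to_proteins(self) -> dict[str, list[str]]:
        inv: dict[str, list[str]] = {}
        for prot, gene in self.human_protein_to_gene.items():
            inv.setdefault(gene, []).append(prot)
        return inv

    def yeast_protein_to_genes(self) -> dict[str, list[str]]:
        inv: dict[str, list[str]] = {}
        for gene, prot in self.yeast_gene_to_protein.items():
            inv.setdefault(prot, []).append(gene)
        return inv


@dataclass(frozen=True)
class OneToOneMap:
    """Bijection between yeast and human protein accessions."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        yeast = [y for y, _ in self.pairs]
        human = [h for _, h in self.pairs]
        if len(set(yeast)) != len(yeast) or len(set(human)) != len(human):
            raise ValueError("one-to-one map is not a bijection")

    @property
    def yeast_to_human(self) -> dict[str, str]:
        return {y: h for y, h in self.pairs}

    @property
    def human_to_yeast(self) -> dict[str, str]:
        return {h: y for y, h in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def filter_one_to_one(clusters: Iterable[OrthologCluster]) -> OneToOneMap:
    """Reduce clusters to the strict one-to-one ortholog map.

    Retains exactly the clusters with a single member on each side. As a
    defensive second pass, any protein that appears in more than one retained
    cluster is dropped together with its pairs, so the result is always a
    bijection. Empty input yields an empty map.
    """
    candidates: list[tuple[str, str]] = []
    for cluster in clusters:
        if cluster.is_one_to_one:
            candidates.append((cluster.yeast_members[0][0], cluster.human_members[0][0]))
    yeast_counts = Counter(y for y, _ in candidates)
    human_counts = Counter(h for _, h in candidates)
    pairs = frozenset(
        (y, h)
        for y, h in candidates
        if yeast_counts[y] == 1 and human_counts[h] == 1
    )
    return OneToOneMap(pairs=pairs)


def translate_gene(
    yeast_gene: str, bridge: IdBridge, mapping: OneToOneMap
) -> Optional[str]:
    """Translate a yeast systematic gene name to a human gene symbol.

    Three stages: yeast gene -> yeast protein (bridge), yeast protein ->
    human protein (one-to-one map), human protein -> human gene symbol
    (bridge). Returns ``None`` whenever any stage fails to resolve;
    unresolvable is a value, not an error. Yeast names are upper-cased
    before lookup; human symbols are returned verbatim.
    """
    yeast_protein = bridge.yeast_gene_to_protein.get(yeast_gene.strip().upper())
    if yeast_protein is None:
        return None
    human_protein = mapping.yeast_to_human.get(yeast_protein)
    if human_protein is None:
        return None
    return bridge.human_protein_to_gene.get(human_protein)


@dataclass(frozen=True)
class Translator:
    """Callable bundling a bridge and a one-to-one map: yeast gene -> human symbol."""

    bridge: IdBridge
    mapping: OneToOneMap

    def __call__(self, yeast_gene: str) -> Optional[str]:
        return translate_gene(yeast_gene, self.bridge, self.mapping)


Direction = Literal["yeast_to_human", "human_to_yeast"]


def query_orthologs(
    symbol: str,
    direction: Direction,
    clusters: Iterable[OrthologCluster],
    bridge: IdBridge,
) -> list[str]:
    """List all counterpart gene symbols reachable through any cluster.

    Unlike :func:`filter_one_to_one`, this query is *not* restricted to
    one-to-one clusters: it reports every counterpart, which is how one
    verifies that a gene of interest has no additional ortholog hiding in a
    multi-member cluster. Returns a sorted, de-duplicated list; an empty
    list when no cluster contains the symbol. Proteins lacking a gene-symbol
    bridge entry are reported by accession.
    """
    if direction not in ("yeast_to_human", "human_to_yeast"):
        raise ValueError(f"unknown direction {direction!r}")

    if direction == "yeast_to_human":
        query_proteins = set()
        prot = bridge.yeast_gene_to_protein.get(symbol.strip().upper())
        if prot is not None:
            query_proteins.add(prot)
        out_bridge: Mapping[str, str] = bridge.human_protein_to_gene

        def side(c: OrthologCluster) -> tuple[tuple[str, float], ...]:
            return c.yeast_members

        def other(c: OrthologCluster) -> tuple[tuple[str, float], ...]:
            return c.human_members

    else:
        inv = bridge.human_gene_to_proteins()
        query_proteins = set(inv.get(symbol.strip(), []))
        yeast_inv = bridge.yeast_protein_to_genes()
        out_bridge = {
            prot: genes[0] for prot, genes in yeast_inv.items() if len(genes) == 1
        }

        def side(c: OrthologCluster) -> tuple[tuple[str, float], ...]:
            return c.human_members

        def other(c: OrthologCluster) -> tuple[tuple[str, float], ...]:
            return c.yeast_members

    if not query_proteins:
        return []
    hits: set[str] = set()
    for cluster in clusters:
        if any(acc in query_proteins for acc, _ in side(cluster)):
            for acc, _ in other(cluster):
                hits.add(out_bridge.get(acc, acc))
    return sorted(hits)
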