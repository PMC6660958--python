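"""Overlap between two undirected synthetic-lethal edge sets.

Two prediction networks are compared purely as sets of unordered gene-symbol
pairs (scores and provenance are ignored). Before comparison an external
edge set can be harmonized to the same ortholog universe by dropping edges
with any endpoint lacking a strict one-to-one yeast ortholog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Tuple

__all__ = [
    "ONE_TO_ONE",
    "OverlapResult",
    "canonical_edges",
    "restrict_to_one_to_one",
    "edge_overlap",
]

logger = logging.getLogger(__name__)

#: Multiplicity label marking a gene with an unambiguous yeast ortholog.
ONE_TO_ONE = "one-to-one"

Edge = Tuple[str, str]


def canonical_edges(edges: Iterable[Edge]) -> frozenset[Edge]:
    """Canonicalize: upper-case symbols, sorted pairs, self-pairs dropped."""
    out = set()
    for a, b in edges:
        a, b = a.strip().upper(), b.strip().upper()
        if a == b:
            continue
        out.add((min(a, b), max(a, b)))
    return frozenset(out)


def restrict_to_one_to_one(
    edges: Iterable[Edge], multiplicity_table: Mapping[str, str]
) -> frozenset[Edge]:
    """Keep edges whose both endpoints are labeled one-to-one.

    ``multiplicity_table`` maps gene symbol -> ortholog multiplicity label
    (e.g. "one-to-one", "one-to-many"). A gene missing from the table is
    treated as non-one-to-one and logged.
    """
    table = {g.strip().upper(): label for g, label in multiplicity_table.items()}
    kept = set()
    missing = set()
    for a, b in canonical_edges(edges):
        la, lb = table.get(a), table.get(b)
        if la is None:
            missing.add(a)
        if lb is None:
            missing.add(b)
        if la == ONE_TO_ONE and lb == ONE_TO_ONE:
            kept.add((a, b))
    if missing:
        logger.info(
            "restrict_to_one_to_one: %d genes missing from multiplicity table", len(missing)
        )
    return frozenset(kept)


@dataclass(frozen=True)
class OverlapResult:
    """Edge-set overlap summary between networks A and B."""

    n_a: int
    n_b: int
    shared: frozenset[Edge]
    jaccard: float
    fraction_of_a: float
    fraction_of_b: float

    def __post_init__(self) -> None:
        if len(self.shared) > min(self.n_a, self.n_b):
            raise ValueError("shared edges exceed the smaller set")


def edge_overlap(set_a: Iterable[Edge], set_b: Iterable[Edge]) -> OverlapResult:
    """Exact intersection of two canonicalized undirected edge sets.

    Symmetric in its arguments and insensitive to pair orientation and
    symbol case.
    """
    a = canonical_edges(set_a)
    b = canonical_edges(set_b)
    shared = a & b
    union = a | b
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        shared=shared,
        jaccard=len(shared) / len(union) if union else 0.0,
        fraction_of_a=len(shared) / len(a) if a else 0.0,
        fraction_of_b=len(shared) / len(b) if b else 0.0,
    )
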