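"""Seed-restricted, nonredundant ontology views (subset extraction).

A view is the slice of the materialized closure induced by a seed term set
and a chosen relation set, reduced to a minimal edge set that still entails
exactly the same seed-restricted relationships.  This mirrors the
subset-extraction workflow used to publish simplified application
ontologies: the full reference ontology may relate the seed terms only
through intermediate terms the application does not need, but the closure
already contains the induced direct relationships, so restriction + reduction
yields a compact graph (e.g. renal corpuscle -> nephron -> kidney without
the redundant renal corpuscle -> kidney grandparent edge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .closure import ClosureGraph, Triple, saturate
from .model import SUBCLASS, Curie, Predicate, PropertyDecl, pred_str

logger = logging.getLogger("ontoview")


@dataclass
class ViewGraph:
    seed_terms: frozenset[Curie]
    edges: set[Triple] = field(default_factory=set)
    relations_used: frozenset = frozenset()
    source_digest: str = ""
    #: property declarations carried along so the view can be re-materialized
    properties: dict[Curie, PropertyDecl] = field(default_factory=dict)
    missing_seeds: frozenset[Curie] = frozenset()

    def predicates(self) -> set[Predicate]:
        return {p for (_, p, _) in self.edges}

    def to_tsv(self) -> str:
        lines = ["subject\tpredicate\tobject"]
        for (s, p, o) in sorted(
            self.edges, key=lambda t: (str(t[0]), pred_str(t[1]), str(t[2]))
        ):
            lines.append(f"{s}\t{pred_str(p)}\t{o}")
        return "\n".join(lines) + "\n"


def restrict_closure(
    closure: ClosureGraph,
    seed_terms: set[Curie],
    relations: set,
) -> set[Triple]:
    """Closure triples with both endpoints in the seeds and an allowed predicate."""
    return {
        (s, p, o)
        for (s, p, o) in closure.triples
        if p in relations and s in seed_terms and o in seed_terms
    }


def extract_view(
    closure: ClosureGraph,
    seed_terms: Iterable[Curie],
    relations: Iterable,
) -> ViewGraph:
    """Seed-restricted, reduced view of a closure.

    Seeds absent from the closure are retained as isolated nodes (the view
    must contain every requested term) and reported with a warning.
    """
    seeds = set(seed_terms)
    rels = set(relations)
    if not seeds:
        raise ValueError("extract_view requires a nonempty seed set")
    if not rels:
        raise ValueError("extract_view requires a nonempty relation set")
    known = {s for (s, _, _) in closure.triples} | {o for (_, _, o) in closure.triples}
    missing = frozenset(s for s in seeds if s not in known)
    if missing:
        logger.warning(
            "%d seed terms absent from the closure kept as isolated nodes: %s",
            len(missing), ", ".join(sorted(map(str, missing))),
        )
    restricted = restrict_closure(closure, seeds, rels)
    reduced = reduce_view(restricted, closure.properties)
    return ViewGraph(
        seed_terms=frozenset(seeds),
        edges=reduced,
        relations_used=frozenset(rels),
        source_digest=closure.source_fragment_digest,
        properties=dict(closure.properties),
        missing_seeds=missing,
    )


def reduce_view(
    edges: set[Triple],
    property_decls: dict[Curie, PropertyDecl],
) -> set[Triple]:
    """Remove edges re-derivable from the remaining ones under the rules.

    Edges are visited in lexicographic (subject, predicate, object) order;
    an edge is removed when the saturation of the remaining edges still
    contains it.  Because derivability is monotone in the edge set, a single
    pass yields a minimal set, and removal of derivable edges never changes
    the overall closure — so the result entails exactly what the input did.
    Cross-relation derivations (through subproperty lifting and chains)
    count, making this stronger than a per-relation transitive reduction.
    """
    kept = set(edges)
    for edge in sorted(edges, key=lambda t: (str(t[0]), pred_str(t[1]), str(t[2]))):
        candidate = kept - {edge}
        if edge in saturate(candidate, property_decls):
            kept = candidate
    return kept


@dataclass(frozen=True)
class ViewStats:
    term_count: int
    relationship_count: int
    relation_type_count: int

    def as_dict(self) -> dict:
        return {
            "term_count": self.term_count,
            "relationship_count": self.relationship_count,
            "relation_type_count": self.relation_type_count,
        }


def view_stats(view: Optional[ViewGraph]) -> ViewStats:
    """Summary counts: terms, relationships, distinct relation types."""
    if view is None or (not view.seed_terms and not view.edges):
        return ViewStats(0, 0, 0)
    return ViewStats(
        term_count=len(view.seed_terms),
        relationship_count=len(view.edges),
        relation_type_count=len(view.predicates()),
    )
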