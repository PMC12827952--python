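"""Materialization of the inference closure ("redundant graph").

The closure makes every entailed classification and existential relationship
explicit as a simple triple, so that validation is a set-membership test
rather than a reasoning task.  Six rules are applied to a least fixpoint:

* R1  transitivity of SubClassOf:          A⊑B, B⊑C        ⊢ A⊑C
* R2  classification (left):               A⊑B, B ∃R C      ⊢ A ∃R C
* R3  classification (right):              A ∃R B, B⊑C      ⊢ A ∃R C
* R4  property-hierarchy lifting:          A ∃S B, S ⊑* R   ⊢ A ∃R B
* R5  transitive properties:               A ∃R B, B ∃R C   ⊢ A ∃R C
* R6  2-step property chains (S∘T ⊑ R):    A ∃S B, B ∃T C   ⊢ A ∃R C

where ⊑* is the reflexive-transitive closure of the subPropertyOf hierarchy.
Reflexive SubClassOf edges are suppressed.  No inverse-property rule is
applied: ``A part_of some B`` never yields ``B has_part some A`` (that is not
an OWL entailment for class-level existentials), so has_part validates only
where asserted or derived directly.

:func:`materialize` is the production implementation (semi-naive, indexed);
:func:`naive_fixpoint_oracle` is an intentionally simple quadratic re-scan
kept as an independent correctness oracle for small inputs.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import (
    SUBCLASS,
    Curie,
    OntologyFragment,
    Predicate,
    PropertyDecl,
    pred_str,
)

logger = logging.getLogger("ontoview")

Triple = tuple[Curie, Predicate, Curie]


@dataclass(frozen=True)
class ClosureEdge:
    subject: Curie
    predicate: Predicate
    object: Curie
    asserted: bool

    @property
    def triple(self) -> Triple:
        return (self.subject, self.predicate, self.object)


@dataclass
class ClosureGraph:
    """Fixpoint of the inference rules over a fragment's axioms.

    ``triples`` maps each entailed (subject, predicate, object) to its
    ``asserted`` flag (True iff the triple is verbatim an input axiom).
    ``property_closure`` maps each property to its reflexive-transitive set
    of super-properties.
    """

    triples: dict[Triple, bool] = field(default_factory=dict)
    property_closure: dict[Curie, set[Curie]] = field(default_factory=dict)
    properties: dict[Curie, PropertyDecl] = field(default_factory=dict)
    source_fragment_digest: str = ""

    @property
    def edges(self) -> set[ClosureEdge]:
        return {ClosureEdge(s, p, o, a) for (s, p, o), a in self.triples.items()}

    def triple_set(self) -> set[Triple]:
        return set(self.triples)

    def asserted_triples(self) -> set[Triple]:
        return {t for t, a in self.triples.items() if a}

    def to_tsv(self) -> str:
        """Export edges as TSV (subject, predicate, object, asserted)."""
        lines = ["subject\tpredicate\tobject\tasserted"]
        for (s, p, o) in sorted(
            self.triples, key=lambda t: (str(t[0]), pred_str(t[1]), str(t[2]))
        ):
            lines.append(f"{s}\t{pred_str(p)}\t{o}\t{str(self.triples[(s, p, o)]).lower()}")
        return "\n".join(lines) + "\n"


def property_hierarchy_closure(
    properties: dict[Curie, PropertyDecl]
) -> dict[Curie, set[Curie]]:
    """Reflexive-transitive closure of subPropertyOf (cycle-tolerant)."""
    out: dict[Curie, set[Curie]] = {}
    for prop in properties:
        supers = {prop}
        stack = [prop]
        while stack:
            cur = stack.pop()
            decl = properties.get(cur)
            if decl is None:
                continue
            for parent in decl.parents:
                if parent not in supers:
                    supers.add(parent)
                    stack.append(parent)
        out[prop] = supers
    return out


def saturate(
    triples: Iterable[Triple],
    properties: dict[Curie, PropertyDecl],
) -> set[Triple]:
    """Least fixpoint of R1-R6 over ``triples`` (worklist, indexed joins).

    Reflexive SubClassOf triples are dropped on derivation.
    """
    prop_sup = property_hierarchy_closure(properties)
    transitive = {c for c, p in properties.items() if p.transitive}
    # chains indexed by first member: S -> [(T, R), ...]
    chains_by_first: dict[Curie, list[tuple[Curie, Curie]]] = {}
    for r, decl in properties.items():
        for s, t in decl.chains:
            chains_by_first.setdefault(s, []).append((t, r))

    closed: set[Triple] = set()
    by_subject: dict[Curie, set[Triple]] = {}
    by_object: dict[Curie, set[Triple]] = {}
    work: deque[Triple] = deque()

    def add(t: Triple) -> None:
        s, p, o = t
        if p == SUBCLASS and s == o:
            return
        if t in closed:
            return
        closed.add(t)
        by_subject.setdefault(s, set()).add(t)
        by_object.setdefault(o, set()).add(t)
        work.append(t)

    for t in triples:
        add(t)

    while work:
        s, p, o = work.popleft()
        derived: list[Triple] = []
        if p == SUBCLASS:
            # R1 right: (s⊑o), (o⊑c) ⊢ (s⊑c); R2: (s⊑o), (o R c) ⊢ (s R c)
            for (_, p2, o2) in by_subject.get(o, ()):
                derived.append((s, p2, o2))
            # R1 left: (a⊑s) with (s⊑o) ⊢ (a⊑o)
            for (s2, p2, _) in by_object.get(s, ()):
                if p2 == SUBCLASS:
                    derived.append((s2, SUBCLASS, o))
                else:
                    # R3: (s2 R s), (s⊑o) ⊢ (s2 R o)
                    derived.append((s2, p2, o))
        else:
            assert isinstance(p, Curie)
            # R4: lift through every strict super-property
            for sup in prop_sup.get(p, {p}):
                if sup != p:
                    derived.append((s, sup, o))
            # R3: (s p o), (o ⊑ c) ⊢ (s p c)
            for (_, p2, o2) in by_subject.get(o, ()):
                if p2 == SUBCLASS:
                    derived.append((s, p, o2))
                elif p2 == p and p in transitive:
                    # R5 right: (s p o), (o p o2) ⊢ (s p o2)
                    derived.append((s, p, o2))
                # R6 with this triple as first member
                for (t_prop, r_prop) in chains_by_first.get(p, ()):
                    if p2 == t_prop:
                        derived.append((s, r_prop, o2))
            # R2: (a ⊑ s) ⊢ (a p o); R5 left; R6 with this triple as second member
            for (s2, p2, _) in by_object.get(s, ()):
                if p2 == SUBCLASS:
                    derived.append((s2, p, o))
                elif p2 == p and p in transitive:
                    derived.append((s2, p, o))
                if isinstance(p2, Curie):
                    for (t_prop, r_prop) in chains_by_first.get(p2, ()):
                        if p == t_prop:
                            derived.append((s2, r_prop, o))
        for t in derived:
            add(t)
    return closed


def materialize(fragment: OntologyFragment) -> ClosureGraph:
    """Materialize the closure of a fragment (see module docstring).

    Cyclic inputs are tolerated (the fixpoint stays finite); SubClassOf
    cycles are reported with a warning because terms in a cycle entail each
    other and usually indicate curation errors worth surfacing downstream.
    """
    fragment.validate()
    asserted = fragment.axiom_triples()
    closed = saturate(asserted, fragment.properties)
    graph = ClosureGraph(
        triples={t: (t in asserted) for t in closed},
        property_closure=property_hierarchy_closure(fragment.properties),
        properties=dict(fragment.properties),
        source_fragment_digest=fragment.digest(),
    )
    _warn_subclass_cycles(graph)
    return graph


def _warn_subclass_cycles(graph: ClosureGraph) -> None:
    cycles = sorted(
        {
            tuple(sorted((str(s), str(o))))
            for (s, p, o) in graph.triples
            if p == SUBCLASS and (o, SUBCLASS, s) in graph.triples
        }
    )
    if cycles:
        logger.warning("SubClassOf cycles detected: %s", ", ".join(f"{a}~{b}" for a, b in cycles))


def naive_fixpoint_oracle(fragment: OntologyFragment, guard: int = 100) -> ClosureGraph:
    """Brute-force closure: re-scan all triple pairs until no rule fires.

    Deliberately unindexed and structured rule-by-rule so it shares no logic
    with :func:`saturate`; guarded to small fragments.
    """
    if len(fragment.terms) > guard:
        raise ValueError(f"oracle guard exceeded: {len(fragment.terms)} terms > {guard}")
    fragment.validate()
    asserted = fragment.axiom_triples()
    prop_sup = property_hierarchy_closure(fragment.properties)
    transitive = {c for c, p in fragment.properties.items() if p.transitive}
    chain_rules = [
        (s, t, r)
        for r, decl in fragment.properties.items()
        for (s, t) in decl.chains
    ]

    closed = {t for t in asserted if not (t[1] == SUBCLASS and t[0] == t[2])}
    changed = True
    while changed:
        changed = False
        new: set[Triple] = set()
        for (a, p1, b) in closed:
            # R4
            if isinstance(p1, Curie):
                for sup in prop_sup.get(p1, set()):
                    new.add((a, sup, b))
            for (c, p2, d) in closed:
                if b != c:
                    continue
                if p1 == SUBCLASS and p2 == SUBCLASS:
                    new.add((a, SUBCLASS, d))          # R1
                elif p1 == SUBCLASS and p2 != SUBCLASS:
                    new.add((a, p2, d))                # R2
                elif p1 != SUBCLASS and p2 == SUBCLASS:
                    new.add((a, p1, d))                # R3
                else:
                    if p1 == p2 and p1 in transitive:
                        new.add((a, p1, d))            # R5
                    for (s, t, r) in chain_rules:      # R6
                        if p1 == s and p2 == t:
                            new.add((a, r, d))
        new = {t for t in new if not (t[1] == SUBCLASS and t[0] == t[2])}
        if not new <= closed:
            closed |= new
            changed = True

    graph = ClosureGraph(
        triples={t: (t in asserted) for t in closed},
        property_closure=prop_sup,
        properties=dict(fragment.properties),
        source_fragment_digest=fragment.digest(),
    )
    return graph


def entails(
    closure: ClosureGraph,
    subject: Curie,
    predicate: Predicate,
    obj: Curie,
) -> bool:
    """Membership test on the closure.

    Reflexive queries (subject == object) are false by convention.  Unknown
    predicates warn and return False rather than raising: curated tables may
    use relations absent from the loaded fragment.
    """
    if subject == obj:
        return False
    if predicate != SUBCLASS and isinstance(predicate, Curie):
        if predicate not in closure.properties:
            logger.warning("entails: unknown predicate %s", predicate)
            return False
    return (subject, predicate, obj) in closure.triples
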