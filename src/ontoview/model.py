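"""Core domain model: CURIEs, term/property declarations, axioms, fragments.

An :class:`OntologyFragment` is the validator's reference knowledge: a small,
self-contained slice of an anatomy/cell-type ontology (e.g. Uberon + CL)
holding term declarations, object-property declarations (with subPropertyOf
parents, transitivity flags and 2-step property chains) and two kinds of
logical axiom:

* ``SubClassOf``  — ``A`` is a kind of ``B``;
* ``SomeValuesRel`` — the existential-restriction pattern ``A SubClassOf
  (R some B)``, read "every A bears relation R to some B" (e.g. every
  podocyte is part_of some glomerular visceral epithelium).

Two interchange formats are supported: OBO-graph JSON (the standard OBO
exchange format, nodes + edges) and a three-column triple TSV dialect with
``#``-prefixed directive rows for property declarations, used for fixtures.
"""

from __future__ import annotations

import functools
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

logger = logging.getLogger("ontoview")

#: Reserved predicate token for classification edges.  It contains no colon,
#: so it can never collide with a serialized CURIE.
SUBCLASS = "subClassOf"

_OBO_IRI = re.compile(r"^https?://purl\.obolibrary\.org/obo/([A-Za-z][\w.]*?)_(\w+)$")
_CURIE_RE = re.compile(r"^([^\s:]+):([^\s:]+)$")


@functools.total_ordering
@dataclass(frozen=True)
class Curie:
    """Compact identifier ``prefix:local_id`` (e.g. ``UBERON:0002113``).

    Equality and ordering are case-sensitive lexicographic on the serialized
    form; this ordering is used everywhere a deterministic tie-break is
    needed.
    """

    prefix: str
    local_id: str

    def __post_init__(self) -> None:
        if not self.prefix or not self.local_id:
            raise ValueError(f"CURIE parts must be nonempty: {self.prefix!r}:{self.local_id!r}")
        if ":" in self.prefix:
            raise ValueError(f"CURIE prefix may not contain a colon: {self.prefix!r}")

    @classmethod
    def parse(cls, text: str) -> "Curie":
        m = _CURIE_RE.match(text.strip())
        if m is None:
            raise ValueError(f"not a CURIE: {text!r}")
        return cls(m.group(1), m.group(2))

    @classmethod
    def from_iri(cls, iri: str) -> Optional["Curie"]:
        """Map an OBO PURL (``.../obo/UBERON_0002113``) to a CURIE, else None."""
        m = _OBO_IRI.match(iri)
        if m is None:
            return None
        return cls(m.group(1), m.group(2))

    def to_iri(self, base: str = "http://purl.obolibrary.org/obo/") -> str:
        return f"{base}{self.prefix}_{self.local_id}"

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    def __lt__(self, other: object) -> bool:
        if isinstance(other, Curie):
            return str(self) < str(other)
        if isinstance(other, str):
            return str(self) < other
        return NotImplemented


#: A closure/axiom predicate: an object-property CURIE or the SUBCLASS token.
Predicate = Union[Curie, str]


def pred_str(p: Predicate) -> str:
    """Serialized form of a predicate (CURIE string or ``subClassOf``)."""
    return p if isinstance(p, str) else str(p)


def parse_pred(text: str) -> Predicate:
    return SUBCLASS if text == SUBCLASS else Curie.parse(text)


@dataclass
class TermDecl:
    id: Curie
    label: Optional[str] = None
    synonyms: list[str] = field(default_factory=list)


@dataclass
class PropertyDecl:
    """Object-property declaration with the axioms that drive inference.

    ``chains`` holds 2-step property chains: ``(S, T)`` in
    ``chains`` of property ``R`` means ``S o T SubPropertyOf R``.
    """

    id: Curie
    label: Optional[str] = None
    parents: list[Curie] = field(default_factory=list)
    transitive: bool = False
    chains: list[tuple[Curie, Curie]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(p == self.id for p in self.parents):
            raise ValueError(f"property {self.id} lists itself as a parent")


@dataclass(frozen=True)
class Axiom:
    """A SubClassOf or existential-restriction axiom as a simple triple.

    ``pred`` is :data:`SUBCLASS` for classification axioms and a property
    CURIE for existential restrictions (``sub SubClassOf pred some obj``).
    """

    sub: Curie
    pred: Predicate
    obj: Curie
    provenance: str = ""

    @property
    def is_subclass(self) -> bool:
        return self.pred == SUBCLASS

    @property
    def triple(self) -> tuple[Curie, Predicate, Curie]:
        return (self.sub, self.pred, self.obj)


def subclass_axiom(sub: Curie, sup: Curie, provenance: str = "") -> Axiom:
    if sub == sup:
        raise ValueError(f"asserted SubClassOf must not be reflexive: {sub}")
    return Axiom(sub, SUBCLASS, sup, provenance)


def some_values_axiom(sub: Curie, prop: Curie, filler: Curie, provenance: str = "") -> Axiom:
    return Axiom(sub, prop, filler, provenance)


@dataclass
class OntologyFragment:
    """Terms + properties + axioms; the unit the reasoner materializes."""

    terms: dict[Curie, TermDecl] = field(default_factory=dict)
    properties: dict[Curie, PropertyDecl] = field(default_factory=dict)
    axioms: list[Axiom] = field(default_factory=list)

    # -- construction helpers -------------------------------------------------

    def ensure_term(self, curie: Curie, label: Optional[str] = None) -> TermDecl:
        decl = self.terms.get(curie)
        if decl is None:
            decl = TermDecl(curie, label)
            self.terms[curie] = decl
        elif label and not decl.label:
            decl.label = label
        return decl

    def ensure_property(self, curie: Curie, label: Optional[str] = None) -> PropertyDecl:
        decl = self.properties.get(curie)
        if decl is None:
            decl = PropertyDecl(curie, label)
            self.properties[curie] = decl
        elif label and not decl.label:
            decl.label = label
        return decl

    def add_axiom(self, axiom: Axiom) -> None:
        """Add an axiom, auto-declaring referenced identifiers with a warning."""
        if axiom.is_subclass:
            if axiom.sub == axiom.obj:
                raise ValueError(f"asserted SubClassOf must not be reflexive: {axiom.sub}")
        else:
            assert isinstance(axiom.pred, Curie)
            if axiom.pred not in self.properties:
                logger.warning("auto-declaring undeclared property %s", axiom.pred)
                self.ensure_property(axiom.pred)
        for endpoint in (axiom.sub, axiom.obj):
            if endpoint not in self.terms and endpoint not in self.properties:
                logger.warning("auto-declaring undeclared term %s", endpoint)
                self.ensure_term(endpoint)
        self.axioms.append(axiom)

    # -- views ----------------------------------------------------------------

    def axiom_triples(self) -> set[tuple[Curie, Predicate, Curie]]:
        return {a.triple for a in self.axioms}

    def label_of(self, curie: Curie) -> Optional[str]:
        decl = self.terms.get(curie) or self.properties.get(curie)
        return decl.label if decl else None

    def labels(self) -> dict[Curie, str]:
        out: dict[Curie, str] = {}
        for c, t in self.terms.items():
            if t.label:
                out[c] = t.label
        for c, p in self.properties.items():
            if p.label:
                out[c] = p.label
        return out

    def digest(self) -> str:
        """Content hash over the canonicalized fragment (order-independent)."""
        h = hashlib.sha256()
        for line in sorted(
            f"{s}\t{pred_str(p)}\t{o}" for (s, p, o) in self.axiom_triples()
        ):
            h.update(line.encode())
            h.update(b"\n")
        for c in sorted(self.properties, key=str):
            p = self.properties[c]
            h.update(
                (
                    f"#{c}|{sorted(map(str, p.parents))}|{p.transitive}|"
                    f"{sorted((str(s), str(t)) for s, t in p.chains)}\n"
                ).encode()
            )
        return h.hexdigest()

    def validate(self) -> None:
        """Assert the fragment invariants; raise ValueError on violation."""
        for c, p in self.properties.items():
            if c != p.id:
                raise ValueError(f"property keyed {c} declares id {p.id}")
            for s, t in p.chains:
                for member in (s, t):
                    if member not in self.properties:
                        raise ValueError(f"chain member {member} of {c} is undeclared")
        for a in self.axioms:
            if not a.is_subclass and a.pred not in self.properties:
                raise ValueError(f"axiom predicate {a.pred} is undeclared")
            for endpoint in (a.sub, a.obj):
                if endpoint not in self.terms and endpoint not in self.properties:
                    raise ValueError(f"axiom references undeclared {endpoint}")


# ---------------------------------------------------------------------------
# OBO-graph JSON
# ---------------------------------------------------------------------------

#: Default predicate map for OBO-graph edges.  The right-hand CURIEs are the
#: relations the validation profiles exercise: part_of, has_part, overlaps,
#: connected_to, develops_from, has_developmental_contribution_from.
DEFAULT_PREDICATE_MAP: dict[str, Curie] = {}
for _c in ("BFO:0000050", "BFO:0000051", "RO:0002131", "RO:0002170",
           "RO:0002202", "RO:0002254"):
    _cur = Curie.parse(_c)
    DEFAULT_PREDICATE_MAP[_c] = _cur
    DEFAULT_PREDICATE_MAP[_cur.to_iri()] = _cur
del _c, _cur


def load_obograph(
    source: str,
    predicate_map: Optional[Mapping[str, Curie]] = None,
    strict: bool = False,
) -> OntologyFragment:
    """Read an OBO-graph JSON document into a fragment.

    Nodes of type CLASS become terms, ``is_a`` edges become SubClassOf, other
    edges become existential restrictions with the predicate mapped through
    ``predicate_map`` (IRI or CURIE keys).  Unknown predicates are skipped
    with a warning (raised in ``strict`` mode); non-class nodes and logical
    definitions are ignored with a counted warning.
    """
    pmap = dict(DEFAULT_PREDICATE_MAP)
    if predicate_map:
        pmap.update(predicate_map)
    try:
        doc = json.loads(source)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed OBO-graph JSON at byte offset {exc.pos}: {exc.msg}") from exc

    frag = OntologyFragment()
    ignored_nodes = 0
    skipped_edges = 0
    for gi, graph in enumerate(doc.get("graphs", [])):
        for node in graph.get("nodes", []):
            curie = _node_curie(node.get("id", ""))
            if curie is None:
                ignored_nodes += 1
                continue
            ntype = node.get("type", "CLASS")
            if ntype == "PROPERTY":
                frag.ensure_property(curie, node.get("lbl"))
            elif ntype == "CLASS":
                decl = frag.ensure_term(curie, node.get("lbl"))
                syns = [
                    s.get("val")
                    for s in node.get("meta", {}).get("synonyms", [])
                    if s.get("val")
                ]
                decl.synonyms.extend(s for s in syns if s not in decl.synonyms)
            else:
                ignored_nodes += 1
        for ei, edge in enumerate(graph.get("edges", [])):
            sub = _node_curie(edge.get("sub", ""))
            obj = _node_curie(edge.get("obj", ""))
            pred = edge.get("pred", "")
            prov = f"obograph:graph{gi}:edge{ei}"
            if sub is None or obj is None:
                skipped_edges += 1
                continue
            if pred in ("is_a", "rdfs:subClassOf", SUBCLASS):
                if sub == obj:
                    skipped_edges += 1
                    continue
                frag.add_axiom(subclass_axiom(sub, obj, prov))
                continue
            prop = pmap.get(pred)
            if prop is None and (c := Curie.from_iri(pred)) is not None:
                prop = pmap.get(str(c))
            if prop is None:
                msg = f"no predicate mapping for {pred!r}; edge skipped"
                if strict:
                    raise ValueError(msg)
                logger.warning(msg)
                skipped_edges += 1
                continue
            frag.ensure_property(prop)
            frag.add_axiom(some_values_axiom(sub, prop, obj, prov))
    if ignored_nodes or skipped_edges:
        logger.warning(
            "load_obograph ignored %d nodes and skipped %d edges",
            ignored_nodes, skipped_edges,
        )
    return frag


def _node_curie(ident: str) -> Optional[Curie]:
    if not ident:
        return None
    curie = Curie.from_iri(ident)
    if curie is not None:
        return curie
    try:
        return Curie.parse(ident)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Triple TSV dialect
# ---------------------------------------------------------------------------

def load_triple_tsv(source: str, provenance: str = "tsv") -> OntologyFragment:
    """Read the triple TSV dialect.

    Data rows are ``subject <TAB> predicate <TAB> object``; a predicate of
    ``subClassOf`` yields a SubClassOf axiom, any other (CURIE) predicate an
    existential restriction.  Directive rows::

        #prop <P> subPropertyOf <Q>
        #prop <P> transitive
        #prop <P> chain <S> <T>
        #label <curie> <text ...>

    populate property declarations and labels.  Malformed rows raise with the
    1-based line number.
    """
    frag = OntologyFragment()
    deferred_labels: list[tuple[Curie, str]] = []
    data_rows: list[tuple[int, str, str, str]] = []

    for lineno, raw in enumerate(source.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            _parse_directive(frag, line, lineno, deferred_labels)
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated columns, got {len(cols)}")
        data_rows.append((lineno, *[c.strip() for c in cols]))

    # chain members must be declared; check after all directives are read
    for c, p in frag.properties.items():
        for s, t in p.chains:
            for member in (s, t):
                if member not in frag.properties:
                    raise ValueError(f"chain member {member} of property {c} is undeclared")

    # labels declare their subjects up front so data rows don't warn about
    # undeclared terms; property labels attach to the property declaration
    for curie, text in deferred_labels:
        if curie in frag.properties:
            frag.properties[curie].label = frag.properties[curie].label or text
        else:
            frag.ensure_term(curie, text)

    for lineno, s, p, o in data_rows:
        try:
            sub, obj = Curie.parse(s), Curie.parse(o)
            prov = f"{provenance}:{lineno}"
            if p == SUBCLASS:
                frag.add_axiom(subclass_axiom(sub, obj, prov))
            else:
                frag.add_axiom(some_values_axiom(sub, Curie.parse(p), obj, prov))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return frag


def _parse_directive(
    frag: OntologyFragment,
    line: str,
    lineno: int,
    deferred_labels: list[tuple[Curie, str]],
) -> None:
    tokens = line.split()
    if not tokens:
        return
    if tokens[0] == "#prop":
        if len(tokens) < 3:
            raise ValueError(f"line {lineno}: malformed #prop directive")
        prop = frag.ensure_property(Curie.parse(tokens[1]))
        verb = tokens[2]
        if verb == "subPropertyOf" and len(tokens) == 4:
            parent = Curie.parse(tokens[3])
            if parent == prop.id:
                raise ValueError(f"line {lineno}: property {prop.id} cannot be its own parent")
            frag.ensure_property(parent)
            if parent not in prop.parents:
                prop.parents.append(parent)
        elif verb == "transitive" and len(tokens) == 3:
            prop.transitive = True
        elif verb == "declare" and len(tokens) == 3:
            pass  # ensure_property above already declared it
        elif verb == "chain" and len(tokens) == 5:
            chain = (Curie.parse(tokens[3]), Curie.parse(tokens[4]))
            if chain not in prop.chains:
                prop.chains.append(chain)
        else:
            raise ValueError(f"line {lineno}: malformed #prop directive: {line!r}")
    elif tokens[0] == "#label":
        if len(tokens) < 3:
            raise ValueError(f"line {lineno}: malformed #label directive")
        deferred_labels.append((Curie.parse(tokens[1]), " ".join(tokens[2:])))
    # other comment lines are ignored


def write_triple_tsv(frag: OntologyFragment) -> str:
    """Serialize a fragment to the triple TSV dialect (stable ordering)."""
    lines: list[str] = []
    for c in sorted(frag.properties, key=str):
        p = frag.properties[c]
        if not p.parents and not p.transitive and not p.chains:
            lines.append(f"#prop {c} declare")
        for parent in sorted(p.parents, key=str):
            lines.append(f"#prop {c} subPropertyOf {parent}")
        if p.transitive:
            lines.append(f"#prop {c} transitive")
        for s, t in sorted(p.chains, key=lambda st: (str(st[0]), str(st[1]))):
            lines.append(f"#prop {c} chain {s} {t}")
        if p.label:
            lines.append(f"#label {c} {p.label}")
    for c in sorted(frag.terms, key=str):
        t = frag.terms[c]
        if t.label:
            lines.append(f"#label {c} {t.label}")
    for triple in sorted(
        frag.axiom_triples(), key=lambda t: (str(t[0]), pred_str(t[1]), str(t[2]))
    ):
        lines.append(f"{triple[0]}\t{pred_str(triple[1])}\t{triple[2]}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

def merge_fragments(fragments: Iterable[OntologyFragment]) -> OntologyFragment:
    """Union of terms, properties and axioms across fragments.

    Conflicting labels keep the first occurrence (warned); duplicate axioms
    are dropped; conflicting property characteristics (transitive vs not,
    once both are asserted) are an error.
    """
    out = OntologyFragment()
    transitive_seen: dict[Curie, bool] = {}
    seen_triples: set[tuple[Curie, Predicate, Curie]] = set()
    for frag in fragments:
        for c, t in frag.terms.items():
            decl = out.terms.get(c)
            if decl is None:
                out.terms[c] = TermDecl(c, t.label, list(t.synonyms))
            else:
                if t.label and decl.label and t.label != decl.label:
                    logger.warning(
                        "conflicting labels for %s: keeping %r, ignoring %r",
                        c, decl.label, t.label,
                    )
                elif t.label and not decl.label:
                    decl.label = t.label
                decl.synonyms.extend(s for s in t.synonyms if s not in decl.synonyms)
        for c, p in frag.properties.items():
            if c in transitive_seen and transitive_seen[c] != p.transitive:
                raise ValueError(f"conflicting transitivity declarations for property {c}")
            transitive_seen[c] = p.transitive if c not in transitive_seen else (
                transitive_seen[c] or p.transitive
            )
            decl = out.properties.get(c)
            if decl is None:
                out.properties[c] = PropertyDecl(
                    c, p.label, list(p.parents), p.transitive, list(p.chains)
                )
            else:
                if p.label and decl.label and p.label != decl.label:
                    logger.warning(
                        "conflicting labels for property %s: keeping %r", c, decl.label
                    )
                elif p.label and not decl.label:
                    decl.label = p.label
                decl.parents.extend(q for q in p.parents if q not in decl.parents)
                decl.chains.extend(ch for ch in p.chains if ch not in decl.chains)
        for a in frag.axioms:
            if a.triple not in seen_triples:
                seen_triples.add(a.triple)
                out.axioms.append(a)
    return out
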