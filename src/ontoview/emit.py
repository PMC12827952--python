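"""Serialization of validation outcomes and views: OWL, CSV report, DOT.

The OWL output follows the application-ontology pattern: every *valid* (or
suggested) relationship becomes a logical axiom — a plain SubClassOf for
classification matches, otherwise a subclass-of-existential-restriction
(``subject SubClassOf (property some object)``) — carrying axiom-level
annotations for validation status, date and source table.  Every candidate,
valid or not, is additionally written as a simple annotation-property triple
using its declared curation relation (ccf_part_of, ccf_located_in, ...), so
the originally curated graph is preserved verbatim without feeding the
logical axiomatization (a non-validated duple must never trigger
inference).

All emitters are pure functions of their inputs and config; the validation
date is injected, never read from the clock here.
"""

from __future__ import annotations

import io
import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL

from .model import SUBCLASS, Curie, Predicate, pred_str
from .tables import CandidateTriple
from .validate import SUGGESTED, VALID, ValidationOutcome
from .views import ViewGraph

OBO = "http://purl.obolibrary.org/obo/"


@dataclass
class OwlEmissionConfig:
    ontology_iri: str = "http://purl.org/ccf/validated.owl"
    ccf_annotation_base: str = "http://purl.org/ccf/"
    validation_date: str = "1970-01-01"
    status_vocab: dict = field(
        default_factory=lambda: {VALID: "validated", SUGGESTED: "suggested"}
    )
    source_table: str = ""

    def __post_init__(self) -> None:
        if not self.ccf_annotation_base.endswith(("/", "#")):
            raise ValueError("ccf_annotation_base must end with '/' or '#'")


def _term_iri(curie: Curie) -> URIRef:
    return URIRef(curie.to_iri(OBO))


def _pred_iri(pred: Predicate) -> URIRef:
    if pred == SUBCLASS:
        return RDFS.subClassOf
    assert isinstance(pred, Curie)
    return _term_iri(pred)


def write_owl(
    outcomes: Sequence[ValidationOutcome] = (),
    view: Optional[ViewGraph] = None,
    config: Optional[OwlEmissionConfig] = None,
    labels: Optional[dict[Curie, str]] = None,
) -> str:
    """Serialize outcomes (and optionally a view) to Turtle.

    Logical-axiom count equals the number of valid + suggested outcomes plus
    view edges; annotation-triple count equals the number of candidates.
    """
    config = config or OwlEmissionConfig()
    labels = labels or {}
    ccf = Namespace(config.ccf_annotation_base)
    g = Graph()
    g.bind("owl", OWL)
    g.bind("obo", OBO)
    g.bind("ccf", ccf)
    ont = URIRef(config.ontology_iri)
    g.add((ont, RDF.type, OWL.Ontology))

    used_props: set[Curie] = set()
    used_ann: set[str] = set()

    def add_label(curie: Curie) -> None:
        lbl = labels.get(curie)
        if lbl:
            node = _term_iri(curie)
            if (node, RDFS.label, None) not in g:
                g.add((node, RDFS.label, Literal(lbl)))

    def add_logical(sub: Curie, pred: Predicate, obj: Curie,
                    status: str, annotate: bool = True) -> None:
        s_node = _term_iri(sub)
        if pred == SUBCLASS:
            target: Union[URIRef, BNode] = _term_iri(obj)
        else:
            assert isinstance(pred, Curie)
            used_props.add(pred)
            target = BNode()
            g.add((target, RDF.type, OWL.Restriction))
            g.add((target, OWL.onProperty, _pred_iri(pred)))
            g.add((target, OWL.someValuesFrom, _term_iri(obj)))
        g.add((s_node, RDFS.subClassOf, target))
        add_label(sub)
        add_label(obj)
        if annotate:
            ax = BNode()
            g.add((ax, RDF.type, OWL.Axiom))
            g.add((ax, OWL.annotatedSource, s_node))
            g.add((ax, OWL.annotatedProperty, RDFS.subClassOf))
            g.add((ax, OWL.annotatedTarget, target))
            g.add((ax, ccf["validation_status"], Literal(status)))
            g.add((ax, ccf["validation_date"], Literal(config.validation_date)))
            if config.source_table:
                g.add((ax, ccf["source_table"], Literal(config.source_table)))

    for outcome in outcomes:
        cand = outcome.candidate
        if cand.subject.id is None or cand.object.id is None:
            continue
        if outcome.status == VALID:
            assert outcome.matched_check is not None
            add_logical(
                cand.subject.id,
                outcome.matched_check.property,
                cand.object.id,
                config.status_vocab.get(VALID, VALID),
            )
        elif outcome.status == SUGGESTED:
            assert outcome.suggestion is not None
            sug = outcome.suggestion
            if sug.swap:
                add_logical(sug.target, sug.property, cand.subject.id,
                            config.status_vocab.get(SUGGESTED, SUGGESTED))
            else:
                add_logical(cand.subject.id, sug.property, sug.target,
                            config.status_vocab.get(SUGGESTED, SUGGESTED))
        # every candidate keeps its curated relation as an annotation triple
        try:
            ann = ccf[cand.declared_relation]
        except Exception as exc:  # pragma: no cover - config guards this
            raise ValueError(
                f"cannot serialize annotation for candidate "
                f"{cand.subject.id} -> {cand.object.id}: {exc}"
            ) from exc
        used_ann.add(cand.declared_relation)
        g.add((_term_iri(cand.subject.id), ann, _term_iri(cand.object.id)))
        add_label(cand.subject.id)
        add_label(cand.object.id)

    if view is not None:
        for (s, p, o) in sorted(
            view.edges, key=lambda t: (str(t[0]), pred_str(t[1]), str(t[2]))
        ):
            add_logical(s, p, o, "view", annotate=False)

    for prop in sorted(used_props, key=str):
        g.add((_pred_iri(prop), RDF.type, OWL.ObjectProperty))
    for token in sorted(used_ann):
        g.add((ccf[token], RDF.type, OWL.AnnotationProperty))

    return g.serialize(format="turtle")


def count_logical_axioms(turtle: str) -> int:
    """Logical axioms in an emitted document (existential + named-subclass).

    Used by tests/post-hoc checks: counts rdfs:subClassOf triples whose
    object is a restriction or a named class.
    """
    g = Graph()
    g.parse(data=turtle, format="turtle")
    return sum(1 for _ in g.triples((None, RDFS.subClassOf, None)))


def count_annotation_triples(turtle: str, base: str = "http://purl.org/ccf/") -> int:
    g = Graph()
    g.parse(data=turtle, format="turtle")
    ann_props = {
        s for s in g.subjects(RDF.type, OWL.AnnotationProperty) if str(s).startswith(base)
    }
    return sum(1 for s, p, o in g if p in ann_props)


# ---------------------------------------------------------------------------
# CSV report
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "s", "slabel", "user_slabel",
    "o", "olabel", "user_olabel",
    "pair_kind", "status", "matched_relation",
    "suggested_relation", "suggested_target", "notes",
]


def outcomes_to_csv(outcomes: Sequence[ValidationOutcome]) -> str:
    """Tabular report, one row per outcome, stable order, deterministic bytes."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for out in outcomes:
        cand = out.candidate
        writer.writerow([
            str(cand.subject.id) if cand.subject.id else "",
            cand.subject.ontology_label or "",
            cand.subject.user_label or "",
            str(cand.object.id) if cand.object.id else "",
            cand.object.ontology_label or "",
            cand.object.user_label or "",
            cand.pair_kind,
            out.status,
            out.matched_check.label() if out.matched_check else "",
            out.suggestion.record_as if out.suggestion else "",
            str(out.suggestion.target) if out.suggestion else "",
            ";".join(out.notes),
        ])
    return buf.getvalue()


# ---------------------------------------------------------------------------
# DOT
# ---------------------------------------------------------------------------

_AS_STYLE = 'shape=box, style=filled, fillcolor="#f4cccc"'   # anatomical structures
_CT_STYLE = 'shape=ellipse, style=filled, fillcolor="#cfe2f3"'  # cell types
_B_STYLE = 'shape=diamond, style=filled, fillcolor="#d9ead3"'


def _quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(
    source: Union[Sequence[ValidationOutcome], ViewGraph],
    labels: Optional[dict[Curie, str]] = None,
) -> str:
    """Graphviz DOT rendering of outcomes (styled by status) or a view.

    Nodes are labeled ``label\\n(CURIE)``; anatomical-structure nodes are
    drawn as filled boxes, cell types as filled ellipses.  Edge styling:
    valid = solid black with the matched relation; failed = red with the
    declared curation relation; suggested = the failed edge in red plus a
    green edge to the suggested target.
    """
    labels = labels or {}
    lines = ["digraph {", "  rankdir=RL;"]

    def node_id(curie: Curie) -> str:
        return _quote(str(curie))

    def node_label(curie: Curie, fallback: str = "") -> str:
        lbl = labels.get(curie) or fallback or str(curie)
        return f"{lbl}\\n({curie})"

    if isinstance(source, ViewGraph):
        for curie in sorted(source.seed_terms, key=str):
            style = _CT_STYLE if curie.prefix in ("CL", "PCL", "LMHA") else _AS_STYLE
            lines.append(f"  {node_id(curie)} [label={_quote(node_label(curie))}, {style}];")
        for (s, p, o) in sorted(
            source.edges, key=lambda t: (str(t[0]), pred_str(t[1]), str(t[2]))
        ):
            lines.append(
                f"  {node_id(s)} -> {node_id(o)} [label={_quote(pred_str(p))}];"
            )
        lines.append("}")
        return "\n".join(lines) + "\n"

    nodes: dict[Curie, tuple[str, str]] = {}  # curie -> (role, best label)
    edges: list[str] = []
    for out in source:
        cand = out.candidate
        for cell in (cand.subject, cand.object):
            if cell.id is not None and cell.id not in nodes:
                nodes[cell.id] = (cell.role, cell.best_label)
        if cand.subject.id is None or cand.object.id is None:
            continue
        s, o = node_id(cand.subject.id), node_id(cand.object.id)
        if out.status == VALID:
            assert out.matched_check is not None
            edges.append(
                f"  {s} -> {o} [label={_quote(out.matched_check.label())}, color=black];"
            )
        else:
            edges.append(
                f"  {s} -> {o} [label={_quote(cand.declared_relation)}, "
                "color=red, fontcolor=red];"
            )
            if out.status == SUGGESTED and out.suggestion is not None:
                sug = out.suggestion
                t = node_id(sug.target)
                if sug.target not in nodes:
                    nodes[sug.target] = ("AS", labels.get(sug.target, ""))
                pair = (t, s) if sug.swap else (s, t)
                edges.append(
                    f"  {pair[0]} -> {pair[1]} [label={_quote(sug.record_as)}, "
                    "color=green, fontcolor=green];"
                )

    style_by_role = {"AS": _AS_STYLE, "CT": _CT_STYLE, "B": _B_STYLE}
    for curie in sorted(nodes, key=str):
        role, lbl = nodes[curie]
        lines.append(
            f"  {node_id(curie)} [label={_quote(node_label(curie, lbl))}, "
            f"{style_by_role.get(role, _AS_STYLE)}];"
        )
    lines.extend(edges)
    lines.append("}")
    return "\n".join(lines) + "\n"
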