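"""Ordered relation checks, fallback suggestions and table validation.

Each candidate duple from a table is tested against the materialized closure
with an ordered list of relation checks specific to its pair kind; the first
check that is entailed wins.  For the reference-atlas profile ("hra"):

* AS-AS: subClassOf, part_of (BFO:0000050), overlaps (RO:0002131),
  connected_to (RO:0002170)
* CT-AS: part_of, overlaps, then has_part (BFO:0000051) tested in the
  swapped direction (AS has_part CT)
* CT-CT: subClassOf, develops_from (RO:0002202)

The developmental-atlas profile ("hdca") additionally accepts
has_developmental_contribution_from (RO:0002254) between anatomical
structures, admitting relationships like pharyngeal arch -> neural crest
that are developmental rather than partonomic.

For a duple that fails every check, :func:`suggest_fallback` searches for the
most specific other table term to which the subject bears a valid
relationship — e.g. a keratocyte recorded under 'anterior stroma' is instead
suggested part_of 'cornea', the most precise enclosing structure present in
the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .closure import ClosureGraph, entails
from .model import SUBCLASS, Curie, Predicate, pred_str
from .tables import (
    AS_AS,
    CT_AS,
    CT_CT,
    CandidateTriple,
    TableDocument,
    extract_candidates_report,
)

logger = logging.getLogger("ontoview")

PART_OF = Curie.parse("BFO:0000050")
HAS_PART = Curie.parse("BFO:0000051")
OVERLAPS = Curie.parse("RO:0002131")
CONNECTED_TO = Curie.parse("RO:0002170")
DEVELOPS_FROM = Curie.parse("RO:0002202")
HAS_DEV_CONTRIB = Curie.parse("RO:0002254")

VALID = "valid"
SUGGESTED = "suggested"
FAILED = "failed"


@dataclass(frozen=True)
class RelationCheck:
    """One step of an ordered check list.

    ``swap=True`` tests object -> subject instead (used for has_part, where
    the anatomical structure is the bearer).
    """

    property: Predicate
    swap: bool = False
    record_as: str = ""

    def label(self) -> str:
        return self.record_as or pred_str(self.property)


@dataclass
class ValidationProfile:
    name: str
    checks: dict[str, list[RelationCheck]]
    ccf_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CCF_MAP))
    #: fallback search order per pair kind; None = that kind's own checks
    suggestion_relations: Optional[dict[str, list[RelationCheck]]] = None

    def checks_for(self, pair_kind: str) -> list[RelationCheck]:
        try:
            out = self.checks[pair_kind]
        except KeyError:
            raise KeyError(f"profile {self.name!r} has no checks for {pair_kind}") from None
        if not out:
            raise ValueError(f"profile {self.name!r} has an empty check list for {pair_kind}")
        return out

    def suggestions_for(self, pair_kind: str) -> list[RelationCheck]:
        if self.suggestion_relations and pair_kind in self.suggestion_relations:
            return self.suggestion_relations[pair_kind]
        return self.checks_for(pair_kind)

    def ccf_relation(self, pair_kind: str, vasculature: bool = False) -> str:
        if pair_kind == AS_AS and vasculature:
            return "ccf_branching_part_of"
        return self.ccf_map[pair_kind]


DEFAULT_CCF_MAP = {AS_AS: "ccf_part_of", CT_AS: "ccf_located_in", CT_CT: "ccf_is_a"}


@dataclass(frozen=True)
class Suggestion:
    property: Predicate
    target: Curie
    all_candidates: tuple[Curie, ...]
    swap: bool = False
    record_as: str = ""


@dataclass
class ValidationOutcome:
    candidate: CandidateTriple
    status: str                              # valid | suggested | failed
    matched_check: Optional[RelationCheck] = None
    suggestion: Optional[Suggestion] = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.status == VALID) != (self.matched_check is not None):
            raise ValueError("status=valid iff matched_check present")
        if (self.status == SUGGESTED) != (self.suggestion is not None):
            raise ValueError("status=suggested iff suggestion present")


def default_profiles() -> dict[str, ValidationProfile]:
    """The two builtin profiles (reference atlas and developmental atlas)."""
    as_as = [
        RelationCheck(SUBCLASS, record_as="subClassOf"),
        RelationCheck(PART_OF, record_as="part_of"),
        RelationCheck(OVERLAPS, record_as="overlaps"),
        RelationCheck(CONNECTED_TO, record_as="connected_to"),
    ]
    ct_as = [
        RelationCheck(PART_OF, record_as="part_of"),
        RelationCheck(OVERLAPS, record_as="overlaps"),
        RelationCheck(HAS_PART, swap=True, record_as="has_part"),
    ]
    ct_ct = [
        RelationCheck(SUBCLASS, record_as="subClassOf"),
        RelationCheck(DEVELOPS_FROM, record_as="develops_from"),
    ]
    hra = ValidationProfile(
        "hra", {AS_AS: list(as_as), CT_AS: list(ct_as), CT_CT: list(ct_ct)}
    )
    hdca = ValidationProfile(
        "hdca",
        {
            AS_AS: list(as_as)
            + [RelationCheck(HAS_DEV_CONTRIB, record_as="has_developmental_contribution_from")],
            CT_AS: list(ct_as),
            CT_CT: list(ct_ct),
        },
    )
    return {"hra": hra, "hdca": hdca}


def load_profile_yaml(source: str, name: str = "custom") -> ValidationProfile:
    """Load a profile from YAML: ``pair_kind: [{property, swap, record_as}]``."""
    data = yaml.safe_load(source) or {}
    checks: dict[str, list[RelationCheck]] = {}
    for pair_kind, entries in data.get("checks", data).items():
        if pair_kind in ("name", "ccf_map"):
            continue
        checks[pair_kind] = [
            RelationCheck(
                property=(
                    SUBCLASS
                    if entry["property"] == SUBCLASS
                    else Curie.parse(entry["property"])
                ),
                swap=bool(entry.get("swap", False)),
                record_as=entry.get("record_as", ""),
            )
            for entry in entries
        ]
    ccf_map = dict(DEFAULT_CCF_MAP)
    if isinstance(data, dict):
        ccf_map.update(data.get("ccf_map", {}))
    return ValidationProfile(data.get("name", name) if isinstance(data, dict) else name,
                             checks, ccf_map)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_candidate(
    candidate: CandidateTriple,
    closure: ClosureGraph,
    profile: ValidationProfile,
) -> ValidationOutcome:
    """First-match test of a candidate against the closure.

    Missing ids and self-pairs short-circuit to failed with an explanatory
    note; fallback suggestions are attached separately by the pipeline.
    """
    notes: list[str] = []
    sub_id, obj_id = candidate.subject.id, candidate.object.id
    if sub_id is None or obj_id is None:
        notes.append("unmapped")
        return ValidationOutcome(candidate, FAILED, notes=notes)
    if sub_id == obj_id:
        notes.append("self-reference")
        return ValidationOutcome(candidate, FAILED, notes=notes)
    if candidate.subject.invalid_id or candidate.object.invalid_id:
        notes.append("invalid_id")
    for check in profile.checks_for(candidate.pair_kind):
        s, o = (obj_id, sub_id) if check.swap else (sub_id, obj_id)
        if entails(closure, s, check.property, o):
            return ValidationOutcome(candidate, VALID, matched_check=check, notes=notes)
    return ValidationOutcome(candidate, FAILED, notes=notes)


def suggest_fallback(
    candidate: CandidateTriple,
    table_term_ids: set[Curie],
    closure: ClosureGraph,
    profile: ValidationProfile,
) -> Optional[Suggestion]:
    """Most specific valid relationship from the subject to another table term.

    Checks are tried in the profile's suggestion order; the first relation
    with any valid target wins.  Among its targets only minimal elements
    under the specificity preorder (t1 below t2 iff the closure entails
    t1 part_of t2 or t1 subClassOf t2) are kept; the lexicographically first
    minimal target is the headline suggestion.  The search re-anchors the
    candidate's object only — its subject stays fixed.
    """
    sub_id = candidate.subject.id
    if sub_id is None:
        return None
    pool = sorted(table_term_ids - {sub_id, candidate.object.id}, key=str)
    for check in profile.suggestions_for(candidate.pair_kind):
        targets = [
            t
            for t in pool
            if entails(closure, *((t, check.property, sub_id) if check.swap
                                  else (sub_id, check.property, t)))
        ]
        if not targets:
            continue
        minimal = _minimal_by_specificity(targets, closure)
        return Suggestion(
            property=check.property,
            target=minimal[0],
            all_candidates=tuple(minimal),
            swap=check.swap,
            record_as=check.label(),
        )
    return None


def _below(t1: Curie, t2: Curie, closure: ClosureGraph) -> bool:
    """Specificity preorder: t1 is more specific than t2."""
    return entails(closure, t1, PART_OF, t2) or entails(closure, t1, SUBCLASS, t2)


def _minimal_by_specificity(targets: list[Curie], closure: ClosureGraph) -> list[Curie]:
    minimal = []
    for t in targets:
        dominated = any(
            u != t and _below(u, t, closure) and not _below(t, u, closure)
            for u in targets
        )
        if not dominated:
            minimal.append(t)
    return sorted(minimal, key=str)


def validate_table(
    doc: TableDocument,
    closure: ClosureGraph,
    profile: ValidationProfile,
) -> list[ValidationOutcome]:
    """Extract candidates, validate each, attach fallback suggestions.

    Output order is candidate-extraction order; the run is deterministic.
    """
    report = extract_candidates_report(doc, profile)
    table_ids = doc.term_ids()
    outcomes: list[ValidationOutcome] = []
    for candidate in report.candidates:
        outcome = validate_candidate(candidate, closure, profile)
        if outcome.status == FAILED and "unmapped" not in outcome.notes:
            suggestion = suggest_fallback(candidate, table_ids, closure, profile)
            if suggestion is not None:
                outcome = ValidationOutcome(
                    candidate, SUGGESTED, suggestion=suggestion, notes=outcome.notes
                )
        outcomes.append(outcome)
    return outcomes


def summarize(outcomes: list[ValidationOutcome]) -> dict:
    """Counts of valid/suggested/failed per pair kind plus totals."""
    summary: dict = {"total": len(outcomes), "by_pair_kind": {}, "by_status": {}}
    for out in outcomes:
        kind = summary["by_pair_kind"].setdefault(
            out.candidate.pair_kind, {VALID: 0, SUGGESTED: 0, FAILED: 0}
        )
        kind[out.status] += 1
        summary["by_status"][out.status] = summary["by_status"].get(out.status, 0) + 1
    return summary


# ---------------------------------------------------------------------------
# Remote (SPARQL) mode
# ---------------------------------------------------------------------------

SPARQL_PREFIXES = (
    "PREFIX UBERON: <http://purl.obolibrary.org/obo/UBERON_>\n"
    "PREFIX CL: <http://purl.obolibrary.org/obo/CL_>\n"
    "PREFIX PCL: <http://purl.obolibrary.org/obo/PCL_>\n"
)
SPARQL_GRAPHS = (
    "FROM <http://reasoner.renci.org/ontology>\n"
    "FROM <http://reasoner.renci.org/redundant>\n"
)


def build_sparql_values_query(
    property: Predicate, pairs: list[tuple[Curie, Curie]]
) -> str:
    """Batch entailment query against a precomputed-closure triplestore.

    One VALUES block carries all subject/object pairs for one relation; a
    returned pair means the triple holds, exactly as a local
    :func:`~ontoview.closure.entails` True.
    """
    if not pairs:
        raise ValueError("build_sparql_values_query requires a nonempty pair list")
    if property == SUBCLASS:
        rel_prefix = "PREFIX rel: <http://www.w3.org/2000/01/rdf-schema#subClassOf>\n"
    else:
        assert isinstance(property, Curie)
        rel_prefix = f"PREFIX rel: <{property.to_iri()}>\n"
    values = " ".join(f"({s} {o})" for s, o in pairs)
    return (
        rel_prefix
        + SPARQL_PREFIXES
        + "SELECT ?subject ?object\n"
        + SPARQL_GRAPHS
        + "WHERE {\n"
        + f"  VALUES (?subject ?object) {{{values}}}\n"
        + "  ?subject rel: ?object .\n"
        + "}\n"
    )


def query_remote_pairs(
    endpoint_url: str,
    property: Predicate,
    pairs: list[tuple[Curie, Curie]],
    timeout: float = 30.0,
    batch_size: int = 100,
) -> set[tuple[Curie, Curie]]:
    """Run the VALUES query against a SPARQL endpoint; returns entailed pairs.

    Network-optional: only used in ``mode=sparql`` pipelines.
    """
    import urllib.parse
    import urllib.request

    held: set[tuple[Curie, Curie]] = set()
    for i in range(0, len(pairs), batch_size):
        batch = pairs[i : i + batch_size]
        query = build_sparql_values_query(property, batch)
        data = urllib.parse.urlencode({"query": query}).encode()
        req = urllib.request.Request(
            endpoint_url,
            data=data,
            headers={"Accept": "application/sparql-results+json"},
        )
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            import json

            results = json.loads(resp.read().decode())
        for binding in results.get("results", {}).get("bindings", []):
            s = Curie.from_iri(binding["subject"]["value"])
            o = Curie.from_iri(binding["object"]["value"])
            if s and o:
                held.add((s, o))
    return held
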