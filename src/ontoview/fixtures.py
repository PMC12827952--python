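"""Builtin reference fixtures and seeded random generators for testing.

The builtin fixtures are tiny, hand-encoded ontology fragments (with
companion tables where a table exists) reproducing well-known validation
scenarios: a kidney partonomy whose table duples all validate as part_of; a
cornea scenario where a keratocyte duple fails but earns a part_of
suggestion to the most specific enclosing structure in the table; a
developing-brain fragment where the midbrain-hindbrain boundary validates
only via overlaps; a neural-crest fragment whose pharyngeal-arch duple
validates only when developmental relations are admitted; and the
part-relations hierarchy demonstrating subproperty lifting
(bounding_layer_of -> part_of).  They are deliberately minimal — only
relationships the reference documentation states — so tests cannot pass for
the wrong reason.

The random generators produce seed-determined fragments (acyclic by
construction for the classification backbone) and guaranteed-valid or
deliberately corrupted tables with a ground-truth key, for property-based
testing of the reasoner, reducer and validator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Optional

from .closure import saturate
from .model import (
    SUBCLASS,
    Curie,
    OntologyFragment,
    load_triple_tsv,
    some_values_axiom,
    subclass_axiom,
)
from .tables import TableCell, TableDocument, TableDialect, parse_table

FIXTURE_NAMES = (
    "kidney",
    "cornea",
    "midbrain_hindbrain",
    "neural_crest",
    "part_relation_hierarchy",
)

#: companion table CSVs per fixture; "main" is the fixture's primary table
_TABLES = {
    "kidney": {"main": "kidney_table.csv", "endothelium": "kidney_endothelium_table.csv"},
    "cornea": {"main": "cornea_table.csv"},
    "midbrain_hindbrain": {"main": "midbrain_hindbrain_table.csv"},
    "neural_crest": {"main": "neural_crest_table.csv"},
    "part_relation_hierarchy": {},
}


class Fixture(NamedTuple):
    fragment: OntologyFragment
    tables: dict[str, TableDocument]

    @property
    def table(self) -> Optional[TableDocument]:
        return self.tables.get("main")


def _read_data(name: str) -> str:
    return (resources.files("ontoview") / "data" / name).read_text()


def builtin_fixture(name: str) -> Fixture:
    """Load a builtin fixture by name; unknown names list the alternatives."""
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    fragment = load_triple_tsv(_read_data(f"{name}.tsv"), provenance=f"fixture:{name}")
    tables = {
        key: parse_table(_read_data(fname), provenance=f"fixture:{name}:{key}")
        for key, fname in _TABLES[name].items()
    }
    return Fixture(fragment, tables)


# ---------------------------------------------------------------------------
# Random ontology generator
# ---------------------------------------------------------------------------

@dataclass
class RandomOntologySpec:
    n_terms: int = 10
    n_properties: int = 2
    p_subclass: float = 0.15
    p_relation: float = 0.15
    subproperty_depth: int = 1
    enable_transitive: bool = True
    enable_chains: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 0:
            raise ValueError("n_terms must be >= 0")
        for p in (self.p_subclass, self.p_relation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def gen_random_ontology(spec: RandomOntologySpec) -> OntologyFragment:
    """Seed-determined fragment: terms T:0..T:n-1, properties P:0..

    SubClassOf edges run only from higher to lower term index, so the
    classification backbone is acyclic by construction; relation edges are
    sampled the same way over the declared properties.  The property
    hierarchy, transitivity flags and 2-step chains are sampled per the
    spec's switches.  Identical spec (incl. seed) gives identical fragments.
    """
    rng = random.Random(spec.seed)
    frag = OntologyFragment()
    terms = [Curie("T", f"{i:04d}") for i in range(spec.n_terms)]
    for t in terms:
        frag.ensure_term(t, f"term {t.local_id}")
    props = [Curie("P", f"{i:02d}") for i in range(spec.n_properties)]
    for p in props:
        frag.ensure_property(p, f"prop {p.local_id}")

    # property hierarchy: each property may get one parent of lower index,
    # up to subproperty_depth layers
    if spec.subproperty_depth > 0 and len(props) > 1:
        for i, p in enumerate(props[1:], start=1):
            if rng.random() < 0.5:
                parent = props[rng.randrange(0, i)]
                frag.properties[p].parents.append(parent)
    if spec.enable_transitive:
        for p in props:
            if rng.random() < 0.5:
                frag.properties[p].transitive = True
    if spec.enable_chains and len(props) >= 2:
        for p in props:
            if rng.random() < 0.3:
                s = props[rng.randrange(len(props))]
                t = props[rng.randrange(len(props))]
                if (s, t) not in frag.properties[p].chains:
                    frag.properties[p].chains.append((s, t))

    for j in range(spec.n_terms):
        for i in range(j):
            # higher index j is the subject, lower index i the object
            if rng.random() < spec.p_subclass:
                frag.add_axiom(subclass_axiom(terms[j], terms[i], "random"))
            if props and rng.random() < spec.p_relation:
                prop = props[rng.randrange(len(props))]
                frag.add_axiom(some_values_axiom(terms[j], prop, terms[i], "random"))
    return frag


# ---------------------------------------------------------------------------
# Random table generator
# ---------------------------------------------------------------------------

class GeneratedTable(NamedTuple):
    document: TableDocument
    #: ground truth per adjacent duple (subject id, object id) -> should validate
    truth: dict[tuple[Curie, Curie], bool]


def gen_random_table(
    fragment: OntologyFragment,
    n_rows: int,
    depth: int,
    seed: int,
    corruption_rate: float = 0.0,
    nesting_prop: Optional[Curie] = None,
) -> GeneratedTable:
    """Sample guaranteed-valid AS rows from a fragment's hierarchy.

    Rows are leaf-to-root walks along SubClassOf/part_of edges, written
    root-first (left = whole, right = part) and trimmed to ``depth``.  With
    ``corruption_rate`` > 0, individual duples are corrupted by re-pointing
    the left cell at a term with no entailed relationship to the subject;
    the returned key records, per duple, whether it should validate.
    """
    if not fragment.terms:
        raise ValueError("gen_random_table requires a nonempty fragment")
    rng = random.Random(seed)
    nesting_prop = nesting_prop or Curie.parse("BFO:0000050")
    closed = saturate(fragment.axiom_triples(), fragment.properties)

    # child -> parents along the nesting relations
    up: dict[Curie, list[Curie]] = {}
    for a in fragment.axioms:
        if a.is_subclass or a.pred == nesting_prop:
            up.setdefault(a.sub, []).append(a.obj)
    for v in up.values():
        v.sort(key=str)

    terms = sorted(fragment.terms, key=str)
    doc = TableDocument(provenance="gen_random_table")
    truth: dict[tuple[Curie, Curie], bool] = {}

    for row_i in range(n_rows):
        start = terms[rng.randrange(len(terms))]
        path = [start]
        while len(path) < depth and path[-1] in up:
            parents = up[path[-1]]
            path.append(parents[rng.randrange(len(parents))])
        path = list(reversed(path))  # root (whole) first

        # corruption: re-point the object of a duple at an unrelated term
        for k in range(len(path) - 1):
            subject = path[k + 1]
            if rng.random() < corruption_rate:
                # a replacement is "unrelated" when the closure holds no
                # triple at all from the subject to it, so no profile check
                # (incl. lifted/ chained relations) can validate the duple
                unrelated = [
                    t for t in terms
                    if t != subject
                    and not any(trip[0] == subject and trip[2] == t for trip in closed)
                ]
                if unrelated:
                    path[k] = unrelated[rng.randrange(len(unrelated))]
        row = [
            TableCell(role="AS", level=level, id=curie,
                      ontology_label=fragment.label_of(curie), row=row_i)
            for level, curie in enumerate(path, start=1)
        ]
        doc.rows.append(row)
        for left, right in zip(path, path[1:]):
            holds = any(
                (right, p, left) in closed for p in (SUBCLASS, nesting_prop)
            )
            key = (right, left)
            truth[key] = truth.get(key, False) or holds
    return GeneratedTable(doc, truth)
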