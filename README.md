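# ontoview

Validate expert-curated anatomy / cell-type term hierarchies against
reference-ontology structure, and extract simplified, grouping-safe ontology
views.

## The problem

Cell and tissue atlas projects organize their annotation vocabularies as
simple spreadsheet hierarchies — ASCT+B-style tables in which adjacency
within a row encodes a relationship between an object (left) and a subject
(right) term, with terms mapped to Uberon and the Cell Ontology. These
hierarchies are easy to author and browse, but a hierarchy entry is only
safe for *grouping annotations by location* if the corresponding quantified
relationship actually holds in the reference ontology: `'finger' part_of
some 'hand'` licenses rolling finger annotations up to the hand, whereas an
`overlaps` relationship does not, and a generic term filed under a specific
one (e.g. `endothelium` under `vasa recta descending limb`) is outright
false as a universally quantified statement.

`ontoview` checks each curated duple against a materialized inference
closure of the reference ontology ("redundant graph"), in which every
entailed classification and existential relationship is an explicit triple.
The closure is computed locally by a small fixpoint reasoner, so no remote
triplestore is required (an optional SPARQL mode can delegate the
entailment checks to an endpoint exposing a precomputed closure).

## What it computes

**Closure.** From subclass axioms, existential restrictions
(`A SubClassOf R some B`), a subPropertyOf hierarchy, transitivity flags
and 2-step property chains, the reasoner materializes the least fixpoint of

| rule | inference |
|------|-----------|
| R1 | `A ⊑ B`, `B ⊑ C` ⊢ `A ⊑ C` |
| R2 | `A ⊑ B`, `B ∃R C` ⊢ `A ∃R C` |
| R3 | `A ∃R B`, `B ⊑ C` ⊢ `A ∃R C` |
| R4 | `A ∃S B`, `S ⊑* R` ⊢ `A ∃R B` |
| R5 | transitive `R`: `A ∃R B`, `B ∃R C` ⊢ `A ∃R C` |
| R6 | chain `S∘T ⊑ R`: `A ∃S B`, `B ∃T C` ⊢ `A ∃R C` |

**Validation.** Each table duple is tested with ordered, pair-kind-specific
relation checks (first match wins). The default profile tests
AS–AS pairs for `subClassOf`, `part_of` (BFO:0000050), `overlaps`
(RO:0002131) and `connected_to` (RO:0002170); CT–AS pairs for `part_of`,
`overlaps`, then `has_part` (BFO:0000051) in the swapped direction; and
CT–CT pairs for `subClassOf` and `develops_from` (RO:0002202). The
developmental profile ("hdca") additionally accepts
`has_developmental_contribution_from` (RO:0002254) between anatomical
structures. For failing duples the validator proposes the most specific
other table term the subject bears a valid relationship to.

**Views.** A seed term set plus a relation set induces a subgraph of the
closure; removing every edge that is re-derivable from the rest (under the
same rules) yields a minimal view that entails exactly the same
seed-restricted relationships — the basis for publishing small,
grouping-safe application ontologies and for round-tripping views back into
nested tables for expert review.

**Emission.** Valid/suggested relationships become annotated OWL axioms
(subclass-of-existential-restriction); *every* curated duple is preserved as
a non-logical annotation triple (`ccf_part_of`, `ccf_located_in`, ...), so
non-validated content never feeds inference. CSV reports and Graphviz DOT
graphs (failed edges red, suggestions green) support curator review.

## Worked example

```sh
ontoview fixtures --name kidney --out fx
ontoview validate --ontology fx/kidney.tsv --table fx/kidney_table.csv \
    --out run --date 2026-01-01
```

prints

```
{"by_pair_kind": {"AS_AS": {"failed": 0, "suggested": 0, "valid": 10}}, "by_status": {"valid": 10}, "total": 10}
```

The bundled kidney table has 7 rows of three nested anatomical structures
each; after deduplication the 14 adjacent duples reduce to 10 unique
candidates (e.g. *renal corpuscle → nephron*, *nephron → kidney*), and every
one validates as `part_of` against the kidney fragment. `run/` then contains
`report.csv`, `report.dot`, `validated.owl.ttl` and `summary.json`.

Extracting a view over three seed terms:

```sh
printf 'UBERON:0002113\nUBERON:0001285\nUBERON:0001229\n' > seeds.txt
ontoview extract-view --ontology fx/kidney.tsv --seeds seeds.txt \
    --relations subClassOf,BFO:0000050 --out view
```

prints `{"relation_type_count": 1, "relationship_count": 2, "term_count": 3}`:
the chain *renal corpuscle → nephron → kidney* with the redundant
*renal corpuscle → kidney* grandparent edge removed as re-derivable.

The same operations are available as a library:

```python
import ontoview as ov

fixture = ov.builtin_fixture("cornea")
closure = ov.materialize(fixture.fragment)
outcomes = ov.validate_table(fixture.table, closure, ov.default_profiles()["hra"])
for o in outcomes:
    print(o.candidate.subject.id, o.status, o.suggestion)
```

shows the keratocyte duple *suggested* a `part_of` relationship to cornea
(the most specific enclosing structure present in the table) and the
telocyte duple *failed* with no suggestion.

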