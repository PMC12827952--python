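# Methods

## Model and assumptions

The validator treats a reference ontology fragment as a set of simple
logical statements over CURIE-identified classes: `SubClassOf` axioms and
class-level existential restrictions `A SubClassOf (R some B)` ("every A
bears R to some B"), plus object-property axioms (subPropertyOf parents,
transitivity, 2-step chains `S∘T ⊑ R`). This is the OWL EL-style subset
that anatomy and cell-type ontologies use for their partonomy and
classification backbones; equivalence classes, intersections, negation,
cardinality and individuals are out of scope, as is consistency checking.

All logic operates on CURIEs; labels and synonyms are metadata only.
Equality and ordering of CURIEs are case-sensitive lexicographic on the
serialized `prefix:local_id` form, and that ordering is the single
tie-break used everywhere determinism matters (suggestion headlines,
reduction order, serialization order).

## Closure materialization

`materialize()` computes the least fixpoint of six rules (R1–R6, see the
README table): subclass transitivity, propagation of existentials through
classification on either side, subproperty lifting through the
reflexive-transitive property-hierarchy closure, transitive properties, and
2-step chains. Design choices:

- **No inverse rule.** `A part_of some B` never yields `B has_part some A`;
  that is not an OWL entailment for class-level existentials. `has_part`
  validates only where asserted or derived directly, which is why the CT–AS
  check list tests it explicitly in the swapped direction.
- **Reflexive subclass edges are suppressed** on derivation, and entailment
  queries with subject = object answer False by convention: validating a
  term against itself is meaningless, and suppression makes the convention
  uniform across asserted and inferred content. (Whether a production
  triplestore stores reflexive pairs is a representation detail; this
  package documents its convention rather than inferring one.)
- **Cycles tolerated.** SubClassOf cycles keep the fixpoint finite; they are
  reported as warnings rather than errors because curated fragments may
  contain exactly the errors the validator exists to surface.
- **Chains are length 2.** Longer chains must be declared as cascaded
  2-chains; the motivating use case (inferring connection to a whole from
  connection to a part) is length 2.
- The production path is an indexed worklist (semi-naive) saturation;
  `naive_fixpoint_oracle()` is a deliberately unindexed quadratic re-scan,
  structured rule-by-rule and sharing no code with the worklist engine, kept
  as an independent correctness oracle and guarded to ≤ 100 terms.

## Table semantics

Within a row, adjacency encodes an object (left) / subject (right) duple.
Per row: every adjacent AS pair yields an AS–AS candidate; the *deepest* AS
cell pairs with the first CT cell (location should attach to the most
specific structure given — a cell recorded under `AS/5 endothelium` pairs
with the endothelium, not the organ); adjacent CT pairs yield CT–CT.
Duplicate candidates (same subject id, object id, pair kind) are removed
across rows; on the bundled 7-row kidney table the 14 adjacent duples
reduce to 10 unique candidates. Cells with a label but no id never produce
candidates silently — they are flagged `unmapped` and listed in a skip
report. Biomarker (B) columns are carried as passthrough records only; no
reference-ontology check applies to them. A dialect flag switches the
declared AS–AS curation relation from `ccf_part_of` to
`ccf_branching_part_of` for vasculature tables.

The `ROLE/n` column is the author's own label and `ROLE/n/LABEL` the
ontology label; either may be absent. Header auto-detection accepts any
`AS/<n>`-style column so extracts that start at deeper levels (e.g. an
`AS/4`–`AS/5` fragment) parse without configuration; official exports with
metadata banner rows are handled by the same detection or an explicit
`header_row`.

## Validation and suggestions

Checks run in profile order and the first entailed check is reported; the
listed orders of the builtin profiles are the documented defaults and are
configurable via profile YAML. For a failed duple, the fallback search
keeps the subject fixed and re-anchors the object: for each check relation
in order, it collects the other table terms the subject relates to,
keeps the minimal elements under the specificity preorder
(`t1 < t2` iff the closure entails `t1 part_of t2` or `t1 subClassOf t2`),
and returns the lexicographically first minimal element as the headline
suggestion together with the full minimal set. Returning all minimal
elements plus a deterministic headline favors reproducibility over an
arbitrary choice when candidates are incomparable. Self-pairs are reported
failed with note `self-reference`; duples with a missing id fail with note
`unmapped` and skip entailment entirely.

## View extraction and reduction

A view is the closure restricted to seed terms and chosen relations,
then reduced: edges are visited in lexicographic (subject, predicate,
object) order and removed when still derivable from the remaining edges
under R1–R6. Because derivability is monotone in the edge set, one pass
suffices, removal never changes the induced closure, and the result is
minimal (no single remaining edge is removable). Reduction counts
*cross-relation* derivations — through subclass edges, subproperty lifting
and chains — making it stronger than per-relation transitive reduction.
Minimal reductions are not unique in general graphs, hence the fixed
removal order. Seeds absent from the closure are kept as isolated nodes
(a published view must contain every requested term) and listed in a
warning.

`view_to_table` nests on one relation (plus SubClassOf): roots occupy
level 1 and each root-to-leaf path becomes a row, so a term with k parents
appears in k rows — duplication, not loss. Cyclic nesting is an error that
names a cycle.

## OWL output

Valid and suggested relationships are emitted as subclass axioms (plain for
`subClassOf` matches, otherwise subclass-of-existential-restriction) with
axiom-level annotations for status, date and source table. Every candidate
— including failures — is also written as a simple annotation triple using
its declared curation relation under a configurable annotation base
(default `http://purl.org/ccf/`; the concrete IRIs and status vocabulary of
any given deployment are configuration, not assumptions). Turtle is the
primary serialization. Emitters are pure functions; the validation date is
injected via config (the CLI defaults it explicitly), so identical inputs
give identical reports.

## Fixtures and generators

The builtin fixtures encode only relationships the reference documentation
states — e.g. the kidney fragment carries the 10 unique table-pair part_of
axioms, the podocyte classification/partonomy chain, and the ureter/kidney
overlap, but deliberately no background partonomy — so a passing test
cannot pass for the wrong reason. Identifiers are real Uberon/CL ids where
printed; terms whose ids the source tables do not print carry plausible
stand-ins, and all logic is id-agnostic.

The random-ontology generator samples classification and relation edges
only from higher to lower term index, so the backbone is acyclic by
construction; subproperty parents, transitivity flags and chains are
sampled per spec switches, and fragments are pure functions of their spec
(including seed). The random-table generator walks leaf-to-root paths
(guaranteed-valid rows) and, at a configurable corruption rate, re-points
duple objects at terms with *no* closure triple from the subject, so
corrupted duples cannot validate through any profile relation; a
ground-truth key accompanies each generated table. What the generators do
not emulate: realistic term-frequency distributions, multi-ontology prefix
mixtures, unmapped/typo'd identifiers at scale, and curation noise that is
correlated across rows — so passing property suites demonstrates logical
correctness of the machinery, not robustness to every artifact of real
curated tables.

## Problem sizes and numerical choices

The property suites run at deliberately small scale, chosen so the whole
suite and the acceptance script each complete in seconds while still
exercising every rule interaction: 200 random fragments (≤ 15 terms, ≤ 3
properties) for closure/oracle equivalence, 100 random views for
reduction invariance and minimality, 50 views for the table round trip.
All randomness is seed-derived; there are no tolerances anywhere — every
comparison in this package is exact set or string equality.

## Known limitations

- Entailment is restricted to the six rules; ontologies relying on logical
  definitions (equivalence + intersection) for classification must be
  pre-reasoned before export to the input formats.
- The fallback search re-anchors only the candidate's object; re-anchoring
  the subject (proposing a different child) is out of scope.
- Whether a CT cell should also pair with shallower AS ancestors in the
  same row is left unspecified by the table convention; only the deepest
  pairing is generated.
- The remote SPARQL mode shares query construction with the local path but
  its execution is network-dependent and not exercised offline.
- Greedy reduction minimizes the edge set but does not claim global
  minimum cardinality among all entailment-preserving subsets (minimal
  reductions are non-unique; the deterministic order picks one).
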