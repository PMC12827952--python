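"""Ordered relation checks, fallback suggestions, SPARQL query building."""

import pytest

import ontoview as ov
from ontoview.tables import AS_AS, CT_AS, CT_CT, TableCell, CandidateTriple
from ontoview.validate import (
    FAILED,
    SUGGESTED,
    VALID,
    load_profile_yaml,
    suggest_fallback,
)

from conftest import curie

PART_OF = curie("BFO:0000050")


def make_candidate(sub, obj, kind=AS_AS, relation="ccf_part_of"):
    return CandidateTriple(
        subject=TableCell(role=kind.split("_")[0], level=2, id=sub and curie(sub)),
        object=TableCell(role=kind.split("_")[1], level=1, id=obj and curie(obj)),
        pair_kind=kind,
        declared_relation=relation,
    )


class TestDefaultProfiles:
    def test_as_as_check_order(self, profiles):
        labels = [c.label() for c in profiles["hra"].checks_for(AS_AS)]
        assert labels == ["subClassOf", "part_of", "overlaps", "connected_to"]

    def test_ct_as_ends_with_swapped_has_part(self, profiles):
        checks = profiles["hra"].checks_for(CT_AS)
        assert [c.label() for c in checks] == ["part_of", "overlaps", "has_part"]
        assert checks[-1].swap and not checks[0].swap

    def test_ct_ct_checks(self, profiles):
        assert [c.label() for c in profiles["hra"].checks_for(CT_CT)] == [
            "subClassOf", "develops_from"
        ]

    def test_hdca_extends_as_as_with_developmental_relation(self, profiles):
        props = [c.property for c in profiles["hdca"].checks_for(AS_AS)]
        assert curie("RO:0002254") in props
        assert props[:4] == [c.property for c in profiles["hra"].checks_for(AS_AS)]

    def test_profile_yaml_roundtrip(self):
        src = (
            "name: custom\n"
            "checks:\n"
            "  AS_AS:\n"
            "    - {property: subClassOf, record_as: subClassOf}\n"
            "    - {property: 'BFO:0000050', record_as: part_of}\n"
        )
        prof = load_profile_yaml(src)
        assert [c.label() for c in prof.checks_for(AS_AS)] == ["subClassOf", "part_of"]


class TestValidateCandidate:
    def test_kidney_duple_valid_part_of(self, kidney_closure, profiles):
        out = ov.validate_candidate(
            make_candidate("UBERON:0001229", "UBERON:0001285"),
            kidney_closure, profiles["hra"],
        )
        assert out.status == VALID and out.matched_check.label() == "part_of"

    def test_generic_term_under_specific_fails(self, kidney_closure, profiles):
        # 'endothelium' placed under 'vasa recta descending limb': quantified
        # as "all endothelium part_of some vasa recta..." this is false
        out = ov.validate_candidate(
            make_candidate("UBERON:0001986", "UBERON:0009202"),
            kidney_closure, profiles["hra"],
        )
        assert out.status == FAILED

    def test_boundary_validates_via_overlaps(self, midbrain_hindbrain, profiles):
        closure = ov.materialize(midbrain_hindbrain.fragment)
        for target in ("UBERON:0002028", "UBERON:0001891"):   # hindbrain, midbrain
            out = ov.validate_candidate(
                make_candidate("UBERON:0003052", target), closure, profiles["hra"]
            )
            assert out.status == VALID and out.matched_check.label() == "overlaps"

    def test_pharyngeal_arch_needs_developmental_profile(self, neural_crest, profiles):
        closure = ov.materialize(neural_crest.fragment)
        cand = make_candidate("UBERON:0002539", "UBERON:0002342")
        assert ov.validate_candidate(cand, closure, profiles["hra"]).status == FAILED
        out = ov.validate_candidate(cand, closure, profiles["hdca"])
        assert out.status == VALID
        assert out.matched_check.property == curie("RO:0002254")

    def test_first_match_wins(self, part_relation_hierarchy, profiles):
        # capsule -> kidney entails both part_of and overlaps; part_of is
        # earlier in the AS-AS order so it must be reported
        closure = ov.materialize(part_relation_hierarchy.fragment)
        out = ov.validate_candidate(
            make_candidate("UBERON:0002015", "UBERON:0002113"),
            closure, profiles["hra"],
        )
        assert out.status == VALID and out.matched_check.label() == "part_of"

    def test_missing_id_noted_unmapped(self, kidney_closure, profiles):
        out = ov.validate_candidate(
            make_candidate(None, "UBERON:0002113"), kidney_closure, profiles["hra"]
        )
        assert out.status == FAILED and "unmapped" in out.notes

    def test_self_pair_failed_with_note(self, kidney_closure, profiles):
        out = ov.validate_candidate(
            make_candidate("UBERON:0002113", "UBERON:0002113"),
            kidney_closure, profiles["hra"],
        )
        assert out.status == FAILED and "self-reference" in out.notes

    def test_valid_part_of_never_validates_swapped(self, kidney_closure, profiles):
        # anti-symmetry on the fixture partonomy DAG
        out = ov.validate_candidate(
            make_candidate("UBERON:0001285", "UBERON:0001229"),
            kidney_closure, profiles["hra"],
        )
        assert out.status == FAILED


class TestSuggestFallback:
    def test_keratocyte_suggested_most_specific_enclosure(self, cornea, cornea_closure, profiles):
        cand = make_candidate("CL:0002363", "UBERON:8000053", kind=CT_AS,
                              relation="ccf_located_in")
        suggestion = suggest_fallback(
            cand, cornea.table.term_ids(), cornea_closure, profiles["hra"]
        )
        assert suggestion is not None
        assert suggestion.property == PART_OF
        assert suggestion.target == curie("UBERON:0000964")          # cornea, not eye
        assert suggestion.all_candidates == (curie("UBERON:0000964"),)

    def test_unrelated_cell_gets_no_suggestion(self, cornea, cornea_closure, profiles):
        cand = make_candidate("CL:4033055", "UBERON:8000053", kind=CT_AS)
        assert suggest_fallback(
            cand, cornea.table.term_ids(), cornea_closure, profiles["hra"]
        ) is None

    def test_singleton_candidate_returned_regardless_of_order(self, kidney_closure, profiles):
        # nephron tubule relates (part_of) only to nephron and kidney among
        # this restricted pool; with only kidney available it is returned
        cand = make_candidate("UBERON:0001231", "UBERON:0001229")
        pool = {curie("UBERON:0001231"), curie("UBERON:0001229"), curie("UBERON:0002113")}
        suggestion = suggest_fallback(cand, pool, kidney_closure, profiles["hra"])
        assert suggestion is not None and suggestion.target == curie("UBERON:0002113")

    def test_minimality_no_dominated_target_returned(self, kidney_closure, profiles):
        cand = make_candidate("UBERON:0009095", "UBERON:0001229")  # tip of papilla
        pool = {curie("UBERON:0009095"), curie("UBERON:0001229"),
                curie("UBERON:0001228"), curie("UBERON:0002113")}
        suggestion = suggest_fallback(cand, pool, kidney_closure, profiles["hra"])
        # renal papilla is below kidney in the partonomy, so kidney must not appear
        assert suggestion.target == curie("UBERON:0001228")
        assert curie("UBERON:0002113") not in suggestion.all_candidates


class TestValidateTable:
    def test_printed_kidney_table_fully_valid(self, kidney, kidney_closure, profiles):
        outcomes = ov.validate_table(kidney.table, kidney_closure, profiles["hra"])
        assert len(outcomes) == 10
        assert all(o.status == VALID for o in outcomes)
        assert {o.matched_check.label() for o in outcomes} == {"part_of"}

    def test_empty_table(self, kidney_closure, profiles):
        assert ov.validate_table(ov.TableDocument(), kidney_closure, profiles["hra"]) == []

    def test_cornea_statuses(self, cornea, cornea_closure, profiles):
        outcomes = ov.validate_table(cornea.table, cornea_closure, profiles["hra"])
        by_subject = {str(o.candidate.subject.id): o for o in outcomes}
        keratocyte = by_subject["CL:0002363"]
        assert keratocyte.status == SUGGESTED
        assert (keratocyte.suggestion.record_as, str(keratocyte.suggestion.target)) == (
            "part_of", "UBERON:0000964"
        )
        telocyte = by_subject["CL:4033055"]
        assert telocyte.status == FAILED and telocyte.suggestion is None

    def test_deterministic_serialization(self, cornea, cornea_closure, profiles):
        runs = [
            ov.outcomes_to_csv(
                ov.validate_table(cornea.table, cornea_closure, profiles["hra"])
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_endothelium_table_duples_fail(self, kidney, kidney_closure, profiles):
        outcomes = ov.validate_table(
            kidney.tables["endothelium"], kidney_closure, profiles["hra"]
        )
        as_as = [o for o in outcomes if o.candidate.pair_kind == AS_AS]
        assert as_as and all(o.status != VALID for o in as_as)


class TestSparqlQuery:
    def test_values_block_substitution(self):
        query = ov.build_sparql_values_query(
            PART_OF, [(curie("UBERON:0001229"), curie("UBERON:0001285"))]
        )
        assert "VALUES (?subject ?object) {(UBERON:0001229 UBERON:0001285)}" in query
        assert "PREFIX rel: <http://purl.obolibrary.org/obo/BFO_0000050>" in query
        assert "FROM <http://reasoner.renci.org/redundant>" in query
        assert "FROM <http://reasoner.renci.org/ontology>" in query

    def test_empty_pairs_error(self):
        with pytest.raises(ValueError):
            ov.build_sparql_values_query(PART_OF, [])
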