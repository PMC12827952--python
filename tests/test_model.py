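"""Domain types and the two ontology input formats."""

import json

import pytest
from hypothesis import given, settings, strategies as st

import ontoview as ov
from ontoview.model import (
    DEFAULT_PREDICATE_MAP,
    PropertyDecl,
    pred_str,
    some_values_axiom,
    subclass_axiom,
)

from conftest import curie


class TestCurie:
    def test_parse_and_serialize(self):
        c = ov.Curie.parse("UBERON:0002113")
        assert (c.prefix, c.local_id) == ("UBERON", "0002113")
        assert str(c) == "UBERON:0002113"

    @pytest.mark.parametrize("bad", ["", "UBERON", ":x", "x:", "a:b:c", "a b:c"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            ov.Curie.parse(bad)

    def test_ordering_is_lexicographic_case_sensitive(self):
        assert curie("CL:9") < curie("UBERON:1")     # 'C' < 'U'
        assert curie("UBERON:1") < curie("cl:1")     # upper before lower
        assert sorted([curie("B:2"), curie("B:1")]) == [curie("B:1"), curie("B:2")]

    @settings(derandomize=True, max_examples=50)
    @given(
        st.text(st.characters(categories=["Lu", "Ll", "Nd"]), min_size=1),
        st.text(st.characters(categories=["Lu", "Ll", "Nd"]), min_size=1),
    )
    def test_parse_roundtrip(self, prefix, local):
        c = ov.Curie(prefix, local)
        assert ov.Curie.parse(str(c)) == c

    def test_obo_iri_mapping(self):
        c = ov.Curie.from_iri("http://purl.obolibrary.org/obo/UBERON_0002113")
        assert c == curie("UBERON:0002113")
        assert c.to_iri() == "http://purl.obolibrary.org/obo/UBERON_0002113"
        assert ov.Curie.from_iri("http://example.org/foo") is None


class TestDeclarations:
    def test_property_self_parent_forbidden(self):
        with pytest.raises(ValueError):
            PropertyDecl(curie("RO:1"), parents=[curie("RO:1")])

    def test_reflexive_subclass_axiom_forbidden(self):
        with pytest.raises(ValueError):
            subclass_axiom(curie("A:1"), curie("A:1"))

    def test_undeclared_chain_member_rejected_on_validate(self):
        frag = ov.OntologyFragment()
        p = frag.ensure_property(curie("RO:1"))
        p.chains.append((curie("RO:2"), curie("RO:3")))
        with pytest.raises(ValueError, match="chain member"):
            frag.validate()

    def test_axiom_auto_declares_referenced_terms(self):
        frag = ov.OntologyFragment()
        frag.ensure_property(curie("BFO:0000050"))
        frag.add_axiom(some_values_axiom(curie("A:1"), curie("BFO:0000050"), curie("A:2")))
        assert curie("A:1") in frag.terms and curie("A:2") in frag.terms
        frag.validate()


OBOGRAPH_PODOCYTE = json.dumps({
    "graphs": [{
        "nodes": [
            {"id": "http://purl.obolibrary.org/obo/CL_0000653",
             "lbl": "podocyte", "type": "CLASS"},
            {"id": "http://purl.obolibrary.org/obo/UBERON_0005751",
             "lbl": "glomerular visceral epithelium", "type": "CLASS"},
        ],
        "edges": [
            {"sub": "http://purl.obolibrary.org/obo/CL_0000653",
             "pred": "http://purl.obolibrary.org/obo/BFO_0000050",
             "obj": "http://purl.obolibrary.org/obo/UBERON_0005751"},
        ],
    }]
})


class TestLoadObograph:
    def test_podocyte_edge_becomes_existential_axiom(self):
        frag = ov.load_obograph(OBOGRAPH_PODOCYTE)
        assert frag.axiom_triples() == {
            (curie("CL:0000653"), curie("BFO:0000050"), curie("UBERON:0005751"))
        }
        assert frag.terms[curie("CL:0000653")].label == "podocyte"

    def test_empty_graphs_array(self):
        frag = ov.load_obograph('{"graphs": []}')
        assert frag.axioms == [] and frag.terms == {}

    def test_malformed_json_names_byte_offset(self):
        with pytest.raises(ValueError, match="byte offset"):
            ov.load_obograph('{"graphs": [')

    def test_is_a_edges_become_subclass(self):
        doc = json.dumps({"graphs": [{"nodes": [], "edges": [
            {"sub": "CL:1", "pred": "is_a", "obj": "CL:2"}]}]})
        frag = ov.load_obograph(doc)
        assert frag.axiom_triples() == {(curie("CL:1"), ov.SUBCLASS, curie("CL:2"))}

    def test_unknown_predicate_skipped_unless_strict(self):
        doc = json.dumps({"graphs": [{"nodes": [], "edges": [
            {"sub": "CL:1", "pred": "http://example.org/mystery", "obj": "CL:2"}]}]})
        assert ov.load_obograph(doc).axioms == []
        with pytest.raises(ValueError, match="no predicate mapping"):
            ov.load_obograph(doc, strict=True)

    def test_default_predicate_map_covers_profile_relations(self):
        for tok in ("BFO:0000050", "BFO:0000051", "RO:0002131",
                    "RO:0002170", "RO:0002202", "RO:0002254"):
            assert DEFAULT_PREDICATE_MAP[tok] == curie(tok)

    def test_roundtrip_through_tsv(self):
        frag = ov.load_obograph(OBOGRAPH_PODOCYTE)
        again = ov.load_triple_tsv(ov.write_triple_tsv(frag))
        assert again.axiom_triples() == frag.axiom_triples()


class TestTripleTsv:
    def test_subproperty_directive_and_relationship(self):
        src = (
            "#prop BFO:0000050 transitive\n"
            "#prop RO:0002007 subPropertyOf BFO:0000050\n"
            "UBERON:0002015\tRO:0002007\tUBERON:0002113\n"
        )
        frag = ov.load_triple_tsv(src)
        assert len(frag.axioms) == 1 and not frag.axioms[0].is_subclass
        assert frag.properties[curie("RO:0002007")].parents == [curie("BFO:0000050")]
        assert frag.properties[curie("BFO:0000050")].transitive

    def test_zero_data_rows(self):
        assert ov.load_triple_tsv("#prop RO:1 declare\n").axioms == []

    def test_kidney_fixture_has_unique_table_pair_axioms(self, kidney):
        part_of = curie("BFO:0000050")
        table_terms = kidney.table.term_ids()
        table_axioms = {
            t for t in kidney.fragment.axiom_triples()
            if t[1] == part_of and t[0] in table_terms and t[2] in table_terms
        }
        # unique adjacent pairs of the printed 7-row table
        assert len(table_axioms) == 10

    def test_bad_column_count_names_line(self):
        with pytest.raises(ValueError, match="line 2"):
            ov.load_triple_tsv("A:1\tsubClassOf\tA:2\nA:1\tB:2\n")

    def test_undeclared_chain_member_is_error(self):
        with pytest.raises(ValueError, match="chain member"):
            ov.load_triple_tsv("#prop RO:1 chain RO:2 RO:3\n")

    def test_write_load_fixed_point(self, kidney):
        text = ov.write_triple_tsv(kidney.fragment)
        again = ov.load_triple_tsv(text)
        assert again.axiom_triples() == kidney.fragment.axiom_triples()
        assert ov.write_triple_tsv(again) == text


class TestMerge:
    def test_term_count_is_set_union(self, kidney, cornea):
        merged = ov.merge_fragments([kidney.fragment, cornea.fragment])
        shared = set(kidney.fragment.terms) & set(cornea.fragment.terms)
        assert len(merged.terms) == (
            len(kidney.fragment.terms) + len(cornea.fragment.terms) - len(shared)
        )
        assert merged.axiom_triples() == (
            kidney.fragment.axiom_triples() | cornea.fragment.axiom_triples()
        )

    def test_empty_is_identity_and_merge_idempotent(self, kidney):
        f = kidney.fragment
        assert ov.merge_fragments([f, ov.OntologyFragment()]).axiom_triples() == f.axiom_triples()
        assert ov.merge_fragments([f, f]).axiom_triples() == f.axiom_triples()

    def test_merge_commutative_on_axiom_sets(self, kidney, cornea):
        ab = ov.merge_fragments([kidney.fragment, cornea.fragment])
        ba = ov.merge_fragments([cornea.fragment, kidney.fragment])
        assert ab.axiom_triples() == ba.axiom_triples()

    def test_conflicting_transitivity_is_error(self):
        a = ov.load_triple_tsv("#prop BFO:0000050 transitive\n")
        b = ov.OntologyFragment()
        b.ensure_property(curie("BFO:0000050"))
        with pytest.raises(ValueError, match="transitivity"):
            ov.merge_fragments([a, b])

    def test_first_label_wins(self):
        a = ov.load_triple_tsv("#label A:1 alpha\n")
        b = ov.load_triple_tsv("#label A:1 beta\n")
        merged = ov.merge_fragments([a, b])
        assert merged.terms[curie("A:1")].label == "alpha"
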