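"""Mapping-axiom instantiation, materialization and BGP answering."""

import pandas as pd
import pytest

import ocrvkit as k
from ocrvkit.obda import (
    RDF_TYPE,
    BGPQuery,
    Lit,
    TemplateError,
    VirtualGraph,
    answer,
    parse_mapping_file,
    write_mapping_file,
)


@pytest.fixture()
def patient_source():
    return k.DataSourceDecl.from_dataframes(
        {
            "patients": pd.DataFrame(
                {"pid": [1, 2, 3], "sex": ["female", "male", "female"]}
            ),
            "weights": pd.DataFrame(
                {"rid": [10, 11], "w": [2.0, 3.0]}
            ),
        }
    )


CLASS_AXIOM = k.MappingAxiom(
    "m-class", "SELECT pid FROM patients",
    "<ocrv:patient/{pid}> rdf:type <ncit:patient> .",
)
DATA_AXIOM = k.MappingAxiom(
    "m-weight", "SELECT rid, w FROM weights",
    '<ocrv:brfss/{rid}> <ocrv:has BRFSS final weight> "{w}"^^decimal .',
)


class TestInstantiate:
    def test_one_class_assertion_per_row(self, patient_source):
        triples = k.instantiate_axiom(CLASS_AXIOM, patient_source)
        assert triples == {
            (f"ocrv:patient/{i}", RDF_TYPE, "ncit:patient") for i in (1, 2, 3)
        }
        assert CLASS_AXIOM.kind() == "class_assertion"

    def test_empty_source_yields_empty_set(self, patient_source):
        ax = k.MappingAxiom(
            "m-empty", "SELECT pid FROM patients WHERE pid > 99",
            "<ocrv:patient/{pid}> rdf:type <ncit:patient> .",
        )
        assert k.instantiate_axiom(ax, patient_source) == set()

    def test_data_property_literals_typed(self, patient_source):
        triples = k.instantiate_axiom(DATA_AXIOM, patient_source)
        assert triples == {
            ("ocrv:brfss/10", "ocrv:has BRFSS final weight",
             Lit(2.0, "decimal")),
            ("ocrv:brfss/11", "ocrv:has BRFSS final weight",
             Lit(3.0, "decimal")),
        }
        assert DATA_AXIOM.kind() == "data_property"

    def test_unresolved_placeholder_raises(self, patient_source):
        ax = k.MappingAxiom(
            "m-bad", "SELECT pid FROM patients",
            "<ocrv:patient/{nope}> rdf:type <ncit:patient> .",
        )
        with pytest.raises(TemplateError):
            k.instantiate_axiom(ax, patient_source)


class TestMaterialize:
    def test_disjoint_union_and_order_invariance(self, patient_source):
        g1 = k.materialize([CLASS_AXIOM, DATA_AXIOM], patient_source)
        g2 = k.materialize([DATA_AXIOM, CLASS_AXIOM], patient_source)
        assert len(g1) == 5  # 3 class assertions + 2 weights
        assert g1.triples == g2.triples

    def test_idempotent_for_fixed_sources(self, patient_source):
        g1 = k.materialize([CLASS_AXIOM], patient_source)
        g2 = k.materialize([CLASS_AXIOM], patient_source)
        assert g1.triples == g2.triples

    def test_duplicate_mapping_id_rejected(self, patient_source):
        with pytest.raises(ValueError):
            k.materialize([CLASS_AXIOM, CLASS_AXIOM], patient_source)

    def test_triple_count_matches_sql_count_oracle(self, small_source,
                                                   small_graph):
        # each shipped axiom contributes SQL-countable rows; the graph is
        # their union (shared-IRI duplicates removed by set semantics)
        expanded = set()
        for ax in k.default_obda_model():
            expanded |= k.instantiate_axiom(ax, small_source)
        assert len(small_graph) == len(expanded)


class TestAnswer:
    def build_graph(self, ontology):
        g = VirtualGraph()
        g.add(("ocrv:patient/1", RDF_TYPE, "ncit:patient"))
        g.add(("ocrv:patient/2", RDF_TYPE, "ncit:patient"))
        g.add(("ocrv:patient/1", "ocrv:has biological sex", Lit("female")))
        g.add(("ocrv:patient/2", "ocrv:has biological sex", Lit("male")))
        return g

    def test_direct_pattern_join(self, ontology):
        g = self.build_graph(ontology)
        q = BGPQuery(
            select_vars=("?p", "?sex"),
            patterns=(
                ("?p", RDF_TYPE, "ncit:patient"),
                ("?p", "ocrv:has biological sex", "?sex"),
            ),
        )
        table = answer(q, g, ontology)
        assert len(table) == 2
        assert set(zip(table["p"], table["sex"])) == {
            ("ocrv:patient/1", "female"), ("ocrv:patient/2", "male"),
        }

    def test_subclass_expansion(self, ontology):
        g = VirtualGraph()
        g.add(("ocrv:brfss/1", RDF_TYPE, "ocrv:BRFSS current every day smoker"))
        g.add(("ocrv:brfss/2", RDF_TYPE, "ocrv:BRFSS current someday smoker"))
        q = BGPQuery(
            select_vars=("?r",),
            patterns=(("?r", RDF_TYPE, "ocrv:BRFSS current smoker"),),
        )
        assert set(answer(q, g, ontology)["r"]) == {
            "ocrv:brfss/1", "ocrv:brfss/2"
        }

    def test_expansion_equals_per_subclass_union(self, ontology, small_graph):
        q_parent = BGPQuery(
            select_vars=("?r",),
            patterns=(("?r", RDF_TYPE, "ocrv:BRFSS current smoker"),),
        )
        got = set(answer(q_parent, small_graph, ontology)["r"])
        union = set()
        for cls in k.subclass_descendants(ontology,
                                          "ocrv:BRFSS current smoker"):
            union |= small_graph.subjects_of_class(cls)
        assert got == union

    def test_empty_graph_empty_answer(self, ontology):
        q = BGPQuery(select_vars=("?p",),
                     patterns=(("?p", RDF_TYPE, "ncit:patient"),))
        assert answer(q, VirtualGraph(), ontology).empty

    def test_unknown_iri_gives_empty_not_error(self, ontology):
        g = self.build_graph(ontology)
        q = BGPQuery(select_vars=("?p",),
                     patterns=(("?p", RDF_TYPE, "ocrv:patient/nonexistent"),))
        assert answer(q, g, ontology).empty

    def test_filters_compare_literals(self, ontology):
        g = VirtualGraph()
        for rid, w in ((1, 2.0), (2, 5.0)):
            g.add((f"ocrv:brfss/{rid}", "ocrv:has BRFSS final weight",
                   Lit(w, "decimal")))
        q = BGPQuery(
            select_vars=("?r",),
            patterns=(("?r", "ocrv:has BRFSS final weight", "?w"),),
            filters=(("?w", ">", 3.0),),
        )
        assert list(answer(q, g, ontology)["r"]) == ["ocrv:brfss/2"]

    def test_monotonic_under_triple_addition(self, ontology):
        g = self.build_graph(ontology)
        q = BGPQuery(
            select_vars=("?p", "?sex"),
            patterns=(
                ("?p", RDF_TYPE, "ncit:patient"),
                ("?p", "ocrv:has biological sex", "?sex"),
            ),
        )
        before = set(map(tuple, answer(q, g, ontology).to_numpy()))
        g.add(("ocrv:patient/3", RDF_TYPE, "ncit:patient"))
        g.add(("ocrv:patient/3", "ocrv:has biological sex", Lit("female")))
        after = set(map(tuple, answer(q, g, ontology).to_numpy()))
        assert before <= after

    def test_select_var_must_appear_in_patterns(self):
        with pytest.raises(ValueError):
            BGPQuery(select_vars=("?missing",),
                     patterns=(("?p", RDF_TYPE, "ncit:patient"),))


class TestRestrictions:
    def graph_with_smoker(self, smoke100_typed: bool, linked: bool = True):
        g = VirtualGraph()
        g.add(("ocrv:brfss/1", RDF_TYPE,
               "ocrv:BRFSS current every day smoker"))
        if linked:
            g.add(("ocrv:brfss/1", "ocrv:has smoking status",
                   "ocrv:smokestatus/1"))
            g.add(("ocrv:smokestatus/1", RDF_TYPE, "ncit:smoking status"))
        if smoke100_typed:
            g.add(("ocrv:smokestatus/1", RDF_TYPE,
                   "ocrv:BRFSS smoker who smoked at least 100 cigarettes "
                   "in the entire life"))
        return g

    def test_satisfied_restriction_no_violation(self, ontology):
        g = self.graph_with_smoker(smoke100_typed=True)
        assert k.check_restrictions(g, ontology) == []

    def test_value_outside_filler_is_violation(self, ontology):
        g = self.graph_with_smoker(smoke100_typed=False)
        violations = k.check_restrictions(g, ontology)
        assert len(violations) == 1
        v = violations[0]
        assert v.individual == "ocrv:brfss/1"
        assert v.on_property == "ocrv:has smoking status"

    def test_vacuous_when_property_absent(self, ontology):
        g = self.graph_with_smoker(smoke100_typed=False, linked=False)
        assert k.check_restrictions(g, ontology) == []


class TestMappingFile:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "model.obda"
        model = k.default_obda_model()
        write_mapping_file(model, path)
        back = parse_mapping_file(path)
        assert [(a.mapping_id, a.source_query, a.target_template)
                for a in back] == [
            (a.mapping_id, a.source_query, a.target_template) for a in model
        ]
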