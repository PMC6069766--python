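"""The four semantic query types and the classification rules."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ocrvkit as k
from ocrvkit.measures import is_current_smoker
from ocrvkit.qc import MalformedDateError
from ocrvkit.queries import (
    DEFAULT_RUCA_GROUPING,
    MARITAL_GROUPING,
    QUERY_CATALOG,
    RUCA_CLASS_BY_CODE,
    CatalogError,
)
from ocrvkit.sources import MARITAL_CATEGORIES


class TestClassifyCancerType:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("C50.4", "breast"),
            ("C50.0", "breast"),
            ("C34.5", "out_of_scope"),  # excluded from the lung list
            ("C34.8", "lung"),
            ("C26.0", "colorectal"),
            ("C18.9", "colorectal"),
            ("C61.9", "out_of_scope"),
        ],
    )
    def test_inclusion_lists(self, code, expected):
        assert k.classify_cancer_type(code) == expected

    def test_invalid_format_raises(self):
        with pytest.raises(ValueError):
            k.classify_cancer_type("breast")

    @given(st.integers(0, 99), st.integers(0, 9))
    def test_partition_no_code_maps_to_two_types(self, major, minor):
        code = f"C{major:02d}.{minor}"
        label = k.classify_cancer_type(code)
        memberships = [
            code in k.sources.BREAST_SITES,
            code in k.sources.LUNG_SITES,
            code in k.sources.COLORECTAL_SITES,
        ]
        assert sum(memberships) <= 1
        assert (label == "out_of_scope") == (sum(memberships) == 0)


class TestRegroupRuca:
    def test_default_metropolitan_split(self):
        assert k.regroup_ruca(1) == "metropolitan"
        assert k.regroup_ruca(3) == "metropolitan"
        assert k.regroup_ruca(4) == "non-metropolitan"
        assert k.regroup_ruca(10) == "non-metropolitan"

    def test_covers_exactly_ten_codes(self):
        assert sorted(RUCA_CLASS_BY_CODE) == list(range(1, 11))
        assert sorted(DEFAULT_RUCA_GROUPING) == list(range(1, 11))

    def test_identity_map(self):
        identity = {c: str(c) for c in range(1, 11)}
        for c in range(1, 11):
            assert k.regroup_ruca(c, identity) == str(c)

    def test_out_of_range_rejected(self):
        for bad in (0, 11, -3):
            with pytest.raises(ValueError):
                k.regroup_ruca(bad)


class TestMaritalGrouping:
    def test_exactly_seven_raw_categories(self):
        assert len(MARITAL_CATEGORIES) == 7

    def test_five_raw_categories_route_to_single(self):
        singles = [c for c in MARITAL_CATEGORIES
                   if MARITAL_GROUPING[c] == "single"]
        assert sorted(singles) == sorted(
            ["never married", "divorced", "widowed", "separated", "unmarried"]
        )
        assert MARITAL_GROUPING["married"] == "married"
        assert MARITAL_GROUPING["unknown"] == "unknown"


class TestYearOfDiagnosis:
    def test_extracts_leading_year(self):
        assert k.year_of_diagnosis("20180105") == 2018
        assert k.year_of_diagnosis("19960101") == 1996

    def test_wrong_dialect_flagged(self):
        with pytest.raises(MalformedDateError):
            k.year_of_diagnosis("2018-01-05")

    def test_accepts_diagnosis_event(self):
        ev = k.DiagnosisEvent("ocrv:diagnosis/1", "ocrv:patient/1",
                              "ncit:breast carcinoma", "20010203")
        assert k.year_of_diagnosis(ev) == 2001


class TestReasonedSmokers:
    def build(self, rows):
        brfss = pd.DataFrame(
            [
                {
                    "respondent_id": i + 1, "county_fips": "12001",
                    "sex": "female", "smokday2": s2, "smoke100": s100,
                    "drinks_per_week": 0.0, "design_weight": 1.0,
                    "raking_adjustment": 1.0, "final_weight": 1.0,
                }
                for i, (s2, s100) in enumerate(rows)
            ]
        )
        src = k.DataSourceDecl.from_dataframes({"brfss": brfss})
        axioms = [a for a in k.default_obda_model()
                  if a.mapping_id.startswith("brfss-")
                  and "lives" not in a.mapping_id]
        return k.materialize(axioms, src), brfss

    def test_exhaustive_truth_table(self, ontology):
        cells = list(itertools.product(
            ["every day", "some days", "not at all", "missing"],
            ["yes", "no", "missing"],
        ))
        assert len(cells) == 12
        graph, brfss = self.build(cells)
        got = {int(iri.rsplit("/", 1)[1])
               for iri in k.q_reasoned_smokers(graph, ontology)}
        expected = {
            i + 1 for i, (s2, s100) in enumerate(cells)
            if is_current_smoker(s2, s100)
        }
        assert got == expected
        assert len(expected) == 2  # (every day, yes) and (some days, yes)

    def test_reasoned_equals_rowwise_rule_on_fixture(self, ontology,
                                                     small_data, small_graph):
        got = {int(i.rsplit("/", 1)[1])
               for i in k.q_reasoned_smokers(small_graph, ontology)}
        b = small_data.brfss
        expected = set(
            b.loc[
                b["smokday2"].isin(["every day", "some days"])
                & (b["smoke100"] == "yes"),
                "respondent_id",
            ]
        )
        assert got == expected


class TestReasonedSingle:
    def test_widowed_included_married_excluded(self, ontology, small_data,
                                               small_graph):
        singles = {int(i.rsplit("/", 1)[1])
                   for i in k.q_reasoned_single(small_graph, ontology)}
        reg = small_data.registry.drop_duplicates("patient_id")
        grouped = reg.set_index("patient_id")["marital_status"].map(
            MARITAL_GROUPING
        )
        assert singles == set(grouped[grouped == "single"].index)

    def test_union_of_subclass_queries_equals_reasoned(self, ontology,
                                                       small_graph):
        from ocrvkit.obda import RDF_TYPE, BGPQuery, answer

        union = set()
        for cat in ("never married", "divorced", "widowed", "separated",
                    "unmarried"):
            q = BGPQuery(
                select_vars=("?p",),
                patterns=(
                    ("?p", RDF_TYPE, "ncit:patient"),
                    ("?p", "ocrv:has marital status", "?m"),
                    ("?m", RDF_TYPE, f"ocrv:{cat}"),
                ),
            )
            union |= set(answer(q, small_graph, ontology)["p"])
        assert union == set(k.q_reasoned_single(small_graph, ontology))


class TestDirectAndGeoLink:
    def test_sex_rows_match_patients(self, ontology, small_data, small_graph):
        table = k.q_direct("sex", small_graph, ontology)
        reg = small_data.registry.drop_duplicates("patient_id")
        assert len(table) == len(reg)

    def test_direct_race_equals_sql_oracle(self, ontology, small_data,
                                           small_graph, small_source):
        got = k.q_direct("race", small_graph, ontology)
        oracle = small_source.query(
            "SELECT DISTINCT patient_id, race FROM registry "
            "ORDER BY patient_id"
        )
        pd.testing.assert_frame_equal(
            got.reset_index(drop=True),
            oracle.rename(columns={"race": "race"}),
            check_dtype=False,
        )

    def test_unknown_variable_raises_catalog_error(self, ontology,
                                                   small_graph):
        with pytest.raises(CatalogError):
            k.q_direct("shoe_size", small_graph, ontology)

    def test_geo_link_svi_matches_join_oracle(self, ontology, small_data,
                                              small_graph):
        got = k.q_geo_link("svi_socioeconomic", small_graph, ontology)
        reg = small_data.registry.drop_duplicates("patient_id")
        oracle = reg.merge(small_data.svi, on="tract_geoid")[
            ["patient_id", "rank_socioeconomic"]
        ].sort_values("patient_id")
        merged = got.merge(oracle, on="patient_id")
        assert len(merged) == len(reg)
        assert (
            (merged["svi_socioeconomic"] - merged["rank_socioeconomic"])
            .abs().max() < 1e-9
        )

    def test_unmatched_geography_yields_missing_value(self, ontology,
                                                      small_data):
        tables = small_data.tables()
        tables = dict(tables)
        # remove one tract from the SVI table: its patients must surface
        # with a missing value, not disappear
        victim = small_data.registry["tract_geoid"].iloc[0]
        tables["svi"] = tables["svi"][
            tables["svi"]["tract_geoid"] != victim
        ]
        src = k.DataSourceDecl.from_dataframes(tables)
        graph = k.materialize(k.default_obda_model(), src)
        flags = []
        got = k.q_geo_link("svi_socioeconomic", graph, ontology, flags=flags)
        n_patients = small_data.registry["patient_id"].nunique()
        assert len(got) == n_patients
        assert got["svi_socioeconomic"].isna().any()
        assert flags


class TestDiagnosisEvents:
    def test_events_are_functional_and_complete(self, ontology, small_data,
                                                small_graph):
        events = k.diagnosis_events(small_graph, ontology)
        assert len(events) == len(small_data.registry)
        by_record = {int(e.event_iri.rsplit("/", 1)[1]): e for e in events}
        for row in small_data.registry.itertuples():
            ev = by_record[row.record_id]
            assert ev.diagnosis_time == row.diagnosis_date
            assert k.year_of_diagnosis(ev) == int(row.diagnosis_date[:4])

    def test_every_catalog_factor_has_exactly_one_spec(self):
        # the factor catalog is total and unambiguous over its keys
        assert len(QUERY_CATALOG) == len(set(QUERY_CATALOG))
        for name, spec in QUERY_CATALOG.items():
            assert spec.name == name
            assert spec.query_type in (
                "direct", "transform", "geo_link", "reasoned", "derived"
            )
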