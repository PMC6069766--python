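"""The four semantic query types and the classification/regrouping rules.

Semantic queries over the virtual graph fall into four kinds:

``direct``
    factors read straight off a patient through one object property
    (sex, race, insurance payer, ...);
``transform``
    factors needing a value-level conversion (extracting the year of
    diagnosis from the raw ``yyyymmdd`` diagnosis date);
``geo_link``
    contextual factors joined to a patient through shared geography — the
    tract or county the patient lives in is the join variable between the
    registry individuals and the contextual individuals;
``reasoned``
    factors resolved through knowledge encoded in the ontology: subclass
    regroupings (the five raw marital categories under ``ocrv:single``)
    and restriction-guarded definitions (the two-condition survey
    current-smoker rule).

This module also ships the default OBDA mapping model for the synthetic
source schema, the ICD-O-3 cancer-type classifier, and the RUCA
regrouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Optional, Union

import pandas as pd

from .obda import (
    RDF_TYPE,
    BGPQuery,
    MappingAxiom,
    VirtualGraph,
    answer,
    check_restrictions,
)
from .ontology import Ontology, subclass_descendants
from .qc import MalformedDateError
from .sources import (
    BREAST_SITES,
    COLORECTAL_SITES,
    LUNG_SITES,
    MARITAL_CATEGORIES,
)

__all__ = [
    "QuerySpec",
    "DiagnosisEvent",
    "CatalogError",
    "QUERY_CATALOG",
    "DISPLAY_NAMES",
    "MARITAL_GROUPING",
    "RUCA_CLASS_BY_CODE",
    "DEFAULT_RUCA_GROUPING",
    "default_obda_model",
    "run_query",
    "q_direct",
    "q_geo_link",
    "q_reasoned_smokers",
    "q_reasoned_single",
    "year_of_diagnosis",
    "classify_cancer_type",
    "regroup_ruca",
    "diagnosis_events",
]


class CatalogError(KeyError):
    """Requested variable has no query specification."""


# ---------------------------------------------------------------------------
# Classification / regrouping rules
# ---------------------------------------------------------------------------

#: Raw marital category -> analysis group. Five raw categories regroup to
#: "single"; "unknown" stays outside both single and married.
MARITAL_GROUPING: dict[str, str] = {
    "never married": "single",
    "divorced": "single",
    "widowed": "single",
    "separated": "single",
    "unmarried": "single",
    "married": "married",
    "unknown": "unknown",
    # ontology class label for the raw "unknown" category
    "unknown marital status": "unknown",
}

#: RUCA code (1-10) -> ontology class label.
RUCA_CLASS_BY_CODE: dict[int, str] = {
    1: "metropolitan area core",
    2: "metropolitan area high commuting",
    3: "metropolitan area low commuting",
    4: "micropolitan area core",
    5: "micropolitan high commuting",
    6: "micropolitan low commuting",
    7: "small town core",
    8: "small town high commuting",
    9: "small town low commuting",
    10: "rural areas",
}

#: Conventional default: the three metropolitan classes (codes 1-3) vs
#: everything else.  Alternative groupings are plain replacement maps.
DEFAULT_RUCA_GROUPING: dict[int, str] = {
    code: ("metropolitan" if code <= 3 else "non-metropolitan")
    for code in range(1, 11)
}


def classify_cancer_type(icdo3_site: str) -> str:
    """ICD-O-3 topography code -> {breast, lung, colorectal, out_of_scope}.

    Membership follows the study inclusion lists (C50.0-C50.9 breast;
    C34.0-C34.3, C34.8, C34.9 lung; C18.0-C18.9 and C26.0 colorectal);
    valid codes outside them are ``out_of_scope``.  A syntactically invalid
    code raises ``ValueError``.
    """
    import re

    code = str(icdo3_site)
    if not re.fullmatch(r"C\d\d(\.\d)?", code):
        raise ValueError(f"not an ICD-O-3 topography code: {icdo3_site!r}")
    if code in BREAST_SITES:
        return "breast"
    if code in LUNG_SITES:
        return "lung"
    if code in COLORECTAL_SITES:
        return "colorectal"
    return "out_of_scope"


def regroup_ruca(
    ruca_code: int, grouping_map: Optional[Mapping[int, str]] = None
) -> str:
    """Map a 10-level RUCA code to its analysis group.

    ``grouping_map`` must be total over 1..10; the default sends codes 1-3
    to "metropolitan" and 4-10 to "non-metropolitan".
    """
    code = int(ruca_code)
    if not 1 <= code <= 10:
        raise ValueError(f"RUCA code out of range 1..10: {ruca_code}")
    grouping_map = grouping_map if grouping_map is not None \
        else DEFAULT_RUCA_GROUPING
    if code not in grouping_map:
        raise ValueError(f"grouping map not total: missing code {code}")
    return grouping_map[code]


def year_of_diagnosis(event: Union["DiagnosisEvent", str]) -> int:
    """First four digits of the yyyymmdd diagnosis date, as an integer.

    Raises :class:`~ocrvkit.qc.MalformedDateError` for anything that is not
    an 8-digit date string, so callers can route the record to the
    consistency checks instead of dropping it silently.
    """
    import re

    raw = event.diagnosis_time if isinstance(event, DiagnosisEvent) else event
    s = str(raw)
    if not re.fullmatch(r"\d{8}", s):
        raise MalformedDateError(f"malformed yyyymmdd date: {raw!r}")
    return int(s[:4])


# ---------------------------------------------------------------------------
# Diagnosis events (the n-ary relation instances)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosisEvent:
    """One reified diagnosis: patient, tumor-type class, time instant.

    ``has tumor type`` and the valid-time link are functional, so each
    event carries exactly one tumor type and one original time value.
    """

    event_iri: str
    patient_iri: str
    tumor_type_class: str
    diagnosis_time: str  # original value, yyyymmdd


def diagnosis_events(graph: VirtualGraph,
                     ontology: Ontology) -> list[DiagnosisEvent]:
    """Extract every diagnosis-relation instance from the graph.

    Raises ``ValueError`` if a functional property (tumor type, valid
    time) carries more than one value on any event.
    """
    events = []
    for ev in sorted(graph.subjects_of_class("ocrv:diagnosis relation"),
                     key=str):
        tumors = graph.objects(ev, "ocrv:has tumor type")
        times = graph.objects(ev, "teo:hasValidTime")
        if len(tumors) > 1 or len(times) > 1:
            raise ValueError(f"functional property violated on {ev}")
        if not tumors or not times:
            continue
        t_classes = [
            o for o in graph.objects(tumors[0], RDF_TYPE) if isinstance(o, str)
        ]
        orig = graph.objects(times[0], "teo:hasOrigTime")
        patients = graph.subjects("ocrv:has diagnosis", ev)
        if not t_classes or not orig or not patients:
            continue
        events.append(
            DiagnosisEvent(
                event_iri=str(ev),
                patient_iri=str(patients[0]),
                tumor_type_class=t_classes[0],
                diagnosis_time=str(orig[0]),
            )
        )
    return events


# ---------------------------------------------------------------------------
# Default OBDA mapping model for the synthetic source schema
# ---------------------------------------------------------------------------

_LUNG_IN = "('C34.0','C34.1','C34.2','C34.3','C34.8','C34.9')"

_SVI_THEME_CLASS = {
    "socioeconomic": "ocrv:SVI socioeconomic status",
    "household": "ocrv:SVI household composition and disability",
    "minority": "ocrv:SVI minority status and languages",
    "housing": "ocrv:SVI housing and transportation",
}


def default_obda_model() -> list[MappingAxiom]:
    """The shipped mapping axioms linking the six source tables to OCRV.

    Mapping ids are grouped by source table (``reg-``, ``brfss-``,
    ``svi-``, ``census-``, ``ruca-``, ``county-``).  Individuals for
    shared entities (patients, tracts, counties) are minted from their
    source keys so cross-table links join by IRI identity.
    """
    ax: list[MappingAxiom] = []

    def add(mid: str, sql: str, target: str) -> None:
        ax.append(MappingAxiom(mid, sql, target))

    # --- registry: patients, demographics, diagnosis events -----------
    add("reg-patient", "SELECT DISTINCT patient_id FROM registry",
        "<ocrv:patient/{patient_id}> rdf:type <ncit:patient> .")
    for mid, col, prop in [
        ("reg-sex", "sex", "ocrv:has biological sex"),
        ("reg-race", "race", "ocrv:has race"),
        ("reg-ethnicity", "ethnicity", "ocrv:has ethnicity"),
        ("reg-payer", "insurance_payer", "ocrv:has insurance payer"),
    ]:
        add(mid, f"SELECT DISTINCT patient_id, {col} FROM registry",
            f'<ocrv:patient/{{patient_id}}> <{prop}> "{{{col}}}" .')
    add("reg-birth-year",
        "SELECT DISTINCT patient_id, birth_year FROM registry",
        '<ocrv:patient/{patient_id}> <ocrv:has birth year> '
        '"{birth_year}"^^integer .')
    for cat in MARITAL_CATEGORIES:
        cls = ("ocrv:unknown marital status" if cat == "unknown"
               else f"ocrv:{cat}")
        mid = "reg-marital-" + cat.replace(" ", "-")
        add(mid,
            "SELECT DISTINCT patient_id FROM registry "
            f"WHERE marital_status = '{cat}'",
            f"<ocrv:marital/{{patient_id}}> rdf:type <{cls}> .")
    add("reg-has-marital", "SELECT DISTINCT patient_id FROM registry",
        "<ocrv:patient/{patient_id}> <ocrv:has marital status> "
        "<ocrv:marital/{patient_id}> .")
    add("reg-lives-in-tract",
        "SELECT DISTINCT patient_id, tract_geoid FROM registry",
        "<ocrv:patient/{patient_id}> <ocrv:lives in> "
        "<ocrv:tract/{tract_geoid}> .")
    add("reg-lives-in-county",
        "SELECT DISTINCT patient_id, county_fips FROM registry",
        "<ocrv:patient/{patient_id}> <ocrv:lives in> "
        "<ocrv:county/{county_fips}> .")
    # n-ary diagnosis relation: event, tumor type, time instant
    add("reg-diagnosis", "SELECT record_id FROM registry",
        "<ocrv:diagnosis/{record_id}> rdf:type <ocrv:diagnosis relation> .")
    add("reg-has-diagnosis", "SELECT patient_id, record_id FROM registry",
        "<ocrv:patient/{patient_id}> <ocrv:has diagnosis> "
        "<ocrv:diagnosis/{record_id}> .")
    add("reg-has-tumor-type", "SELECT record_id FROM registry",
        "<ocrv:diagnosis/{record_id}> <ocrv:has tumor type> "
        "<ocrv:tumor/{record_id}> .")
    add("reg-tumor-breast",
        "SELECT record_id FROM registry WHERE icdo3_site LIKE 'C50.%'",
        "<ocrv:tumor/{record_id}> rdf:type <ncit:breast carcinoma> .")
    add("reg-tumor-lung",
        f"SELECT record_id FROM registry WHERE icdo3_site IN {_LUNG_IN}",
        "<ocrv:tumor/{record_id}> rdf:type <ncit:lung carcinoma> .")
    add("reg-tumor-colorectal",
        "SELECT record_id FROM registry "
        "WHERE icdo3_site LIKE 'C18.%' OR icdo3_site = 'C26.0'",
        "<ocrv:tumor/{record_id}> rdf:type <ncit:colorectal carcinoma> .")
    add("reg-dxtime", "SELECT record_id FROM registry",
        "<ocrv:dxtime/{record_id}> rdf:type <ocrv:date of diagnosis> .")
    add("reg-valid-time", "SELECT record_id FROM registry",
        "<ocrv:diagnosis/{record_id}> <teo:hasValidTime> "
        "<ocrv:dxtime/{record_id}> .")
    add("reg-orig-time", "SELECT record_id, diagnosis_date FROM registry",
        '<ocrv:dxtime/{record_id}> <teo:hasOrigTime> "{diagnosis_date}" .')
    for mid, col, prop, tag in [
        ("reg-stage", "tumor_stage", "ocrv:has tumor stage", "string"),
        ("reg-procedure", "treatment_procedure", "ocrv:has procedure",
         "string"),
        ("reg-survival-status", "survival_status",
         "ocrv:has survival status", "string"),
        ("reg-survival-months", "survival_months",
         "ocrv:has survival months", "decimal"),
        ("reg-recorded-age", "age_at_diagnosis",
         "ocrv:has recorded age at diagnosis", "integer"),
    ]:
        add(mid, f"SELECT record_id, {col} FROM registry",
            f'<ocrv:diagnosis/{{record_id}}> <{prop}> "{{{col}}}"^^{tag} .')
    add("reg-death-cause",
        "SELECT record_id, cause_of_death FROM registry "
        "WHERE cause_of_death <> ''",
        '<ocrv:diagnosis/{record_id}> <ocrv:has death cause> '
        '"{cause_of_death}" .')

    # --- behavioral survey --------------------------------------------
    add("brfss-interviewee", "SELECT respondent_id FROM brfss",
        "<ocrv:brfss/{respondent_id}> rdf:type <ncit:interviewee> .")
    add("brfss-everyday",
        "SELECT respondent_id FROM brfss WHERE smokday2 = 'every day'",
        "<ocrv:brfss/{respondent_id}> rdf:type "
        "<ocrv:BRFSS current every day smoker> .")
    add("brfss-someday",
        "SELECT respondent_id FROM brfss WHERE smokday2 = 'some days'",
        "<ocrv:brfss/{respondent_id}> rdf:type "
        "<ocrv:BRFSS current someday smoker> .")
    add("brfss-smoke100",
        "SELECT respondent_id FROM brfss WHERE smoke100 = 'yes'",
        "<ocrv:smokestatus/{respondent_id}> rdf:type "
        "<ocrv:BRFSS smoker who smoked at least 100 cigarettes in the "
        "entire life> .")
    add("brfss-smokestatus-base",
        "SELECT respondent_id FROM brfss "
        "WHERE smokday2 <> 'missing' OR smoke100 <> 'missing'",
        "<ocrv:smokestatus/{respondent_id}> rdf:type "
        "<ncit:smoking status> .")
    add("brfss-has-smoking-status",
        "SELECT respondent_id FROM brfss "
        "WHERE smokday2 IN ('every day', 'some days') "
        "OR smoke100 <> 'missing'",
        "<ocrv:brfss/{respondent_id}> <ocrv:has smoking status> "
        "<ocrv:smokestatus/{respondent_id}> .")
    add("brfss-heavy-male",
        "SELECT respondent_id FROM brfss "
        "WHERE sex = 'male' AND drinks_per_week > 14",
        "<ocrv:brfss/{respondent_id}> rdf:type "
        "<ocrv:male heavy drinker who reported having more than 14 drinks "
        "per week> .")
    add("brfss-heavy-female",
        "SELECT respondent_id FROM brfss "
        "WHERE sex = 'female' AND drinks_per_week > 7",
        "<ocrv:brfss/{respondent_id}> rdf:type "
        "<ocrv:female heavy drinker who reported having more than 7 drinks "
        "per week> .")
    add("brfss-lives-in",
        "SELECT respondent_id, county_fips FROM brfss",
        "<ocrv:brfss/{respondent_id}> <ocrv:lives in> "
        "<ocrv:county/{county_fips}> .")
    add("brfss-final-weight",
        "SELECT respondent_id, final_weight FROM brfss",
        '<ocrv:brfss/{respondent_id}> <ocrv:has BRFSS final weight> '
        '"{final_weight}"^^decimal .')
    add("brfss-sex", "SELECT respondent_id, sex FROM brfss",
        '<ocrv:brfss/{respondent_id}> <ocrv:has biological sex> "{sex}" .')
    add("brfss-drinks", "SELECT respondent_id, drinks_per_week FROM brfss",
        '<ocrv:brfss/{respondent_id}> <ocrv:has drinking status> '
        '"{drinks_per_week}"^^decimal .')

    # --- contextual tract / county tables -----------------------------
    add("svi-tract", "SELECT tract_geoid FROM svi",
        "<ocrv:tract/{tract_geoid}> rdf:type <ncit:census tract> .")
    for theme, cls in _SVI_THEME_CLASS.items():
        add(f"svi-{theme}", "SELECT tract_geoid FROM svi",
            f"<ocrv:svi_{theme}/{{tract_geoid}}> rdf:type <{cls}> .")
        add(f"svi-{theme}-link", "SELECT tract_geoid FROM svi",
            "<ocrv:tract/{tract_geoid}> <ocrv:has svi> "
            f"<ocrv:svi_{theme}/{{tract_geoid}}> .")
        add(f"svi-{theme}-value",
            f"SELECT tract_geoid, rank_{theme} FROM svi",
            f'<ocrv:svi_{theme}/{{tract_geoid}}> <ocrv:has value> '
            f'"{{rank_{theme}}}"^^decimal .')
    add("census-poverty", "SELECT tract_geoid FROM census",
        "<ocrv:poverty/{tract_geoid}> rdf:type "
        "<ocrv:census tract family poverty rate> .")
    add("census-poverty-link", "SELECT tract_geoid FROM census",
        "<ocrv:tract/{tract_geoid}> <ocrv:has family poverty level> "
        "<ocrv:poverty/{tract_geoid}> .")
    add("census-poverty-value",
        "SELECT tract_geoid, family_poverty_rate FROM census",
        '<ocrv:poverty/{tract_geoid}> <ocrv:has value> '
        '"{family_poverty_rate}"^^decimal .')
    add("census-education", "SELECT tract_geoid FROM census",
        "<ocrv:education/{tract_geoid}> rdf:type "
        "<ocrv:census tract high school completion rate> .")
    add("census-education-link", "SELECT tract_geoid FROM census",
        "<ocrv:tract/{tract_geoid}> <ocrv:has education level> "
        "<ocrv:education/{tract_geoid}> .")
    add("census-education-value",
        "SELECT tract_geoid, hs_completion_rate FROM census",
        '<ocrv:education/{tract_geoid}> <ocrv:has value> '
        '"{hs_completion_rate}"^^decimal .')
    for code, label in RUCA_CLASS_BY_CODE.items():
        add(f"ruca-{code}",
            f"SELECT tract_geoid FROM ruca WHERE ruca_code = {code}",
            f"<ocrv:ruca/{{tract_geoid}}> rdf:type <ocrv:{label}> .")
    add("ruca-link", "SELECT tract_geoid FROM ruca",
        "<ocrv:tract/{tract_geoid}> <ocrv:has rurality status> "
        "<ocrv:ruca/{tract_geoid}> .")
    add("county-decl", "SELECT county_fips FROM county_health",
        "<ocrv:county/{county_fips}> rdf:type <ncit:county> .")
    for short, cls, prop, col in [
        ("mental", "ocrv:county adult mental health status",
         "ocrv:has mental health condition", "mental_unhealthy_days"),
        ("physical", "ocrv:county adult physical health status",
         "ocrv:has physical health condition", "physical_unhealthy_days"),
        ("pcp", "ocrv:county density of primary care physicians",
         "ocrv:has primary care physician ratio", "pcp_ratio"),
    ]:
        add(f"county-{short}", "SELECT county_fips FROM county_health",
            f"<ocrv:{short}/{{county_fips}}> rdf:type <{cls}> .")
        add(f"county-{short}-link", "SELECT county_fips FROM county_health",
            f"<ocrv:county/{{county_fips}}> <{prop}> "
            f"<ocrv:{short}/{{county_fips}}> .")
        add(f"county-{short}-value",
            f"SELECT county_fips, {col} FROM county_health",
            f'<ocrv:{short}/{{county_fips}}> <ocrv:has value> '
            f'"{{{col}}}"^^decimal .')
    return ax


# ---------------------------------------------------------------------------
# Query catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuerySpec:
    """One risk factor's query: type, BGP, join level, post-processing.

    ``join_level`` says whether the answer keys on the patient or on the
    diagnosis record; ``post_map`` optionally maps the bound value (e.g. a
    raw marital class label) to its analysis group.
    """

    name: str
    query_type: str  # direct | transform | geo_link | reasoned | derived
    join_level: str  # "patient" | "record" | "county"
    bgp: Optional[BGPQuery] = None
    key_var: str = "?p"
    value_var: str = "?v"
    post_map: Optional[Callable[[Any], Any]] = None
    measure: str = ""  # for derived county rates


def _label(class_iri: Any) -> str:
    return str(class_iri).split(":", 1)[1]


def _patient_bgp(*extra_patterns, value_var="?v",
                 transforms=None) -> BGPQuery:
    pats = ((("?p", RDF_TYPE, "ncit:patient"),) + tuple(extra_patterns))
    tf = {"?p": "localname"}
    tf.update(transforms or {})
    return BGPQuery(select_vars=("?p", value_var), patterns=pats,
                    transforms=tf)


def _record_bgp(*extra_patterns, value_var="?v", transforms=None) -> BGPQuery:
    pats = ((("?d", RDF_TYPE, "ocrv:diagnosis relation"),)
            + tuple(extra_patterns))
    tf = {"?d": "localname"}
    tf.update(transforms or {})
    return BGPQuery(select_vars=("?d", value_var), patterns=pats,
                    transforms=tf)


def _geo_value_bgp(link_prop: str, holder_class: str) -> BGPQuery:
    """patient -> lives in -> area -> holder individual -> literal value."""
    return _patient_bgp(
        ("?p", "ocrv:lives in", "?area"),
        ("?area", link_prop, "?h"),
        ("?h", RDF_TYPE, holder_class),
        ("?h", "ocrv:has value", "?v"),
    )


def _build_catalog() -> dict[str, QuerySpec]:
    catalog: dict[str, QuerySpec] = {}

    def put(spec: QuerySpec) -> None:
        catalog[spec.name] = spec

    # type 1: direct patient-level extraction
    for name, prop in [
        ("sex", "ocrv:has biological sex"),
        ("race", "ocrv:has race"),
        ("ethnicity", "ocrv:has ethnicity"),
        ("insurance_payer", "ocrv:has insurance payer"),
    ]:
        put(QuerySpec(name, "direct", "patient",
                      _patient_bgp(("?p", prop, "?v"))))
    put(QuerySpec("birth_year", "direct", "patient",
                  _patient_bgp(("?p", "ocrv:has birth year", "?v"))))
    # type 1: direct record-level extraction
    for name, prop in [
        ("tumor_stage", "ocrv:has tumor stage"),
        ("treatment_procedure", "ocrv:has procedure"),
        ("survival_status", "ocrv:has survival status"),
        ("survival_months", "ocrv:has survival months"),
        ("cause_of_death", "ocrv:has death cause"),
        ("age_at_diagnosis", "ocrv:has recorded age at diagnosis"),
    ]:
        put(QuerySpec(name, "direct", "record",
                      _record_bgp(("?d", prop, "?v")), key_var="?d"))

    # type 2: value transforms
    put(QuerySpec(
        "year_of_diagnosis", "transform", "record",
        _record_bgp(
            ("?d", "teo:hasValidTime", "?t"),
            ("?t", "teo:hasOrigTime", "?v"),
            transforms={"?v": "year"},
        ),
        key_var="?d",
    ))

    # type 4 (regrouping via ontology classes) on record spine companions
    put(QuerySpec(
        "marital_status", "reasoned", "patient",
        _patient_bgp(
            ("?p", "ocrv:has marital status", "?m"),
            ("?m", RDF_TYPE, "?v"),
        ),
        post_map=lambda cls: MARITAL_GROUPING[_label(cls)],
    ))
    put(QuerySpec(
        "tumor_type", "reasoned", "record",
        _record_bgp(
            ("?d", "ocrv:has tumor type", "?t"),
            ("?t", RDF_TYPE, "?v"),
        ),
        key_var="?d",
        post_map=lambda cls: {
            "breast carcinoma": "breast",
            "lung carcinoma": "lung",
            "colorectal carcinoma": "colorectal",
        }[_label(cls)],
    ))

    # type 3: geographic linkage to contextual factors
    for name, holder in [
        ("svi_socioeconomic", "ocrv:SVI socioeconomic status"),
        ("svi_household", "ocrv:SVI household composition and disability"),
        ("svi_minority", "ocrv:SVI minority status and languages"),
        ("svi_housing", "ocrv:SVI housing and transportation"),
    ]:
        put(QuerySpec(name, "geo_link", "patient",
                      _geo_value_bgp("ocrv:has svi", holder)))
    put(QuerySpec("family_poverty_rate", "geo_link", "patient",
                  _geo_value_bgp("ocrv:has family poverty level",
                                 "ocrv:census tract family poverty rate")))
    put(QuerySpec("hs_completion_rate", "geo_link", "patient",
                  _geo_value_bgp("ocrv:has education level",
                                 "ocrv:census tract high school completion "
                                 "rate")))
    for name, prop, holder in [
        ("county_mental_health", "ocrv:has mental health condition",
         "ocrv:county adult mental health status"),
        ("county_physical_health", "ocrv:has physical health condition",
         "ocrv:county adult physical health status"),
        ("county_pcp_ratio", "ocrv:has primary care physician ratio",
         "ocrv:county density of primary care physicians"),
    ]:
        put(QuerySpec(name, "geo_link", "patient",
                      _geo_value_bgp(prop, holder)))
    # rurality: geo-linked RUCA class, regrouped (type 3 + type 4)
    put(QuerySpec(
        "rurality", "geo_link", "patient",
        _patient_bgp(
            ("?p", "ocrv:lives in", "?area"),
            ("?area", "ocrv:has rurality status", "?r"),
            ("?r", RDF_TYPE, "?v"),
        ),
        post_map=lambda cls: regroup_ruca(
            _RUCA_CODE_BY_CLASS[_label(cls)]
        ),
    ))
    put(QuerySpec(
        "ruca_class", "geo_link", "patient",
        _patient_bgp(
            ("?p", "ocrv:lives in", "?area"),
            ("?area", "ocrv:has rurality status", "?r"),
            ("?r", RDF_TYPE, "?v"),
        ),
        post_map=_label,
    ))
    # residency county (the linkage variable itself; also used by the
    # derived county-rate columns)
    put(QuerySpec(
        "county", "geo_link", "patient",
        _patient_bgp(
            ("?p", "ocrv:lives in", "?v"),
            ("?v", RDF_TYPE, "ncit:county"),
            transforms={"?v": "localname"},
        ),
    ))

    # derived county aggregates (computed by the measures module from the
    # raw survey table, joined in through the residency county)
    put(QuerySpec("county_smoking_rate", "derived", "county",
                  measure="smoking"))
    put(QuerySpec("county_alcohol_rate", "derived", "county",
                  measure="heavy_drinking"))
    return catalog


_RUCA_CODE_BY_CLASS = {label: code for code, label in
                       RUCA_CLASS_BY_CODE.items()}

QUERY_CATALOG: dict[str, QuerySpec] = _build_catalog()

#: Analysis-matrix column headers for factors whose display name is not
#: just the title-cased key.
DISPLAY_NAMES: dict[str, str] = {
    "sex": "Biological Sex",
    "marital_status": "Marital Status",
    "year_of_diagnosis": "Year of Diagnosis",
    "svi_socioeconomic": "SVI Socioeconomic Status",
    "svi_household": "SVI Household Composition and Disability",
    "svi_minority": "SVI Minority Status and Language",
    "svi_housing": "SVI Housing and Transportation",
    "survival_months": "Survival",
    "hs_completion_rate": "HS Completion Rate",
    "county_pcp_ratio": "County PCP Ratio",
    "ruca_class": "RUCA Class",
}


def display_name(factor: str) -> str:
    return DISPLAY_NAMES.get(
        factor, factor.replace("_", " ").title()
    )


# ---------------------------------------------------------------------------
# Query execution
# ---------------------------------------------------------------------------


def run_query(
    spec: QuerySpec,
    graph: VirtualGraph,
    ontology: Ontology,
    flags: Optional[list] = None,
) -> pd.DataFrame:
    """Execute a catalog query; returns ``[key, <name>]`` rows.

    The key column is ``patient_id`` or ``record_id`` according to the
    spec's join level, decoded from the individual IRIs.
    """
    if spec.bgp is None:
        raise CatalogError(
            f"{spec.name} is a derived measure; computed by the pipeline"
        )
    table = answer(spec.bgp, graph, ontology, flags=flags)
    key_col = spec.key_var.lstrip("?$")
    value_col = spec.value_var.lstrip("?$")
    out = table.rename(columns={key_col: _key_name(spec),
                                value_col: spec.name})
    if spec.post_map is not None:
        out[spec.name] = out[spec.name].map(
            lambda v: spec.post_map(v) if pd.notna(v) else v
        )
    out[_key_name(spec)] = out[_key_name(spec)].astype(int)
    return out[[_key_name(spec), spec.name]].sort_values(
        _key_name(spec), kind="mergesort"
    ).reset_index(drop=True)


def _key_name(spec: QuerySpec) -> str:
    return "patient_id" if spec.join_level == "patient" else "record_id"


def q_direct(variable: str, graph: VirtualGraph,
             ontology: Ontology) -> pd.DataFrame:
    """Type-1 query: a factor read directly off the patient/record."""
    spec = QUERY_CATALOG.get(variable)
    if spec is None or spec.query_type not in ("direct", "transform"):
        raise CatalogError(f"no direct query for variable {variable!r}")
    return run_query(spec, graph, ontology)


def q_geo_link(contextual_variable: str, graph: VirtualGraph,
               ontology: Ontology,
               flags: Optional[list] = None) -> pd.DataFrame:
    """Type-3 query: contextual factor joined through shared geography.

    Patients with no matching contextual row are kept with a missing
    value (and a flag when ``flags`` is a list) rather than dropped.
    """
    spec = QUERY_CATALOG.get(contextual_variable)
    if spec is None or spec.query_type != "geo_link":
        raise CatalogError(f"no geo-link query for {contextual_variable!r}")
    values = run_query(spec, graph, ontology)
    all_patients = run_query(QUERY_CATALOG["sex"], graph,
                             ontology)[["patient_id"]]
    out = all_patients.merge(values, on="patient_id", how="left")
    if flags is not None:
        for pid in out.loc[out[spec.name].isna(), "patient_id"]:
            flags.append({"variable": spec.name, "patient_id": int(pid),
                          "reason": "unmatched geography"})
    return out.sort_values("patient_id", kind="mergesort").reset_index(
        drop=True
    )


def q_reasoned_smokers(graph: VirtualGraph, ontology: Ontology) -> list[str]:
    """Type-4 query: all survey-defined current smokers.

    Individuals asserted under the current-smoker class (via subclass
    expansion over the every-day/some-day subclasses) whose universal
    restriction on the smoking-status property holds — operationally,
    respondents smoking every day or some days who smoked at least 100
    cigarettes lifetime.
    """
    q = BGPQuery(select_vars=("?r",),
                 patterns=(("?r", RDF_TYPE, "ocrv:BRFSS current smoker"),))
    candidates = set(answer(q, graph, ontology)["r"])
    violating = {
        v.individual
        for v in check_restrictions(graph, ontology)
        if v.on_property == "ocrv:has smoking status"
    }
    return sorted(candidates - violating)


def q_reasoned_single(graph: VirtualGraph, ontology: Ontology) -> list[str]:
    """Type-4 query: all patients whose marital status regroups to single.

    Leverages the subclass axioms placing the five raw categories under
    ``ocrv:single``.
    """
    q = BGPQuery(
        select_vars=("?p",),
        patterns=(
            ("?p", RDF_TYPE, "ncit:patient"),
            ("?p", "ocrv:has marital status", "?m"),
            ("?m", RDF_TYPE, "ocrv:single"),
        ),
    )
    return sorted(answer(q, graph, ontology)["p"])
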