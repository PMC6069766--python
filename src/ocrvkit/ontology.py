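"""In-memory model of the Ontology for Cancer Research Variables (OCRV).

OCRV is a small application ontology built to drive semantic integration of
cancer-registry, behavioral-survey and contextual (census-tract / county)
data.  It reuses a handful of stub terms from larger reference ontologies
(NCI Thesaurus, a time-event ontology, BFO) and adds its own classes and
properties that encode *data-analysis* knowledge: regroupings of raw
categorical codes (e.g. the five raw marital categories folded under
``ocrv:single``), survey-definition logic (the two-condition BRFSS
current-smoker rule expressed as ``owl:allValuesFrom`` restrictions), and
the contextual-factor vocabulary (SVI themes, RUCA codes, county health
measures).

The model here is deliberately structural: classes, typed properties,
subclass axioms and universal (allValuesFrom) restrictions, plus the
closure/depth queries the integration engine needs.  Full OWL-DL tableau
reasoning is out of scope; subclass-transitive reasoning and closed-world
restriction checking (in :mod:`ocrvkit.obda`) cover every inference the
pipeline relies on.

Identifiers
-----------
Entities are addressed by *namespaced labels* such as
``"ocrv:BRFSS current smoker"`` or ``"teo:hasValidTime"`` — the form the
source material uses in prose — and converted to full IRIs (CamelCased
fragment under the namespace base) only at serialization time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import rdflib
from rdflib import OWL, RDF, RDFS, XSD, BNode, Literal as RLiteral, URIRef

__all__ = [
    "OntClass",
    "OntProperty",
    "Restriction",
    "Ontology",
    "OntologyError",
    "build_ocrv",
    "subclass_descendants",
    "class_depth",
    "entity_counts",
    "export_ontology",
    "load_ontology",
    "NAMESPACE_BASES",
    "OCRV_BASE",
]

#: Namespace base IRIs.  The ocrv base mirrors the published prefix
#: declaration; the others are canonical-ish bases for the stubbed imports.
OCRV_BASE = "http://www.semanticweb.org/ontologies/OCRV"
NAMESPACE_BASES = {
    "ocrv": OCRV_BASE + "#",
    "ncit": "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#",
    "teo": "http://informatics.mayo.edu/TEO.owl#",
    "bfo": "http://purl.obolibrary.org/obo/bfo.owl#",
}

#: Datatype tags accepted as data-property ranges.
DATATYPE_TAGS = {"string", "integer", "decimal", "date", "boolean"}

# Annotation IRI used to persist the entity-registry flag through export.
_REGISTRY_ANNOTATION = URIRef(NAMESPACE_BASES["ocrv"] + "inEntityRegistry")


class OntologyError(ValueError):
    """Structural problem in the ontology (duplicate, dangling or cyclic)."""


@dataclass(frozen=True)
class OntClass:
    """An ontology class.

    ``registry`` marks classes belonging to the published OCRV entity
    registry (the census of newly created entities); support classes that
    exist only to carry regrouping or n-ary-relation structure are
    ``registry=False`` and excluded from :func:`entity_counts`.
    """

    iri: str
    label: str
    parents: frozenset[str] = frozenset()
    source_namespace: str = "ocrv"
    registry: bool = True

    def __post_init__(self) -> None:
        if self.source_namespace not in NAMESPACE_BASES:
            raise OntologyError(f"unknown namespace: {self.source_namespace}")


@dataclass(frozen=True)
class OntProperty:
    """An object or data property.

    ``range_class`` holds a class iri for object properties and a datatype
    tag (``string``/``integer``/``decimal``/``date``) for data properties.
    """

    iri: str
    kind: str  # "object" | "data"
    label: str
    domain_class: Optional[str] = None
    range_class: Optional[str] = None
    functional: bool = False
    source_namespace: str = "ocrv"
    registry: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("object", "data"):
            raise OntologyError(f"{self.iri}: bad property kind {self.kind!r}")
        if self.kind == "data":
            if self.range_class not in DATATYPE_TAGS:
                raise OntologyError(
                    f"{self.iri}: data property needs a datatype range, "
                    f"got {self.range_class!r}"
                )
        elif self.range_class is not None and self.range_class in DATATYPE_TAGS:
            raise OntologyError(
                f"{self.iri}: object property cannot have datatype range"
            )


@dataclass(frozen=True)
class Restriction:
    """A universal (``owl:allValuesFrom``) restriction attached to a class."""

    on_class: str
    on_property: str
    constraint_kind: str = "allValuesFrom"
    filler_class: str = ""

    def __post_init__(self) -> None:
        if self.constraint_kind != "allValuesFrom":
            raise OntologyError(
                f"unsupported restriction kind: {self.constraint_kind}"
            )


@dataclass
class Ontology:
    """A closed set of classes, properties and restrictions."""

    classes: dict[str, OntClass] = field(default_factory=dict)
    properties: dict[str, OntProperty] = field(default_factory=dict)
    restrictions: list[Restriction] = field(default_factory=list)

    # -- construction -------------------------------------------------

    def add_class(self, cls: OntClass) -> None:
        if cls.iri in self.classes or cls.iri in self.properties:
            raise OntologyError(f"duplicate iri: {cls.iri}")
        self.classes[cls.iri] = cls

    def add_property(self, prop: OntProperty) -> None:
        if prop.iri in self.properties or prop.iri in self.classes:
            raise OntologyError(f"duplicate iri: {prop.iri}")
        self.properties[prop.iri] = prop

    def add_restriction(self, r: Restriction) -> None:
        self.restrictions.append(r)

    def add_subclass_edge(self, child_iri: str, parent_iri: str) -> None:
        """Insert ``child rdfs:subClassOf parent``, rejecting cycles."""
        child = self._require_class(child_iri)
        self._require_class(parent_iri)
        if child_iri == parent_iri or child_iri in self._ancestors(parent_iri):
            raise OntologyError(
                f"subclass edge {child_iri} -> {parent_iri} creates a cycle"
            )
        self.classes[child_iri] = replace(
            child, parents=child.parents | {parent_iri}
        )

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        """Check reference closure and acyclicity; raise on violation."""
        for cls in self.classes.values():
            for p in cls.parents:
                if p not in self.classes:
                    raise OntologyError(f"{cls.iri}: dangling parent {p}")
        for prop in self.properties.values():
            if prop.domain_class is not None and prop.domain_class not in self.classes:
                raise OntologyError(f"{prop.iri}: dangling domain {prop.domain_class}")
            if (
                prop.kind == "object"
                and prop.range_class is not None
                and prop.range_class not in self.classes
            ):
                raise OntologyError(f"{prop.iri}: dangling range {prop.range_class}")
        for r in self.restrictions:
            if r.on_class not in self.classes:
                raise OntologyError(f"restriction on unknown class {r.on_class}")
            if r.on_property not in self.properties:
                raise OntologyError(f"restriction on unknown property {r.on_property}")
            if r.filler_class not in self.classes:
                raise OntologyError(f"restriction filler unknown: {r.filler_class}")
        for iri in self.classes:
            self._ancestors(iri)  # raises on cycle

    # -- structural queries -------------------------------------------

    def _require_class(self, iri: str) -> OntClass:
        try:
            return self.classes[iri]
        except KeyError:
            raise OntologyError(f"unknown class iri: {iri}") from None

    def _ancestors(self, iri: str) -> set[str]:
        """Strict ancestors of ``iri``; raises OntologyError on a cycle."""
        out: set[str] = set()
        stack = [(iri, (iri,))]
        while stack:
            node, path = stack.pop()
            for parent in self.classes[node].parents:
                if parent in path:
                    raise OntologyError(f"subclass cycle through {parent}")
                if parent not in out:
                    out.add(parent)
                    stack.append((parent, path + (parent,)))
        return out

    def children_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {iri: set() for iri in self.classes}
        for cls in self.classes.values():
            for p in cls.parents:
                idx[p].add(cls.iri)
        return idx


def subclass_descendants(ontology: Ontology, class_iri: str) -> set[str]:
    """Reflexive-transitive subclass closure below ``class_iri``.

    This is the inference the integration engine's "reasoned" queries rely
    on: asking for members of a class also returns members of every class
    beneath it (e.g. every-day and some-day smokers under the current-smoker
    class).
    """
    ontology._require_class(class_iri)
    idx = ontology.children_index()
    out = {class_iri}
    stack = [class_iri]
    while stack:
        for child in idx[stack.pop()]:
            if child not in out:
                out.add(child)
                stack.append(child)
    return out


def class_depth(ontology: Ontology, class_iri: str) -> int:
    """Longest parent-chain length (in nodes) from ``class_iri`` to a root.

    A root (class with no parents) has depth 1.  Depth is measured within
    the hierarchy as shipped — i.e. up to the most general stub class each
    tree hangs from — since the full upper ontologies are not imported.
    """
    ontology._require_class(class_iri)
    ontology._ancestors(class_iri)  # cycle guard
    memo: dict[str, int] = {}

    def depth(iri: str) -> int:
        if iri not in memo:
            parents = ontology.classes[iri].parents
            memo[iri] = 1 + max((depth(p) for p in parents), default=0)
        return memo[iri]

    return depth(class_iri)


def entity_counts(ontology: Ontology) -> dict[str, int]:
    """Census of the OCRV-created entities.

    Counts are restricted to ocrv-namespace entities in the published entity
    registry; ``max_depth`` is the maximum :func:`class_depth` over all
    ocrv-namespace classes.
    """
    ocrv_reg_classes = [
        c for c in ontology.classes.values()
        if c.source_namespace == "ocrv" and c.registry
    ]
    ocrv_reg_props = [
        p for p in ontology.properties.values()
        if p.source_namespace == "ocrv" and p.registry
    ]
    n_obj = sum(1 for p in ocrv_reg_props if p.kind == "object")
    n_data = sum(1 for p in ocrv_reg_props if p.kind == "data")
    max_depth = max(
        (
            class_depth(ontology, c.iri)
            for c in ontology.classes.values()
            if c.source_namespace == "ocrv"
        ),
        default=0,
    )
    return {
        "n_classes": len(ocrv_reg_classes),
        "n_object_properties": n_obj,
        "n_data_properties": n_data,
        "n_properties": n_obj + n_data,
        "max_depth": max_depth,
    }


# ---------------------------------------------------------------------------
# The shipped OCRV model
# ---------------------------------------------------------------------------

# The 30 classes of the OCRV entity registry, as (label, parent labels).
# Namespaced labels; parents outside ocrv are NCIt stubs declared below.
_REGISTRY_CLASSES: list[tuple[str, tuple[str, ...]]] = [
    # social-vulnerability-index group
    ("ocrv:social vulnerability index", ()),
    ("ocrv:SVI socioeconomic status", ("ocrv:social vulnerability index",)),
    ("ocrv:SVI household composition and disability",
     ("ocrv:social vulnerability index",)),
    ("ocrv:SVI minority status and languages",
     ("ocrv:social vulnerability index",)),
    ("ocrv:SVI housing and transportation",
     ("ocrv:social vulnerability index",)),
    # BRFSS smoker group (two-condition current-smoker definition)
    ("ocrv:BRFSS current smoker", ("ncit:smoking status",)),
    ("ocrv:BRFSS current every day smoker", ("ocrv:BRFSS current smoker",)),
    ("ocrv:BRFSS current someday smoker", ("ocrv:BRFSS current smoker",)),
    ("ocrv:BRFSS smoker who smoked at least 100 cigarettes in the entire life",
     ("ncit:smoking status",)),
    # BRFSS heavy-drinker group (sex-specific weekly thresholds)
    ("ocrv:BRFSS heavy drinker", ("ncit:personal attribute",)),
    ("ocrv:male heavy drinker who reported having more than 14 drinks per week",
     ("ocrv:BRFSS heavy drinker",)),
    ("ocrv:female heavy drinker who reported having more than 7 drinks per week",
     ("ocrv:BRFSS heavy drinker",)),
    # 10-level RUCA classification
    ("ocrv:rural-urban commuting area codes", ()),
    ("ocrv:metropolitan area core", ("ocrv:rural-urban commuting area codes",)),
    ("ocrv:metropolitan area high commuting",
     ("ocrv:rural-urban commuting area codes",)),
    ("ocrv:metropolitan area low commuting",
     ("ocrv:rural-urban commuting area codes",)),
    ("ocrv:micropolitan area core", ("ocrv:rural-urban commuting area codes",)),
    ("ocrv:micropolitan high commuting",
     ("ocrv:rural-urban commuting area codes",)),
    ("ocrv:micropolitan low commuting",
     ("ocrv:rural-urban commuting area codes",)),
    ("ocrv:small town core", ("ocrv:rural-urban commuting area codes",)),
    ("ocrv:small town high commuting",
     ("ocrv:rural-urban commuting area codes",)),
    ("ocrv:small town low commuting",
     ("ocrv:rural-urban commuting area codes",)),
    ("ocrv:rural areas", ("ocrv:rural-urban commuting area codes",)),
    # census-tract and county contextual measures
    ("ocrv:census tract high school completion rate", ()),
    ("ocrv:census tract family poverty rate", ()),
    ("ocrv:county adult mental health status", ()),
    ("ocrv:county adult physical health status", ()),
    ("ocrv:county density of primary care physicians", ()),
    # marital regrouping
    ("ocrv:single", ("ncit:marital status",)),
    ("ocrv:unknown marital status", ("ncit:marital status",)),
]

# ocrv support classes outside the registry census: the raw marital
# categories folded under `single`, the n-ary diagnosis-relation pattern,
# and the married category.
_SUPPORT_CLASSES: list[tuple[str, tuple[str, ...]]] = [
    ("ocrv:never married", ("ocrv:single",)),
    ("ocrv:divorced", ("ocrv:single",)),
    ("ocrv:widowed", ("ocrv:single",)),
    ("ocrv:separated", ("ocrv:single",)),
    ("ocrv:unmarried", ("ocrv:single",)),
    ("ocrv:married", ("ncit:marital status",)),
    ("ocrv:diagnosis relation", ()),
    ("ocrv:diagnosed tumor type", ()),
    ("ocrv:date of diagnosis", ("teo:timeInstance",)),
]

# Stubbed terms from the reference ontologies (not wholesale imports).
_STUB_CLASSES: list[tuple[str, tuple[str, ...]]] = [
    ("ncit:property or attribute", ()),
    ("ncit:personal attribute", ("ncit:property or attribute",)),
    ("ncit:smoking status", ("ncit:personal attribute",)),
    ("ncit:marital status", ("ncit:personal attribute",)),
    ("ncit:sex at birth", ("ncit:personal attribute",)),
    ("ncit:age at diagnosis", ("ncit:personal attribute",)),
    ("ncit:birth year", ("ncit:personal attribute",)),
    ("ncit:patient", ()),
    ("ncit:interviewee", ()),
    ("ncit:census tract", ()),
    ("ncit:county", ()),
    ("ncit:breast carcinoma", ("ocrv:diagnosed tumor type",)),
    ("ncit:lung carcinoma", ("ocrv:diagnosed tumor type",)),
    ("ncit:colorectal carcinoma", ("ocrv:diagnosed tumor type",)),
    ("teo:timeInstance", ()),
]

# The 23 registry properties: 22 object + 1 data.  The source registry
# prints "has tumor stage" twice; the second occurrence is declared as the
# distinct `ocrv:has tumor stage group` (summary-stage grouping) so the
# census stays faithful while iris remain unique.
_REGISTRY_OBJECT_PROPERTIES: list[tuple[str, Optional[str], Optional[str], bool]] = [
    # (label, domain, range, functional)
    ("ocrv:has death cause", "ocrv:diagnosis relation", None, False),
    ("ocrv:has diagnosis", "ncit:patient", "ocrv:diagnosis relation", False),
    ("ocrv:has marital status", "ncit:patient", "ncit:marital status", False),
    ("ocrv:has procedure", "ocrv:diagnosis relation", None, False),
    ("ocrv:has smoking status", "ncit:interviewee", "ncit:smoking status", False),
    ("ocrv:has drinking status", "ncit:interviewee", None, False),
    ("ocrv:has tumor type", "ocrv:diagnosis relation",
     "ocrv:diagnosed tumor type", True),
    ("ocrv:has tumor stage", "ocrv:diagnosis relation", None, False),
    ("ocrv:has stage", "ocrv:diagnosis relation", None, False),
    ("ocrv:has race", "ncit:patient", None, False),
    ("ocrv:has biological sex", None, "ncit:sex at birth", False),
    ("ocrv:has ethnicity", "ncit:patient", None, False),
    ("ocrv:has insurance payer", "ncit:patient", None, False),
    ("ocrv:has survival status", "ocrv:diagnosis relation", None, False),
    ("ocrv:has tumor stage group", "ocrv:diagnosis relation", None, False),
    ("ocrv:has family poverty level", "ncit:census tract",
     "ocrv:census tract family poverty rate", False),
    ("ocrv:has education level", "ncit:census tract",
     "ocrv:census tract high school completion rate", False),
    ("ocrv:has mental health condition", "ncit:county",
     "ocrv:county adult mental health status", False),
    ("ocrv:has physical health condition", "ncit:county",
     "ocrv:county adult physical health status", False),
    ("ocrv:has primary care physician ratio", "ncit:county",
     "ocrv:county density of primary care physicians", False),
    ("ocrv:has svi", "ncit:census tract",
     "ocrv:social vulnerability index", False),
    ("ocrv:lives in", None, None, False),
]

# (label, kind, domain, range, functional, registry)
_EXTRA_PROPERTIES: list[tuple[str, str, Optional[str], Optional[str], bool, bool]] = [
    ("ocrv:has BRFSS final weight", "data", "ncit:interviewee",
     "decimal", False, True),
    # helper properties needed to carry values on the graph; not part of
    # the published entity-registry census
    ("ocrv:has value", "data", None, "decimal", False, False),
    ("ocrv:has rurality status", "object", "ncit:census tract",
     "ocrv:rural-urban commuting area codes", False, False),
    ("ocrv:has survival months", "data", "ocrv:diagnosis relation",
     "decimal", False, False),
    ("ocrv:has birth year", "data", "ncit:patient", "integer", False, False),
    ("ocrv:has recorded age at diagnosis", "data", "ocrv:diagnosis relation",
     "integer", False, False),
    # time-event ontology stubs
    ("teo:hasValidTime", "object", "ocrv:diagnosis relation",
     "teo:timeInstance", True, False),
    ("teo:hasOrigTime", "data", "teo:timeInstance", "string", False, False),
]

_SMOKER_FILLER = (
    "ocrv:BRFSS smoker who smoked at least 100 cigarettes in the entire life"
)


def _ns_of(iri: str) -> str:
    return iri.split(":", 1)[0]


def _label_of(iri: str) -> str:
    return iri.split(":", 1)[1]


def build_ocrv() -> Ontology:
    """Build the shipped OCRV model and validate it.

    Returns the complete ontology: the 30-class / 23-property entity
    registry, the regrouping and n-ary support classes, the reference-
    ontology stubs, and the two ``allValuesFrom`` restrictions encoding the
    BRFSS current-smoker definition.
    """
    onto = Ontology()
    for label, parents in _STUB_CLASSES + _REGISTRY_CLASSES + _SUPPORT_CLASSES:
        registry = (label, parents) in _REGISTRY_CLASSES
        onto.add_class(
            OntClass(
                iri=label,
                label=_label_of(label),
                parents=frozenset(parents),
                source_namespace=_ns_of(label),
                registry=registry,
            )
        )
    for label, domain, rng, functional in _REGISTRY_OBJECT_PROPERTIES:
        onto.add_property(
            OntProperty(
                iri=label,
                kind="object",
                label=_label_of(label),
                domain_class=domain,
                range_class=rng,
                functional=functional,
                source_namespace=_ns_of(label),
                registry=True,
            )
        )
    for label, kind, domain, rng, functional, registry in _EXTRA_PROPERTIES:
        onto.add_property(
            OntProperty(
                iri=label,
                kind=kind,
                label=_label_of(label),
                domain_class=domain,
                range_class=rng,
                functional=functional,
                source_namespace=_ns_of(label),
                registry=registry,
            )
        )
    # The BRFSS current-smoker definition: every value of `has smoking
    # status` on either current-smoker subclass must lie in the
    # 100-cigarette class.
    for smoker_cls in (
        "ocrv:BRFSS current every day smoker",
        "ocrv:BRFSS current someday smoker",
    ):
        onto.add_restriction(
            Restriction(
                on_class=smoker_cls,
                on_property="ocrv:has smoking status",
                constraint_kind="allValuesFrom",
                filler_class=_SMOKER_FILLER,
            )
        )
    onto.validate()
    return onto


# ---------------------------------------------------------------------------
# Serialization (Turtle / N3 via rdflib)
# ---------------------------------------------------------------------------

_XSD_OF_TAG = {
    "string": XSD.string,
    "integer": XSD.integer,
    "decimal": XSD.decimal,
    "date": XSD.date,
    "boolean": XSD.boolean,
}
_TAG_OF_XSD = {v: k for k, v in _XSD_OF_TAG.items()}


def to_uri(iri: str) -> URIRef:
    """Namespaced label -> full IRI (CamelCased fragment under the base).

    The mapping is one-way; round-trips go through ``rdfs:label``, so the
    fragment style is purely cosmetic.
    """
    ns, label = iri.split(":", 1)
    frag = "".join(
        w[:1].upper() + w[1:] for w in label.replace("-", " ").split()
    )
    return URIRef(NAMESPACE_BASES[ns] + frag)


def _iri_namespace(uri: URIRef) -> Optional[str]:
    s = str(uri)
    for ns, base in NAMESPACE_BASES.items():
        if s.startswith(base):
            return ns
    return None


def export_ontology(ontology: Ontology, path: str, fmt: str = "turtle") -> None:
    """Serialize the ontology to Turtle/N3 at ``path``.

    The export is lossless for the structural model: re-parsing with
    :func:`load_ontology` reproduces identical class, property and
    restriction sets (labels carried via ``rdfs:label``, the registry flag
    via a boolean annotation).
    """
    ontology.validate()
    g = rdflib.Graph()
    for ns, base in NAMESPACE_BASES.items():
        g.bind(ns, base)
    g.bind("owl", OWL)
    for cls in ontology.classes.values():
        u = to_uri(cls.iri)
        g.add((u, RDF.type, OWL.Class))
        g.add((u, RDFS.label, RLiteral(cls.label)))
        g.add((u, _REGISTRY_ANNOTATION, RLiteral(cls.registry)))
        for p in sorted(cls.parents):
            g.add((u, RDFS.subClassOf, to_uri(p)))
    for prop in ontology.properties.values():
        u = to_uri(prop.iri)
        g.add((u, RDF.type,
               OWL.ObjectProperty if prop.kind == "object"
               else OWL.DatatypeProperty))
        g.add((u, RDFS.label, RLiteral(prop.label)))
        g.add((u, _REGISTRY_ANNOTATION, RLiteral(prop.registry)))
        if prop.functional:
            g.add((u, RDF.type, OWL.FunctionalProperty))
        if prop.domain_class:
            g.add((u, RDFS.domain, to_uri(prop.domain_class)))
        if prop.range_class:
            if prop.kind == "data":
                g.add((u, RDFS.range, _XSD_OF_TAG[prop.range_class]))
            else:
                g.add((u, RDFS.range, to_uri(prop.range_class)))
    for r in ontology.restrictions:
        node = BNode()
        g.add((node, RDF.type, OWL.Restriction))
        g.add((node, OWL.onProperty, to_uri(r.on_property)))
        g.add((node, OWL.allValuesFrom, to_uri(r.filler_class)))
        g.add((to_uri(r.on_class), RDFS.subClassOf, node))
    if len(g) == 0:
        # rdflib omits unused prefixes; an empty export should still be a
        # syntactically valid document carrying the prefix declarations
        header = "".join(
            f"@prefix {ns}: <{base}> .\n"
            for ns, base in NAMESPACE_BASES.items()
        ) + f"@prefix owl: <{OWL}> .\n"
        from pathlib import Path as _Path

        _Path(path).write_text(header)
        return
    g.serialize(destination=path, format=fmt)


def load_ontology(path: str, fmt: Optional[str] = None) -> Ontology:
    """Parse a Turtle/N3 export back into an :class:`Ontology`."""
    g = rdflib.Graph()
    g.parse(path, format=fmt or "turtle")

    def short(uri: URIRef) -> str:
        ns = _iri_namespace(uri)
        label = g.value(uri, RDFS.label)
        if ns is None or label is None:
            raise OntologyError(f"cannot resolve imported iri {uri}")
        return f"{ns}:{label}"

    onto = Ontology()
    uris_of_classes = sorted(set(g.subjects(RDF.type, OWL.Class)))
    uri_to_short = {u: short(u) for u in uris_of_classes
                    if not isinstance(u, BNode)}
    for u in uris_of_classes:
        if isinstance(u, BNode):
            continue
        parents = frozenset(
            uri_to_short[p]
            for p in g.objects(u, RDFS.subClassOf)
            if not isinstance(p, BNode)
        )
        iri = uri_to_short[u]
        onto.add_class(
            OntClass(
                iri=iri,
                label=_label_of(iri),
                parents=parents,
                source_namespace=_ns_of(iri),
                registry=bool(g.value(u, _REGISTRY_ANNOTATION)),
            )
        )
    for u in sorted(
        set(g.subjects(RDF.type, OWL.ObjectProperty))
        | set(g.subjects(RDF.type, OWL.DatatypeProperty))
    ):
        kind = "object" if (u, RDF.type, OWL.ObjectProperty) in g else "data"
        rng = g.value(u, RDFS.range)
        if kind == "data":
            range_class = _TAG_OF_XSD.get(rng) if rng is not None else None
        else:
            range_class = uri_to_short.get(rng) if rng is not None else None
        dom = g.value(u, RDFS.domain)
        iri = short(u)
        onto.add_property(
            OntProperty(
                iri=iri,
                kind=kind,
                label=_label_of(iri),
                domain_class=uri_to_short.get(dom) if dom is not None else None,
                range_class=range_class,
                functional=(u, RDF.type, OWL.FunctionalProperty) in g,
                source_namespace=_ns_of(iri),
                registry=bool(g.value(u, _REGISTRY_ANNOTATION)),
            )
        )
    prop_uri_to_short = {to_uri(p): p for p in onto.properties}
    for node in set(g.subjects(RDF.type, OWL.Restriction)):
        on_prop = g.value(node, OWL.onProperty)
        filler = g.value(node, OWL.allValuesFrom)
        for cls_uri in g.subjects(RDFS.subClassOf, node):
            onto.add_restriction(
                Restriction(
                    on_class=uri_to_short[cls_uri],
                    on_property=prop_uri_to_short[on_prop],
                    filler_class=uri_to_short[filler],
                )
            )
    onto.validate()
    return onto
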