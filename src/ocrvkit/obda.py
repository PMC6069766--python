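"""Ontology-based data access over relational sources.

The bridge between relational rows and the semantic layer is a set of
*mapping axioms*.  Each axiom carries a ``mappingId``, a ``source`` (a SQL
query against one declared data source) and a ``target`` (an RDF triple
template whose ``{column}`` placeholders are filled from each result row).
Running every axiom materializes a *virtual graph* — the triple set the
mapped sources induce — which conjunctive basic-graph-pattern (BGP) queries
are answered against.

Two pieces of ontology-aware behavior live here:

* **subclass expansion** — a pattern ``?x rdf:type C`` matches individuals
  asserted in ``C`` or any subclass of ``C`` (so querying for the
  current-smoker class finds the every-day and some-day smokers);
* **closed-world restriction checking** — ``owl:allValuesFrom``
  restrictions are enforced as checks over the materialized graph: every
  value of the restricted property on a member of the restricted class must
  be asserted in the filler class.

A deliberate simplification relative to on-the-fly SPARQL-to-SQL rewriting:
the graph is materialized in memory and queried there.  Answers are
identical (the test suite holds them to hand-written SQL over the same
sources); the engine is far simpler.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .ontology import Ontology, subclass_descendants

__all__ = [
    "Lit",
    "RDFTriple",
    "DataSourceDecl",
    "MappingAxiom",
    "VirtualGraph",
    "BGPQuery",
    "Violation",
    "SourceError",
    "TemplateError",
    "TransformError",
    "instantiate_axiom",
    "materialize",
    "answer",
    "check_restrictions",
    "parse_mapping_file",
    "write_mapping_file",
    "TRANSFORMS",
    "RDF_TYPE",
]

RDF_TYPE = "rdf:type"


class SourceError(RuntimeError):
    """The source SQL query failed or referenced a missing table."""


class TemplateError(ValueError):
    """A target template placeholder does not resolve to a source column."""


class TransformError(ValueError):
    """A post-processing transform rejected a bound value."""


@dataclass(frozen=True, order=True)
class Lit:
    """A typed RDF literal. ``dtype`` in {string, integer, decimal, date}."""

    value: Any
    dtype: str = "string"

    def __str__(self) -> str:  # canonical lexical form, used for sorting
        return f"{self.value}"


#: Triple terms: IRIs are plain namespaced strings, literals are Lit.
Term = Union[str, Lit]
RDFTriple = tuple[Term, str, Term]


# ---------------------------------------------------------------------------
# Data sources
# ---------------------------------------------------------------------------


class DataSourceDecl:
    """A declared relational source: an id, a SQL connection, a catalog."""

    def __init__(self, source_id: str, connection: sqlite3.Connection):
        self.source_id = source_id
        self.connection = connection
        self.table_catalog = self._introspect()

    def _introspect(self) -> dict[str, list[str]]:
        cur = self.connection.execute(
            "SELECT name FROM sqlite_master WHERE type='table'"
        )
        catalog = {}
        for (name,) in cur.fetchall():
            cols = self.connection.execute(f'PRAGMA table_info("{name}")')
            catalog[name] = [c[1] for c in cols.fetchall()]
        return catalog

    def query(self, sql: str) -> pd.DataFrame:
        try:
            return pd.read_sql_query(sql, self.connection)
        except Exception as exc:  # surfaced with source context
            raise SourceError(f"[{self.source_id}] {exc}") from exc

    # -- constructors --------------------------------------------------

    @classmethod
    def from_sqlite(cls, path: Union[str, Path],
                    source_id: str = "db") -> "DataSourceDecl":
        conn = sqlite3.connect(str(path))
        return cls(source_id, conn)

    @classmethod
    def from_dataframes(cls, tables: Mapping[str, pd.DataFrame],
                        source_id: str = "mem") -> "DataSourceDecl":
        conn = sqlite3.connect(":memory:")
        for name, df in tables.items():
            df.to_sql(name, conn, index=False)
        return cls(source_id, conn)

    @classmethod
    def from_csv_dir(cls, directory: Union[str, Path],
                     source_id: str = "csv") -> "DataSourceDecl":
        directory = Path(directory)
        tables = {
            p.stem: pd.read_csv(p, dtype={"county_fips": str,
                                          "tract_geoid": str,
                                          "diagnosis_date": str})
            for p in sorted(directory.glob("*.csv"))
        }
        if not tables:
            raise SourceError(f"no CSV tables found in {directory}")
        return cls.from_dataframes(tables, source_id=source_id)


# ---------------------------------------------------------------------------
# Mapping axioms and templates
# ---------------------------------------------------------------------------

# Template tokens: <iri possibly with {placeholders}>, "literal"^^tag,
# or the bare rdf:type keyword.
_TOKEN_RE = re.compile(
    r"<(?P<iri>[^<>]+)>"
    r'|"(?P<lit>[^"]*)"(?:\^\^(?P<tag>\w+))?'
    r"|(?P<kw>rdf:type)"
)
_PLACEHOLDER_RE = re.compile(r"\{(\w+)\}")


def _parse_template(template: str) -> list[tuple]:
    """Parse a target template into a list of 3-term token triples."""
    triples = []
    for chunk in template.split(" . "):
        chunk = chunk.strip().rstrip(".").strip()
        if not chunk:
            continue
        terms = []
        for m in _TOKEN_RE.finditer(chunk):
            if m.group("iri") is not None:
                terms.append(("iri", m.group("iri")))
            elif m.group("kw") is not None:
                terms.append(("iri", RDF_TYPE))
            else:
                terms.append(("lit", m.group("lit"), m.group("tag") or "string"))
        if len(terms) != 3:
            raise TemplateError(f"template triple is not 3 terms: {chunk!r}")
        triples.append(tuple(terms))
    if not triples:
        raise TemplateError(f"empty target template: {template!r}")
    return triples


@dataclass(frozen=True)
class MappingAxiom:
    """One (mappingId, source SQL, target template) mapping axiom."""

    mapping_id: str
    source_query: str
    target_template: str
    axiom_kind: str = ""  # inferred from the template when empty
    source_id: str = ""  # data-source key; blank = the sole/default source

    def parsed_target(self) -> list[tuple]:
        return _parse_template(self.target_template)

    def placeholders(self) -> set[str]:
        return set(_PLACEHOLDER_RE.findall(self.target_template))

    def kind(self) -> str:
        if self.axiom_kind:
            return self.axiom_kind
        first = self.parsed_target()[0]
        pred = first[1]
        if pred[0] == "iri" and pred[1] == RDF_TYPE:
            return "class_assertion"
        return "data_property" if first[2][0] == "lit" else "object_property"


def _coerce_literal(value: Any, tag: str) -> Any:
    if tag == "integer":
        return int(value)
    if tag == "decimal":
        return float(value)
    return str(value)


def instantiate_axiom(axiom: MappingAxiom,
                      source: DataSourceDecl) -> set[RDFTriple]:
    """Execute one axiom: one substituted triple set per SQL result row.

    Rows with a NULL in any referenced placeholder column produce no triple
    (the standard relational-to-RDF convention).
    """
    rows = source.query(axiom.source_query)
    missing = axiom.placeholders() - set(rows.columns)
    if missing:
        raise TemplateError(
            f"[{axiom.mapping_id}] placeholders {sorted(missing)} not in "
            f"source query columns {list(rows.columns)}"
        )
    parsed = axiom.parsed_target()
    out: set[RDFTriple] = set()
    for row in rows.itertuples(index=False):
        values = dict(zip(rows.columns, row))
        if any(pd.isna(values[ph]) for ph in axiom.placeholders()):
            continue
        for trip in parsed:
            terms: list[Term] = []
            for tok in trip:
                if tok[0] == "iri":
                    terms.append(tok[1].format(**values))
                else:
                    terms.append(
                        Lit(_coerce_literal(tok[1].format(**values), tok[2]),
                            tok[2])
                    )
            out.add((terms[0], terms[1], terms[2]))
    return out


# ---------------------------------------------------------------------------
# Virtual graph
# ---------------------------------------------------------------------------


class VirtualGraph:
    """The materialized triple set, with provenance and lookup indexes."""

    def __init__(self) -> None:
        self.triples: set[RDFTriple] = set()
        self.provenance: dict[RDFTriple, str] = {}
        self._by_p: dict[str, list[RDFTriple]] = {}
        self._by_ps: dict[tuple, list[Term]] = {}
        self._by_po: dict[tuple, list[Term]] = {}
        self._types: dict[str, set[Term]] = {}  # class -> subjects

    def add(self, triple: RDFTriple, mapping_id: str = "") -> None:
        if triple in self.triples:
            return
        s, p, o = triple
        self.triples.add(triple)
        if mapping_id:
            self.provenance[triple] = mapping_id
        self._by_p.setdefault(p, []).append(triple)
        self._by_ps.setdefault((p, s), []).append(o)
        self._by_po.setdefault((p, o), []).append(s)
        if p == RDF_TYPE:
            self._types.setdefault(o, set()).add(s)  # type: ignore[arg-type]

    def __len__(self) -> int:
        return len(self.triples)

    def __contains__(self, triple: RDFTriple) -> bool:
        return triple in self.triples

    def subjects_of_class(self, cls: str) -> set[Term]:
        return self._types.get(cls, set())

    def objects(self, subject: Term, predicate: str) -> list[Term]:
        return self._by_ps.get((predicate, subject), [])

    def subjects(self, predicate: str, obj: Term) -> list[Term]:
        return self._by_po.get((predicate, obj), [])

    def with_predicate(self, predicate: str) -> list[RDFTriple]:
        return self._by_p.get(predicate, [])


def materialize(
    obda_model: Sequence[MappingAxiom],
    sources: Union[DataSourceDecl, Mapping[str, DataSourceDecl]],
) -> VirtualGraph:
    """Union of :func:`instantiate_axiom` over all axioms.

    ``sources`` may be a single declaration (all axioms run against it) or
    a mapping keyed by source id.  The triple set is independent of axiom
    order; for a triple emitted by several axioms, provenance records the
    lexicographically first mapping id (deterministic).
    """
    ids = [a.mapping_id for a in obda_model]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mapping_id in OBDA model")
    graph = VirtualGraph()
    produced: dict[RDFTriple, str] = {}
    for axiom in sorted(obda_model, key=lambda a: a.mapping_id):
        if isinstance(sources, DataSourceDecl):
            src = sources
        else:
            src = sources[axiom.source_id or next(iter(sources))]
        try:
            triples = instantiate_axiom(axiom, src)
        except (SourceError, TemplateError):
            raise
        except Exception as exc:
            raise SourceError(f"[{axiom.mapping_id}] {exc}") from exc
        for t in triples:
            graph.add(t, axiom.mapping_id)
    return graph


# ---------------------------------------------------------------------------
# BGP query answering
# ---------------------------------------------------------------------------


def _tf_year(value: Any) -> int:
    """Extract the year from an 8-digit yyyymmdd date string."""
    s = str(value)
    if not re.fullmatch(r"\d{8}", s):
        raise TransformError(f"malformed yyyymmdd date: {value!r}")
    return int(s[:4])


def _tf_localname(value: Any) -> str:
    """Trailing path segment of a minted individual IRI (its source key)."""
    return str(value).rsplit("/", 1)[-1]


TRANSFORMS: dict[str, Callable[[Any], Any]] = {
    "year": _tf_year,
    "localname": _tf_localname,
}

_FILTER_OPS: dict[str, Callable[[Any, Any], bool]] = {
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


def _is_var(term: Any) -> bool:
    return isinstance(term, str) and term.startswith(("?", "$"))


@dataclass(frozen=True)
class BGPQuery:
    """A conjunctive basic graph pattern with filters and transforms.

    ``patterns`` terms are IRIs (plain strings), :class:`Lit` literals, or
    variables (strings prefixed ``?`` or ``$``).  ``transforms`` maps a
    variable to a named post-processing tag (``year``, ``localname``);
    ``filters`` are ``(variable, op, value)`` comparisons applied to bound
    literal values after matching.
    """

    select_vars: tuple[str, ...]
    patterns: tuple[tuple[Term, Term, Term], ...]
    transforms: Mapping[str, str] = field(default_factory=dict)
    filters: tuple[tuple[str, str, Any], ...] = ()

    def __post_init__(self) -> None:
        pattern_vars = {
            t for pat in self.patterns for t in pat if _is_var(t)
        }
        for v in self.select_vars:
            if v not in pattern_vars:
                raise ValueError(f"select variable {v} not in any pattern")


def _pattern_candidates(
    pat: tuple, binding: dict, graph: VirtualGraph, ontology: Optional[Ontology]
) -> Iterable[RDFTriple]:
    """Triples that could match ``pat`` under ``binding`` (index-driven)."""
    s, p, o = (binding.get(t, t) if _is_var(t) else t for t in pat)
    s_bound, p_bound, o_bound = (not _is_var(t) for t in (s, p, o))
    if p_bound and p == RDF_TYPE and o_bound and isinstance(o, str):
        classes: Iterable[str]
        if ontology is not None and o in ontology.classes:
            classes = sorted(subclass_descendants(ontology, o))
        else:
            classes = [o]
        for cls in classes:
            for subj in graph.subjects_of_class(cls):
                if not s_bound or subj == s:
                    yield (subj, RDF_TYPE, o)
        return
    if p_bound and s_bound:
        for obj in graph.objects(s, p):
            if not o_bound or obj == o:
                yield (s, p, obj)
        return
    if p_bound and o_bound:
        for subj in graph.subjects(p, o):
            yield (subj, p, o)
        return
    if p_bound:
        yield from graph.with_predicate(p)
        return
    yield from graph.triples  # unbound predicate: full scan


def answer(
    query: BGPQuery,
    graph: VirtualGraph,
    ontology: Optional[Ontology] = None,
    flags: Optional[list] = None,
) -> pd.DataFrame:
    """Answer a BGP query over the materialized graph.

    Returns a deduplicated DataFrame, one column per select variable
    (leading ``?`` stripped), rows sorted canonically.  ``rdf:type``
    patterns are subclass-expanded through the ontology.  A transform that
    rejects a value (e.g. a malformed date) yields a null cell and, when
    ``flags`` is a list, an appended flag record — flagged rows are
    surfaced, never silently dropped.
    """
    bindings: list[dict] = [{}]
    for pat in query.patterns:
        nxt: list[dict] = []
        for b in bindings:
            for s, p, o in _pattern_candidates(pat, b, graph, ontology):
                nb = b
                ok = True
                for term, val in zip(pat, (s, p, o)):
                    if _is_var(term):
                        bound = nb.get(term)
                        if bound is None:
                            if nb is b:
                                nb = dict(b)
                            nb[term] = val
                        elif bound != val:
                            ok = False
                            break
                if ok:
                    nxt.append(nb)
        bindings = nxt
        if not bindings:
            break

    for var, op, value in query.filters:
        fn = _FILTER_OPS[op]
        bindings = [
            b for b in bindings
            if var in b and _filter_value(b[var]) is not None
            and fn(_filter_value(b[var]), value)
        ]

    rows = []
    for b in bindings:
        row = {}
        flagged = None
        for v in query.select_vars:
            val = b.get(v)
            if isinstance(val, Lit):
                val = val.value
            tag = query.transforms.get(v)
            if tag is not None and val is not None:
                try:
                    val = TRANSFORMS[tag](val)
                except TransformError as exc:
                    flagged = {"variable": v, "value": val, "reason": str(exc),
                               "binding": {k: str(x) for k, x in b.items()}}
                    val = None
            row[v.lstrip("?$")] = val
        if flagged is not None and flags is not None:
            flags.append(flagged)
        rows.append(row)

    cols = [v.lstrip("?$") for v in query.select_vars]
    table = pd.DataFrame(rows, columns=cols).drop_duplicates()
    table = table.sort_values(
        by=cols, key=lambda s: s.map(str), kind="mergesort"
    ).reset_index(drop=True)
    return table


def _filter_value(val: Any) -> Any:
    return val.value if isinstance(val, Lit) else val


# ---------------------------------------------------------------------------
# Closed-world restriction checking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One failed allValuesFrom check on one individual/value pair."""

    individual: str
    on_class: str
    on_property: str
    value: str


def check_restrictions(graph: VirtualGraph,
                       ontology: Ontology) -> list[Violation]:
    """Enforce every allValuesFrom restriction against the graph.

    Closed world: for each individual asserted in a restricted class (or a
    subclass of it), every asserted value of the restricted property must
    itself be asserted in the filler class (or a subclass).  An individual
    with no value for the property passes vacuously.  An empty return means
    the graph is consistent with all restrictions.
    """
    violations: list[Violation] = []
    for r in ontology.restrictions:
        filler_ok = subclass_descendants(ontology, r.filler_class)
        members: set[Term] = set()
        for cls in subclass_descendants(ontology, r.on_class):
            members |= graph.subjects_of_class(cls)
        for ind in sorted(members, key=str):
            for value in graph.objects(ind, r.on_property):
                in_filler = isinstance(value, str) and any(
                    (value, RDF_TYPE, c) in graph for c in filler_ok
                )
                if not in_filler:
                    violations.append(
                        Violation(str(ind), r.on_class, r.on_property,
                                  str(value))
                    )
    return sorted(violations, key=lambda v: (v.individual, v.on_class,
                                             v.on_property, v.value))


# ---------------------------------------------------------------------------
# Mapping-file round trip (Ontop-like text format)
# ---------------------------------------------------------------------------


def write_mapping_file(axioms: Sequence[MappingAxiom],
                       path: Union[str, Path]) -> None:
    """Write axioms as blank-line-separated mappingId/source/target blocks."""
    blocks = []
    for a in axioms:
        blocks.append(
            f"mappingId\t{a.mapping_id}\n"
            f"source\t\t{a.source_query}\n"
            f"target\t\t{a.target_template}\n"
        )
    Path(path).write_text("\n".join(blocks))


def parse_mapping_file(path: Union[str, Path]) -> list[MappingAxiom]:
    """Parse the text mapping format written by :func:`write_mapping_file`."""
    axioms = []
    for block in Path(path).read_text().split("\n\n"):
        if not block.strip():
            continue
        fields = {}
        for line in block.splitlines():
            if not line.strip():
                continue
            key, _, value = line.partition("\t")
            fields[key.strip()] = value.strip()
        try:
            axioms.append(
                MappingAxiom(
                    mapping_id=fields["mappingId"],
                    source_query=fields["source"],
                    target_template=fields["target"],
                )
            )
        except KeyError as exc:
            raise TemplateError(f"mapping block missing field {exc}") from exc
    return axioms
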