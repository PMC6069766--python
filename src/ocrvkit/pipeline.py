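"""End-to-end integration: sources -> virtual graph -> pooled matrix.

The pipeline runs the integration steps in order: (1) connect the engine
to the ontology, mapping model and relational sources; (2) list all
diagnosis records and use the patient identifier as the first column of
the final dataset; (3) execute the per-factor semantic queries and append
each result to the corresponding records; (4) compute and attach the
derived county aggregates; (5) run the consistency checks under the
configured policy; (6) write the final dataset as CSV.

The output matrix has **one row per cancer diagnosis record** (a patient
with two diagnoses contributes two rows) and one column per selected risk
factor, headed by the patient identifier.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .measures import county_rates_table
from .obda import BGPQuery, DataSourceDecl, RDF_TYPE, VirtualGraph, answer, materialize
from .ontology import Ontology, build_ocrv
from .qc import QCFinding, consistency_report, findings_frame
from .queries import (
    QUERY_CATALOG,
    CatalogError,
    QuerySpec,
    default_obda_model,
    display_name,
    regroup_ruca,
    run_query,
)
from .sources import SourceConfig, SyntheticData, generate_all

__all__ = [
    "RunConfig",
    "PooledResult",
    "PipelineError",
    "build_pooled_dataset",
    "write_output",
    "DEFAULT_FACTORS",
]

log = logging.getLogger("ocrvkit")


class PipelineError(RuntimeError):
    """Fatal pipeline condition (missing source table, catalog gap)."""


#: The example factor selection producing the published matrix layout:
#: patient id, sex, marital status, year of diagnosis, ..., SVI
#: socioeconomic status, survival.
DEFAULT_FACTORS: tuple[str, ...] = (
    "sex",
    "marital_status",
    "year_of_diagnosis",
    "svi_socioeconomic",
    "survival_months",
)

_REQUIRED_TABLES = ("registry", "brfss", "svi", "census", "ruca",
                    "county_health")


@dataclass
class RunConfig:
    """Everything one integration run needs.

    ``source`` is a SQLite file, a directory of CSV tables, or an
    in-memory :class:`~ocrvkit.sources.SyntheticData`; when ``generate``
    is set the sources are generated fresh from ``(generate, seed)``.
    """

    source: Union[str, Path, SyntheticData, None] = None
    generate: Optional[SourceConfig] = None
    seed: int = 0
    factors: Sequence[str] = DEFAULT_FACTORS
    rurality_scheme: str = "ruca"  # "ruca" | "nchs"
    ruca_grouping: Optional[Mapping[int, str]] = None
    nchs_codes: Optional[Mapping[str, str]] = None  # county fips -> label
    drop_on_error: bool = False
    age_tolerance: int = 0
    output: Optional[Union[str, Path]] = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generate", None)
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        if gen is not None:
            gen = dict(gen)
            for key in ("county_names",):
                if key in gen:
                    gen[key] = tuple(gen[key])
            cfg.generate = SourceConfig(**gen)
        if cfg.ruca_grouping is not None:
            cfg.ruca_grouping = {int(k): v
                                 for k, v in cfg.ruca_grouping.items()}
        return cfg


@dataclass
class PooledResult:
    """The pooled matrix plus everything the run produced along the way."""

    matrix: pd.DataFrame
    qc_findings: list[QCFinding]
    county_rates: pd.DataFrame
    query_flags: list[dict] = field(default_factory=list)
    graph: Optional[VirtualGraph] = None


def _connect(config: RunConfig) -> tuple[DataSourceDecl, dict[str, pd.DataFrame]]:
    if config.generate is not None:
        data = generate_all(config.generate, config.seed)
        source = DataSourceDecl.from_dataframes(data.tables())
    elif isinstance(config.source, SyntheticData):
        source = DataSourceDecl.from_dataframes(config.source.tables())
    elif config.source is not None:
        p = Path(config.source)
        source = (
            DataSourceDecl.from_csv_dir(p)
            if p.is_dir()
            else DataSourceDecl.from_sqlite(p)
        )
    else:
        raise PipelineError("RunConfig needs either source or generate")
    missing = [t for t in _REQUIRED_TABLES if t not in source.table_catalog]
    if missing:
        raise PipelineError(f"missing source tables: {missing}")
    tables = {
        t: source.query(f"SELECT * FROM {t}") for t in _REQUIRED_TABLES
    }
    return source, tables


def _resolve_spec(name: str, config: RunConfig) -> QuerySpec:
    spec = QUERY_CATALOG.get(name)
    if spec is None:
        raise PipelineError(
            f"no query specification for selected factor {name!r}"
        )
    if name == "rurality":
        if config.rurality_scheme == "nchs":
            if not config.nchs_codes:
                raise PipelineError(
                    "rurality_scheme 'nchs' needs a county code table "
                    "(nchs_codes)"
                )
            county_spec = QUERY_CATALOG["county"]
            codes = dict(config.nchs_codes)
            return replace(
                county_spec, name="rurality",
                post_map=lambda fips: codes.get(str(fips)),
            )
        if config.ruca_grouping is not None:
            grouping = dict(config.ruca_grouping)
            from .queries import _RUCA_CODE_BY_CLASS, _label

            return replace(
                spec,
                post_map=lambda cls: regroup_ruca(
                    _RUCA_CODE_BY_CLASS[_label(cls)], grouping
                ),
            )
    return spec


def build_pooled_dataset(config: RunConfig) -> PooledResult:
    """Run the full integration and return the pooled analytic matrix.

    The matrix keys on the diagnosis record: its first column is the
    patient identifier, followed by one column per selected factor under
    its display header.  Left joins onto the record spine are checked to
    preserve cardinality — pooling can neither drop nor duplicate spine
    rows.
    """
    unknown = [f for f in config.factors if f not in QUERY_CATALOG]
    if unknown:
        raise PipelineError(f"factors without a query spec: {unknown}")

    log.info("step 1: connecting sources and materializing the graph")
    source, tables = _connect(config)
    ontology = build_ocrv()
    graph = materialize(default_obda_model(), source)
    log.info("materialized %d triples", len(graph))

    log.info("step 2: listing diagnosis records (patient spine)")
    spine_q = BGPQuery(
        select_vars=("?p", "?d", "?date"),
        patterns=(
            ("?p", RDF_TYPE, "ncit:patient"),
            ("?p", "ocrv:has diagnosis", "?d"),
            ("?d", "teo:hasValidTime", "?t"),
            ("?t", "teo:hasOrigTime", "?date"),
        ),
        transforms={"?p": "localname", "?d": "localname"},
    )
    spine = answer(spine_q, graph, ontology).rename(
        columns={"p": "patient_id", "d": "record_id",
                 "date": "diagnosis_date"}
    )
    spine["patient_id"] = spine["patient_id"].astype(int)
    spine["record_id"] = spine["record_id"].astype(int)
    spine = spine.sort_values(
        ["patient_id", "diagnosis_date", "record_id"], kind="mergesort"
    ).reset_index(drop=True)

    log.info("step 3/4: executing %d factor queries", len(config.factors))
    flags: list[dict] = []
    county_rates = county_rates_table(tables["brfss"])
    matrix = spine[["patient_id", "record_id", "diagnosis_date"]].copy()
    for name in config.factors:
        spec = _resolve_spec(name, config)
        if spec.query_type == "derived":
            county = run_query(QUERY_CATALOG["county"], graph, ontology)
            rates = county_rates[county_rates["measure"] == spec.measure]
            col = county.merge(
                rates[["county_fips", "rate"]],
                left_on="county", right_on="county_fips", how="left",
            )[["patient_id", "rate"]].rename(columns={"rate": name})
            key = "patient_id"
        else:
            col = run_query(spec, graph, ontology, flags=flags)
            key = col.columns[0]
        before = len(matrix)
        matrix = matrix.merge(col, on=key, how="left")
        if len(matrix) != before:
            raise PipelineError(
                f"join for factor {name!r} changed spine cardinality "
                f"({before} -> {len(matrix)})"
            )

    log.info("step 5: consistency checks")
    findings = consistency_report(
        tables["registry"], tables["county_health"],
        age_tolerance=config.age_tolerance,
    )
    if config.drop_on_error:
        bad = {
            int(f.record_key.split("/", 1)[1])
            for f in findings
            if f.severity == "error" and f.record_key.startswith("registry/")
        }
        matrix = matrix[~matrix["record_id"].isin(bad)].reset_index(drop=True)
        log.info("dropped %d records with error findings", len(bad))

    matrix = matrix.drop(columns=["record_id", "diagnosis_date"])
    matrix.columns = ["Patient ID"] + [display_name(f)
                                       for f in config.factors]

    result = PooledResult(matrix, findings, county_rates, flags, graph)
    log.info("step 6: output")
    if config.output is not None:
        write_output(matrix, config.output)
    return result


def write_output(table: pd.DataFrame, path: Union[str, Path],
                 fmt: str = "csv") -> None:
    """Write the pooled matrix as CSV (header + one line per record)."""
    if fmt != "csv":
        raise PipelineError(f"unsupported output format: {fmt}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
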