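"""Ontology-driven data quality and consistency checks.

The ontology makes dependencies between registry variables explicit — age
at diagnosis is derivable from diagnosis date and birth year — so recorded
values can be checked against computed ones.  Checks implemented:

``age_mismatch``
    recorded age at diagnosis differs from ``year(diagnosis_date) -
    birth_year`` by more than the configured tolerance (default 0; the
    registry carries birth *year* only, so the year-difference convention
    is used throughout, including by the synthetic generator).
``malformed_date``
    diagnosis date is not an 8-digit ``yyyymmdd`` string parsing as a real
    calendar date.
``impossible_chronology``
    birth year later than the diagnosis year.
``adult_filter``
    computed age under 18 (the study includes adults only) — a warning,
    since dropping is a pipeline policy, not a fact about the record.
``code_format``
    ICD-O-3 topography code not matching ``C\\d\\d(.\\d)?``.
``out_of_range``
    county unhealthy-days measures outside [0, 30].

Findings never mutate data; downstream filtering is an explicit pipeline
option.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict
from datetime import date
from typing import Optional

import pandas as pd

__all__ = [
    "QCFinding",
    "ChronologyError",
    "MalformedDateError",
    "computed_age",
    "consistency_report",
    "findings_frame",
]

_DATE_RE = re.compile(r"\d{8}")
_ICDO3_RE = re.compile(r"C\d\d(\.\d)?")


class MalformedDateError(ValueError):
    """Diagnosis date is not a valid yyyymmdd calendar date."""


class ChronologyError(ValueError):
    """Birth year later than diagnosis year."""


@dataclass(frozen=True)
class QCFinding:
    """One concrete finding on one record."""

    record_key: str
    check_id: str
    detail: str
    severity: str  # "error" | "warning"


def _parse_yyyymmdd(value: str) -> date:
    s = str(value)
    if not _DATE_RE.fullmatch(s):
        raise MalformedDateError(f"not an 8-digit yyyymmdd date: {value!r}")
    try:
        return date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError as exc:
        raise MalformedDateError(f"invalid calendar date: {value!r}") from exc


def computed_age(birth_year: int, diagnosis_date: str) -> int:
    """Age at diagnosis by the year-difference convention.

    ``year(diagnosis_date) - birth_year``; the registry does not carry
    birth month/day.  Raises :class:`MalformedDateError` on a bad date and
    :class:`ChronologyError` when the birth year postdates the diagnosis.
    """
    dx = _parse_yyyymmdd(diagnosis_date)
    age = dx.year - int(birth_year)
    if age < 0:
        raise ChronologyError(
            f"birth year {birth_year} after diagnosis year {dx.year}"
        )
    return age


def consistency_report(
    registry: pd.DataFrame,
    county_health: Optional[pd.DataFrame] = None,
    age_tolerance: int = 0,
) -> list[QCFinding]:
    """Deterministic, exhaustive findings over the registry (and counties).

    Pure function of its inputs: identical calls return identical finding
    lists, sorted by record key then check id.
    """
    findings: list[QCFinding] = []
    for row in registry.itertuples(index=False):
        key = f"registry/{row.record_id}"
        code = str(row.icdo3_site)
        if not _ICDO3_RE.fullmatch(code):
            findings.append(
                QCFinding(key, "code_format",
                          f"expected C##(.#), observed {code!r}", "error")
            )
        try:
            age = computed_age(row.birth_year, row.diagnosis_date)
        except MalformedDateError as exc:
            findings.append(QCFinding(key, "malformed_date", str(exc),
                                      "error"))
            continue
        except ChronologyError as exc:
            findings.append(
                QCFinding(key, "impossible_chronology", str(exc), "error")
            )
            continue
        if abs(int(row.age_at_diagnosis) - age) > age_tolerance:
            findings.append(
                QCFinding(
                    key,
                    "age_mismatch",
                    f"expected {age}, observed {int(row.age_at_diagnosis)}",
                    "error",
                )
            )
        if age < 18:
            findings.append(
                QCFinding(key, "adult_filter",
                          f"computed age {age} under adult threshold 18",
                          "warning")
            )
    if county_health is not None:
        for row in county_health.itertuples(index=False):
            key = f"county_health/{row.county_fips}"
            for col in ("mental_unhealthy_days", "physical_unhealthy_days"):
                v = float(getattr(row, col))
                if not 0.0 <= v <= 30.0:
                    findings.append(
                        QCFinding(key, "out_of_range",
                                  f"{col} expected in [0, 30], observed {v}",
                                  "error")
                    )
    return sorted(findings, key=lambda f: (f.record_key, f.check_id, f.detail))


def findings_frame(findings: list[QCFinding]) -> pd.DataFrame:
    """Findings as a DataFrame (one row per finding) for CSV export."""
    cols = ["record_key", "check_id", "detail", "severity"]
    return pd.DataFrame([asdict(f) for f in findings], columns=cols)
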