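"""Survey-weighted contextual aggregates.

The county-level behavioral measures are computed outside the ontology:
for each county, the weighted rate equals the sum of survey final weights
over qualifying respondents divided by the sum of final weights over all
eligible respondents in the county.  The survey's final weight is the
product of its design weight and raking adjustment.

Eligibility convention: respondents with a missing item needed by the
qualifier (smoking-status items for the smoking rate) are excluded from
both numerator and denominator; pass ``include_missing_in_denominator=True``
for the denominator-inclusive alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import pandas as pd

__all__ = [
    "CountyRate",
    "MeasureError",
    "final_weight",
    "classify_heavy_drinker",
    "is_current_smoker",
    "county_weighted_rate",
    "county_rates_table",
]


class MeasureError(ValueError):
    """Invalid input to a derived-measure computation."""


@dataclass(frozen=True)
class CountyRate:
    county_fips: str
    measure: str  # "smoking" | "heavy_drinking"
    numerator_weight: float
    denominator_weight: float
    rate: float


def final_weight(design_weight: float, raking_adjustment: float) -> float:
    """Survey final weight = design weight x raking adjustment (exact)."""
    if design_weight <= 0 or raking_adjustment <= 0:
        raise MeasureError("weights must be positive")
    return design_weight * raking_adjustment


def classify_heavy_drinker(sex: str, drinks_per_week: float) -> bool:
    """Sex-specific heavy-drinking rule, strict thresholds.

    True iff a male reports more than 14 drinks per week or a female more
    than 7.
    """
    if drinks_per_week < 0:
        raise MeasureError("drinks_per_week must be non-negative")
    if sex == "male":
        return drinks_per_week > 14
    if sex == "female":
        return drinks_per_week > 7
    raise MeasureError(f"unknown sex category: {sex!r}")


def is_current_smoker(smokday2: str, smoke100: str) -> bool:
    """The two-condition survey current-smoker rule.

    A current smoker (1) now smokes every day or some days, and (2) has
    smoked at least 100 cigarettes in their entire life.
    """
    return smokday2 in ("every day", "some days") and smoke100 == "yes"


def county_weighted_rate(
    respondents: pd.DataFrame,
    qualifier: Callable[[pd.Series], bool],
    county_fips: str,
    measure: str = "custom",
    eligible: Optional[Callable[[pd.Series], bool]] = None,
) -> CountyRate:
    """Weighted rate for one county.

    ``rate = sum(final_weight | qualifier) / sum(final_weight | eligible)``
    over the county's respondents.  ``eligible`` defaults to everyone;
    an empty denominator raises :class:`MeasureError`.
    """
    rows = respondents[respondents["county_fips"] == county_fips]
    if eligible is not None:
        rows = rows[rows.apply(eligible, axis=1)]
    denom = float(rows["final_weight"].sum())
    if denom <= 0:
        raise MeasureError(f"undefined rate: county {county_fips} has no "
                           "eligible respondents")
    qualifies = rows.apply(qualifier, axis=1)
    num = float(rows.loc[qualifies, "final_weight"].sum())
    return CountyRate(county_fips, measure, num, denom, num / denom)


def _smoking_eligible(row: pd.Series) -> bool:
    return row["smokday2"] != "missing" and row["smoke100"] != "missing"


def county_rates_table(
    respondents: pd.DataFrame,
    measures: tuple[str, ...] = ("smoking", "heavy_drinking"),
    include_missing_in_denominator: bool = False,
) -> pd.DataFrame:
    """Weighted smoking / heavy-drinking rates for every county present.

    Returns one row per (county, measure) with numerator, denominator and
    rate, sorted by county then measure.
    """
    spec: dict[str, tuple] = {
        "smoking": (
            lambda r: is_current_smoker(r["smokday2"], r["smoke100"]),
            None if include_missing_in_denominator else _smoking_eligible,
        ),
        "heavy_drinking": (
            lambda r: classify_heavy_drinker(r["sex"], r["drinks_per_week"]),
            None,
        ),
    }
    out = []
    for cf in sorted(respondents["county_fips"].unique()):
        for m in measures:
            qualifier, eligible = spec[m]
            cr = county_weighted_rate(respondents, qualifier, cf, m, eligible)
            out.append(
                {
                    "county_fips": cr.county_fips,
                    "measure": cr.measure,
                    "rate": cr.rate,
                    "numerator_weight": cr.numerator_weight,
                    "denominator_weight": cr.denominator_weight,
                }
            )
    return pd.DataFrame(out)
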