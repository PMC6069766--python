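"""Seeded synthetic source tables for the five emulated data systems.

Real multi-level cancer-survival integration draws on a restricted state
cancer registry, a weighted behavioral telephone survey, tract-level social
vulnerability and census tables, tract rurality codes, and county health
rankings.  None of those can ship with a desk-scale artifact, so this
module generates structurally faithful stand-ins with *planted ground
truth*: the per-county smoking and heavy-drinking rates used in generation,
the list of deliberately inconsistent age-at-diagnosis records, and the
per-cancer-type counts are all recorded in a :class:`TruthBundle` so every
downstream stage (weighted rates, reasoned queries, QC) can be checked
against a known answer.

Everything is a pure function of ``(config, seed)``: identical inputs give
byte-identical output tables.

Default study conditions
------------------------
The defaults mirror the emulated study: a 20-county north-Florida
catchment, a 1996–2010 registry of 50,151 patients with the reported
breast/lung/colorectal mix (18,644 / 21,552 / 9,955), ICD-O-3 inclusion
codes only, the 7 raw marital categories, and a survey of 5,000
respondents per county with planted county smoking rates spread over
0.05–0.40.  Geographic codes are synthetic FIPS-style identifiers (state
prefix ``12``); the tract GEOID embeds its county code, which is the
linkage key the integration relies on.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "SourceConfig",
    "TruthBundle",
    "SyntheticData",
    "ConfigError",
    "CATCHMENT_COUNTIES",
    "BREAST_SITES",
    "LUNG_SITES",
    "COLORECTAL_SITES",
    "MARITAL_CATEGORIES",
    "gen_catchment",
    "gen_registry",
    "gen_brfss",
    "gen_contextual",
    "gen_county_health",
    "generate_all",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


#: The 20-county catchment area, alphabetical as published.
CATCHMENT_COUNTIES: tuple[str, ...] = (
    "Alachua", "Baker", "Bradford", "Citrus", "Clay", "Columbia", "Dixie",
    "Gilchrist", "Hamilton", "Jefferson", "Lafayette", "Leon", "Levy",
    "Madison", "Marion", "Putnam", "Sumter", "Suwannee", "Taylor", "Union",
)

#: ICD-O-3 topography inclusion codes per cancer type.
BREAST_SITES = tuple(f"C50.{i}" for i in range(10))
LUNG_SITES = ("C34.0", "C34.1", "C34.2", "C34.3", "C34.8", "C34.9")
COLORECTAL_SITES = tuple(f"C18.{i}" for i in range(10)) + ("C26.0",)

#: The 7 raw registry marital-status categories.
MARITAL_CATEGORIES: tuple[str, ...] = (
    "never married", "divorced", "widowed", "separated", "married",
    "unknown", "unmarried",
)

# Registry counts of the emulated study: 18,644 breast / 21,552 lung /
# 9,955 colorectal of 50,151 patients.
_DEFAULT_N_PATIENTS = 50151
_DEFAULT_MIX = {
    "breast": 18644 / 50151,
    "lung": 21552 / 50151,
    "colorectal": 9955 / 50151,
}

# SVI theme composition: 15 factors in 4 themes
# (socioeconomic 4, household composition & disability 4,
#  minority status & language 2, housing & transportation 5).
SVI_THEME_SLICES = {
    "socioeconomic": slice(0, 4),
    "household": slice(4, 8),
    "minority": slice(8, 10),
    "housing": slice(10, 15),
}


@dataclass
class SourceConfig:
    """All knobs of the synthetic generators, with study-condition defaults."""

    county_names: tuple[str, ...] = CATCHMENT_COUNTIES
    tracts_per_county: int = 4
    # registry
    n_patients: int = _DEFAULT_N_PATIENTS
    cancer_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    marital_probs: dict = field(default_factory=lambda: {
        "never married": 0.12, "divorced": 0.12, "widowed": 0.12,
        "separated": 0.03, "married": 0.50, "unknown": 0.06,
        "unmarried": 0.05,
    })
    diagnosis_years: tuple[int, int] = (1996, 2010)
    inconsistency_rate: float = 0.02
    underage_rate: float = 0.0
    multi_diagnosis_rate: float = 0.05
    # survey
    brfss_n_per_county: int = 5000
    smoking_rates: Optional[Sequence[float]] = None  # default: 0.05..0.40
    heavy_drinking_rates: Optional[Sequence[float]] = None  # default 0.05..0.25
    missing_rate: float = 0.02

    def validate(self) -> None:
        if self.tracts_per_county < 1:
            raise ConfigError("tracts_per_county must be >= 1")
        if abs(sum(self.cancer_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("cancer_mix probabilities must sum to 1")
        if set(self.cancer_mix) - {"breast", "lung", "colorectal"}:
            raise ConfigError("cancer_mix keys must be breast/lung/colorectal")
        if abs(sum(self.marital_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("marital_probs must sum to 1")
        if set(self.marital_probs) - set(MARITAL_CATEGORIES):
            raise ConfigError("unknown marital category in marital_probs")
        for name in ("inconsistency_rate", "underage_rate",
                     "multi_diagnosis_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for rates in (self.smoking_rates, self.heavy_drinking_rates):
            if rates is not None:
                if len(rates) != len(self.county_names):
                    raise ConfigError("per-county rate list length mismatch")
                if any(not 0.0 <= r <= 1.0 for r in rates):
                    raise ConfigError("planted rates must be in [0, 1]")

    # planted per-county rates, deterministic in config
    def planted_smoking(self) -> np.ndarray:
        if self.smoking_rates is not None:
            return np.asarray(self.smoking_rates, dtype=float)
        return np.round(np.linspace(0.05, 0.40, len(self.county_names)), 6)

    def planted_heavy_drinking(self) -> np.ndarray:
        if self.heavy_drinking_rates is not None:
            return np.asarray(self.heavy_drinking_rates, dtype=float)
        return np.round(np.linspace(0.05, 0.25, len(self.county_names)), 6)

    def county_fips(self) -> list[str]:
        # synthetic FIPS-style: state prefix "12" + zero-padded county index
        return [f"12{i + 1:03d}" for i in range(len(self.county_names))]


@dataclass
class TruthBundle:
    """Planted ground truth, fully determined by (seed, config)."""

    seed: int
    smoking_rate_by_county: dict[str, float]
    heavy_drinking_rate_by_county: dict[str, float]
    planted_age_inconsistencies: list[dict]
    counts_per_cancer_type: dict[str, int]

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "TruthBundle":
        return cls(**json.loads(Path(path).read_text()))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# Catchment geography
# ---------------------------------------------------------------------------


def gen_catchment(config: SourceConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """County table skeleton + tract skeleton for the catchment.

    Returns ``(counties, tracts)``: one row per county (fips, name) and one
    row per tract (geoid, county fips), with each tract GEOID prefixed by
    its county code.
    """
    config.validate()
    fips = config.county_fips()
    counties = pd.DataFrame(
        {"county_fips": fips, "county_name": list(config.county_names)}
    )
    rows = [
        {"tract_geoid": f"{cf}{(t + 1) * 100:06d}", "county_fips": cf}
        for cf in fips
        for t in range(config.tracts_per_county)
    ]
    return counties, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cancer registry
# ---------------------------------------------------------------------------

_SITE_POOLS = {
    "breast": BREAST_SITES,
    "lung": LUNG_SITES,
    "colorectal": COLORECTAL_SITES,
}
_CAUSE_OF_DEATH = {"breast": "174.9", "lung": "162.9", "colorectal": "153.9"}
_RACES = ("white", "black", "asian", "other")
_RACE_P = (0.72, 0.18, 0.04, 0.06)
_ETHNICITIES = ("non-hispanic", "hispanic")
_ETH_P = (0.88, 0.12)
_PAYERS = ("private", "medicare", "medicaid", "uninsured", "other")
_PAYER_P = (0.38, 0.34, 0.12, 0.08, 0.08)
_PROCEDURES = ("surgery", "chemotherapy", "radiation",
               "surgery and chemotherapy", "none")
_PROC_P = (0.32, 0.2, 0.16, 0.22, 0.1)
_STAGES = ("localized", "regional", "distant", "unknown")
_STAGE_P = (0.45, 0.3, 0.18, 0.07)


def gen_registry(
    config: SourceConfig, seed: int, tracts: Optional[pd.DataFrame] = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Generate the cancer-registry table.

    One row per *diagnosis record*; a configured fraction of patients carry
    a second record.  Sites are drawn only from the ICD-O-3 inclusion code
    lists.  Recorded ``age_at_diagnosis`` equals ``year(diagnosis_date) -
    birth_year`` except for the planted-inconsistent fraction, which is
    returned as the second element (one dict per planted record).
    """
    config.validate()
    if tracts is None:
        _, tracts = gen_catchment(config)
    rng = _rng(seed, 1)
    n_pat = config.n_patients

    # patient-level attributes (constant across a patient's records)
    pat_id = np.arange(1, n_pat + 1)
    pat_sex = rng.choice(["female", "male"], p=[0.55, 0.45], size=n_pat)
    pat_race = rng.choice(_RACES, p=_RACE_P, size=n_pat)
    pat_eth = rng.choice(_ETHNICITIES, p=_ETH_P, size=n_pat)
    pat_marital = rng.choice(
        list(config.marital_probs), p=list(config.marital_probs.values()),
        size=n_pat,
    )
    tract_idx = rng.integers(0, len(tracts), size=n_pat)
    pat_tract = tracts["tract_geoid"].to_numpy()[tract_idx]
    pat_county = tracts["county_fips"].to_numpy()[tract_idx]
    pat_payer = rng.choice(_PAYERS, p=_PAYER_P, size=n_pat)

    y0, y1 = config.diagnosis_years
    first_year = rng.integers(y0, y1 + 1, size=n_pat)
    first_age = np.clip(
        np.round(rng.normal(64, 13, size=n_pat)), 18, 99
    ).astype(int)
    underage = rng.random(n_pat) < config.underage_rate
    first_age[underage] = rng.integers(5, 18, size=int(underage.sum()))
    pat_birth_year = first_year - first_age
    extra = rng.random(n_pat) < config.multi_diagnosis_rate

    # expand to records: every patient has one record; a configured
    # fraction carries a second, later diagnosis (so the adult constraint
    # holds for both)
    second_year = first_year + rng.integers(
        0, np.maximum(y1 - first_year + 1, 1)
    )
    rec_pat_idx = np.sort(
        np.concatenate([np.arange(n_pat), np.arange(n_pat)[extra]]),
        kind="stable",
    )
    is_second = np.zeros(len(rec_pat_idx), dtype=bool)
    is_second[1:] = rec_pat_idx[1:] == rec_pat_idx[:-1]
    n = len(rec_pat_idx)

    dx_year = np.where(is_second, second_year[rec_pat_idx],
                       first_year[rec_pat_idx])
    dx_month = rng.integers(1, 13, size=n)
    dx_day = rng.integers(1, 29, size=n)
    dx_date = np.array(
        [f"{y:04d}{m:02d}{d:02d}" for y, m, d in zip(dx_year, dx_month, dx_day)]
    )
    birth_year = pat_birth_year[rec_pat_idx]
    true_age = dx_year - birth_year

    types = rng.choice(
        list(config.cancer_mix), p=list(config.cancer_mix.values()), size=n
    )
    sites = np.array([rng.choice(_SITE_POOLS[t]) for t in types])

    recorded_age = true_age.copy()
    planted_mask = rng.random(n) < config.inconsistency_rate
    offsets = rng.integers(1, 6, size=n) * rng.choice([-1, 1], size=n)
    recorded_age[planted_mask] = true_age[planted_mask] + offsets[planted_mask]

    dead = rng.random(n) < 0.45
    survival_months = np.minimum(
        np.round(rng.exponential(40, size=n)).astype(int), 180
    )
    cause = np.where(dead, np.vectorize(_CAUSE_OF_DEATH.get)(types), "")

    registry = pd.DataFrame(
        {
            "record_id": np.arange(1, n + 1),
            "patient_id": pat_id[rec_pat_idx],
            "sex": pat_sex[rec_pat_idx],
            "race": pat_race[rec_pat_idx],
            "ethnicity": pat_eth[rec_pat_idx],
            "marital_status": pat_marital[rec_pat_idx],
            "birth_year": birth_year,
            "icdo3_site": sites,
            "diagnosis_date": dx_date,
            "age_at_diagnosis": recorded_age,
            "county_fips": pat_county[rec_pat_idx],
            "tract_geoid": pat_tract[rec_pat_idx],
            "insurance_payer": pat_payer[rec_pat_idx],
            "treatment_procedure": rng.choice(_PROCEDURES, p=_PROC_P, size=n),
            "tumor_stage": rng.choice(_STAGES, p=_STAGE_P, size=n),
            "survival_status": np.where(dead, "dead", "alive"),
            "survival_months": survival_months,
            "cause_of_death": cause,
        }
    )
    planted = [
        {
            "record_id": int(r.record_id),
            "patient_id": int(r.patient_id),
            "recorded_age": int(r.age_at_diagnosis),
            "true_age": int(t),
        }
        for r, t in zip(
            registry.loc[planted_mask].itertuples(), true_age[planted_mask]
        )
    ]
    return registry, planted


# ---------------------------------------------------------------------------
# Behavioral survey
# ---------------------------------------------------------------------------


def gen_brfss(config: SourceConfig, seed: int) -> pd.DataFrame:
    """Generate survey respondents with planted per-county smoker rates.

    Smoking status is drawn so that, among respondents with non-missing
    smoking items, the fraction satisfying the two-condition current-smoker
    rule (smokes every day or some days AND smoked >= 100 cigarettes
    lifetime) equals the planted county rate in expectation; weights are
    drawn independently of status, so the weighted rate converges there
    too.  ``final_weight`` is exactly ``design_weight * raking_adjustment``.
    """
    config.validate()
    rng = _rng(seed, 2)
    fips = config.county_fips()
    p_smoke = config.planted_smoking()
    p_heavy = config.planted_heavy_drinking()
    m = config.brfss_n_per_county
    frames = []
    next_id = 1
    for cf, ps, ph in zip(fips, p_smoke, p_heavy):
        miss = rng.random(m) < config.missing_rate
        smoker = rng.random(m) < ps
        u = rng.random(m)
        smokday2 = np.where(
            smoker,
            np.where(u < 0.7, "every day", "some days"),
            # non-smokers: mostly never-smokers, some former (not at all,
            # yes) and some light experimenters (some days, no) so the
            # restriction-violation path is exercised
            np.where(u < 0.10, "some days",
                     "not at all"),
        )
        smoke100 = np.where(
            smoker, "yes",
            np.where((u >= 0.10) & (u < 0.25), "yes", "no"),
        )
        smokday2 = np.where(miss, "missing", smokday2)
        smoke100 = np.where(miss, "missing", smoke100)

        sex = rng.choice(["female", "male"], size=m)
        heavy = rng.random(m) < ph
        threshold = np.where(sex == "male", 14.0, 7.0)
        drinks = np.where(
            heavy,
            threshold + rng.exponential(4.0, size=m),
            rng.uniform(0.0, 1.0, size=m) * threshold,
        )
        design = rng.uniform(0.8, 1.2, size=m)
        raking = rng.uniform(0.95, 1.05, size=m)
        design = np.round(design, 6)
        raking = np.round(raking, 6)
        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": np.arange(next_id, next_id + m),
                    "county_fips": cf,
                    "sex": sex,
                    "smokday2": smokday2,
                    "smoke100": smoke100,
                    "drinks_per_week": np.round(drinks, 3),
                    "design_weight": design,
                    "raking_adjustment": raking,
                    "final_weight": design * raking,
                }
            )
        )
        next_id += m
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Contextual tables (SVI, census, RUCA) and county health rankings
# ---------------------------------------------------------------------------

_RUCA_P = (0.30, 0.07, 0.05, 0.12, 0.05, 0.04, 0.12, 0.05, 0.04, 0.16)


def _percentile_rank(values: np.ndarray) -> np.ndarray:
    """Min-max percentile rank in [0, 1]; average ranks on ties."""
    order = pd.Series(values).rank(method="average").to_numpy()
    n = len(values)
    if n < 2:
        raise ConfigError("percentile ranking needs at least 2 tracts")
    return np.round((order - 1.0) / (n - 1.0), 6)


def gen_contextual(
    config: SourceConfig, seed: int, tracts: Optional[pd.DataFrame] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (svi, census, ruca) tract tables.

    The 15 SVI factors are drawn per tract; each theme rank is the
    percentile rank (higher = more vulnerable) of the theme's factor sum
    across all tracts, and the overall rank is the percentile rank of the
    full factor total.
    """
    config.validate()
    if tracts is None:
        _, tracts = gen_catchment(config)
    if len(tracts) < 2:
        raise ConfigError("contextual ranking undefined for < 2 tracts")
    rng = _rng(seed, 3)
    n = len(tracts)
    factors = np.round(rng.uniform(0.0, 1.0, size=(n, 15)), 6)
    svi = pd.DataFrame(
        factors, columns=[f"factor_{i + 1}" for i in range(15)]
    )
    svi.insert(0, "tract_geoid", tracts["tract_geoid"].to_numpy())
    for theme, sl in SVI_THEME_SLICES.items():
        svi[f"rank_{theme}"] = _percentile_rank(factors[:, sl].sum(axis=1))
    svi["rank_overall"] = _percentile_rank(factors.sum(axis=1))

    census = pd.DataFrame(
        {
            "tract_geoid": tracts["tract_geoid"].to_numpy(),
            "hs_completion_rate": np.round(rng.uniform(0.5, 0.99, size=n), 6),
            "family_poverty_rate": np.round(rng.uniform(0.02, 0.40, size=n), 6),
        }
    )
    ruca = pd.DataFrame(
        {
            "tract_geoid": tracts["tract_geoid"].to_numpy(),
            "ruca_code": rng.choice(np.arange(1, 11), p=_RUCA_P, size=n),
        }
    )
    return svi, census, ruca


def gen_county_health(
    config: SourceConfig, seed: int, counties: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """County health-ranking table (unhealthy days in [0, 30], PCP ratio)."""
    config.validate()
    if counties is None:
        counties, _ = gen_catchment(config)
    rng = _rng(seed, 4)
    n = len(counties)
    return pd.DataFrame(
        {
            "county_fips": counties["county_fips"].to_numpy(),
            "county_name": counties["county_name"].to_numpy(),
            "mental_unhealthy_days": np.round(rng.uniform(2.5, 6.0, n), 2),
            "physical_unhealthy_days": np.round(rng.uniform(2.5, 6.5, n), 2),
            "pcp_ratio": np.round(rng.uniform(800.0, 3500.0, n), 0),
        }
    )


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

TABLE_NAMES = ("registry", "brfss", "svi", "census", "ruca", "county_health")


@dataclass
class SyntheticData:
    """All generated tables plus the planted truth."""

    registry: pd.DataFrame
    brfss: pd.DataFrame
    svi: pd.DataFrame
    census: pd.DataFrame
    ruca: pd.DataFrame
    county_health: pd.DataFrame
    truth: TruthBundle

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}

    def write_csv(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(directory / f"{name}.csv", index=False)
        self.truth.to_json(directory / "truth.json")

    def to_sqlite(self, path: Union[str, Path, sqlite3.Connection]) -> None:
        conn = (
            path
            if isinstance(path, sqlite3.Connection)
            else sqlite3.connect(str(path))
        )
        for name, df in self.tables().items():
            df.to_sql(name, conn, index=False, if_exists="replace")
        if not isinstance(path, sqlite3.Connection):
            conn.commit()
            conn.close()


def generate_all(config: Optional[SourceConfig] = None,
                 seed: int = 0) -> SyntheticData:
    """Generate every source table and the truth bundle for (config, seed)."""
    config = config or SourceConfig()
    config.validate()
    counties, tracts = gen_catchment(config)
    registry, planted = gen_registry(config, seed, tracts)
    brfss = gen_brfss(config, seed)
    svi, census, ruca = gen_contextual(config, seed, tracts)
    county_health = gen_county_health(config, seed, counties)
    truth = TruthBundle(
        seed=seed,
        smoking_rate_by_county=dict(
            zip(config.county_fips(), map(float, config.planted_smoking()))
        ),
        heavy_drinking_rate_by_county=dict(
            zip(config.county_fips(),
                map(float, config.planted_heavy_drinking()))
        ),
        planted_age_inconsistencies=planted,
        counts_per_cancer_type={
            t: int((registry["icdo3_site"].isin(_SITE_POOLS[t])).sum())
            for t in ("breast", "lung", "colorectal")
        },
    )
    return SyntheticData(registry, brfss, svi, census, ruca, county_health,
                         truth)
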