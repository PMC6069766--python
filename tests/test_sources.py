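"""Synthetic source generators: determinism, integrity, planted truth."""

import numpy as np
import pandas as pd
import pytest

import ocrvkit as k
from ocrvkit.sources import ConfigError, SourceConfig


class TestCatchment:
    def test_default_emits_twenty_counties(self):
        counties, _ = k.gen_catchment(SourceConfig())
        assert len(counties) == 20
        assert list(counties["county_name"]) == list(k.CATCHMENT_COUNTIES)

    def test_tract_count_and_prefixing(self):
        cfg = SourceConfig(tracts_per_county=3)
        counties, tracts = k.gen_catchment(cfg)
        assert len(tracts) == 60
        assert (tracts["tract_geoid"].str[:5] == tracts["county_fips"]).all()
        assert tracts["tract_geoid"].str.len().eq(11).all()

    def test_singleton_county_list(self):
        counties, _ = k.gen_catchment(SourceConfig(county_names=("Alachua",)))
        assert len(counties) == 1

    def test_invalid_tracts_per_county(self):
        with pytest.raises(ConfigError):
            k.gen_catchment(SourceConfig(tracts_per_county=0))


class TestRegistry:
    def test_breast_only_mix_uses_inclusion_codes(self):
        cfg = SourceConfig(n_patients=100, cancer_mix={"breast": 1.0},
                           brfss_n_per_county=5)
        registry, _ = k.gen_registry(cfg, seed=3)
        assert registry["icdo3_site"].isin(k.sources.BREAST_SITES).all()

    def test_all_sites_from_inclusion_lists(self, small_data):
        allowed = set(k.sources.BREAST_SITES) | set(
            k.sources.LUNG_SITES) | set(k.sources.COLORECTAL_SITES)
        assert small_data.registry["icdo3_site"].isin(allowed).all()

    def test_adults_only_by_default(self, small_data):
        reg = small_data.registry
        true_age = (reg["diagnosis_date"].str[:4].astype(int)
                    - reg["birth_year"])
        assert (true_age >= 18).all()

    def test_zero_inconsistency_rate_plants_nothing(self):
        cfg = SourceConfig(n_patients=50, inconsistency_rate=0.0)
        _, planted = k.gen_registry(cfg, seed=5)
        assert planted == []

    def test_planted_list_reproducible_across_runs(self):
        cfg = SourceConfig(n_patients=200, inconsistency_rate=0.1)
        reg1, planted1 = k.gen_registry(cfg, seed=7)
        reg2, planted2 = k.gen_registry(cfg, seed=7)
        assert planted1 == planted2
        pd.testing.assert_frame_equal(reg1, reg2)
        assert len(planted1) > 0
        # every planted record really is inconsistent
        by_id = reg1.set_index("record_id")
        for p in planted1:
            row = by_id.loc[p["record_id"]]
            assert p["recorded_age"] != p["true_age"]
            assert int(row["age_at_diagnosis"]) == p["recorded_age"]

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SourceConfig(cancer_mix={"breast": 0.5, "lung": 0.2}).validate()

    def test_patient_level_attributes_constant_across_records(self,
                                                              small_data):
        reg = small_data.registry
        per_patient = reg.groupby("patient_id")[
            ["sex", "race", "marital_status", "birth_year", "tract_geoid"]
        ].nunique()
        assert (per_patient == 1).all().all()


class TestBrfss:
    def test_final_weight_identity_everywhere(self, small_data):
        b = small_data.brfss
        assert np.allclose(
            b["final_weight"], b["design_weight"] * b["raking_adjustment"],
            rtol=0, atol=1e-9,
        )

    def test_zero_planted_rate_has_no_smokers(self):
        cfg = SourceConfig(
            county_names=("Alachua",), brfss_n_per_county=300,
            smoking_rates=[0.0], heavy_drinking_rates=[0.0], n_patients=5,
        )
        b = k.gen_brfss(cfg, seed=2)
        smokers = b["smokday2"].isin(["every day", "some days"]) & (
            b["smoke100"] == "yes"
        )
        assert not smokers.any()

    def test_weighted_fraction_near_planted_rate(self):
        cfg = SourceConfig(county_names=("Alachua",), tracts_per_county=2,
                           brfss_n_per_county=5000, smoking_rates=[0.25],
                           heavy_drinking_rates=[0.1], n_patients=5)
        b = k.gen_brfss(cfg, seed=11)
        elig = b[(b.smokday2 != "missing") & (b.smoke100 != "missing")]
        qualifies = elig["smokday2"].isin(["every day", "some days"]) & (
            elig["smoke100"] == "yes"
        )
        rate = elig.loc[qualifies, "final_weight"].sum() / \
            elig["final_weight"].sum()
        se = np.sqrt(0.25 * 0.75 / len(elig))
        assert abs(rate - 0.25) < 3 * se

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            SourceConfig(county_names=("A",), smoking_rates=[1.5]).validate()


class TestContextual:
    def test_two_tract_minmax_ranks(self):
        cfg = SourceConfig(county_names=("Alachua",), tracts_per_county=2,
                           n_patients=5)
        svi, census, ruca = k.gen_contextual(cfg, seed=4)
        for theme in ("socioeconomic", "household", "minority", "housing"):
            assert sorted(svi[f"rank_{theme}"]) == [0.0, 1.0]
        assert sorted(svi["rank_overall"]) == [0.0, 1.0]

    def test_tied_factors_get_equal_ranks(self):
        from ocrvkit.sources import _percentile_rank

        ranks = _percentile_rank(np.array([3.0, 3.0, 3.0, 3.0]))
        assert np.allclose(ranks, 0.5)

    def test_overall_rank_matches_bruteforce(self):
        cfg = SourceConfig(tracts_per_county=5)  # 100 tracts
        svi, _, _ = k.gen_contextual(cfg, seed=9)
        factors = svi[[f"factor_{i}" for i in range(1, 16)]].to_numpy()
        totals = factors.sum(axis=1)
        # independent oracle: pairwise comparison counting
        n = len(totals)
        brute = np.array([
            (np.sum(totals < t) + (np.sum(totals == t) - 1) / 2) / (n - 1)
            for t in totals
        ])
        assert np.allclose(svi["rank_overall"], brute, atol=1e-6)

    def test_ruca_codes_in_range(self, small_data):
        assert small_data.ruca["ruca_code"].between(1, 10).all()

    def test_single_tract_ranking_rejected(self):
        cfg = SourceConfig(county_names=("Alachua",), tracts_per_county=1,
                           n_patients=5)
        with pytest.raises(ConfigError):
            k.gen_contextual(cfg, seed=0)


class TestBundle:
    def test_referential_integrity(self, small_data):
        reg = small_data.registry
        assert reg["tract_geoid"].isin(small_data.svi["tract_geoid"]).all()
        assert reg["county_fips"].isin(
            small_data.county_health["county_fips"]
        ).all()
        assert small_data.brfss["county_fips"].isin(
            small_data.county_health["county_fips"]
        ).all()

    def test_county_health_days_in_range(self, small_data):
        ch = small_data.county_health
        assert ch["mental_unhealthy_days"].between(0, 30).all()
        assert ch["physical_unhealthy_days"].between(0, 30).all()

    def test_byte_identical_output_for_fixed_seed(self, small_config,
                                                  tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        k.generate_all(small_config, seed=13).write_csv(d1)
        k.generate_all(small_config, seed=13).write_csv(d2)
        for name in ("registry", "brfss", "svi", "census", "ruca",
                     "county_health"):
            assert (d1 / f"{name}.csv").read_bytes() == \
                (d2 / f"{name}.csv").read_bytes()
        assert (d1 / "truth.json").read_bytes() == \
            (d2 / "truth.json").read_bytes()

    def test_truth_bundle_roundtrip(self, small_data, tmp_path):
        path = tmp_path / "truth.json"
        small_data.truth.to_json(path)
        back = k.TruthBundle.from_json(path)
        assert back == small_data.truth
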