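"""Prevalence arithmetic, class binning and table builders."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rareg import (
    AgeClass,
    Inheritance,
    Registry,
    Sex,
    SEVEN_CLASS_SCHEME,
    bin_prevalence_class,
    build_class_table,
    build_region_table,
    build_specialty_table,
    cumulative_prevalence,
    disease_prevalences,
    one_in_n,
    point_prevalence,
    xl_male_prevalence,
)
from rareg.prevalence import ClassScheme, round_half_away

from conftest import REGION, make_patient, make_toy_registry


class TestPointPrevalence:
    @pytest.mark.parametrize(
        "count, denominator, expected",
        [
            (646, 3_703_018, 17.45),
            (10_265, 3_703_018, 277.21),
            (145, 3_703_018, 3.92),
            (4_270, 764_260, 558.71),
            (0, 1_000_000, 0.00),
        ],
    )
    def test_reference_rates(self, count, denominator, expected):
        assert point_prevalence(count, denominator) == expected

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(17.445, 2) == 17.45
        assert round_half_away(2.675, 2) == 2.68
        assert round_half_away(-0.005, 2) == -0.01

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            point_prevalence(1, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n=st.integers(0, 10_000),
        denominator=st.integers(1, 10_000_000),
        k=st.integers(1, 50),
    )
    def test_scale_equivariance(self, n, denominator, k):
        assert point_prevalence(n, denominator) == point_prevalence(k * n, k * denominator)


class TestOneInN:
    @pytest.mark.parametrize(
        "count, denominator, expected",
        [(10_265, 3_703_018, 361), (1_756, 3_703_018, 2_109), (7, 7, 1)],
    )
    def test_reference_ratios(self, count, denominator, expected):
        assert one_in_n(count, denominator) == expected

    def test_zero_cases_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            one_in_n(0, 100)


class TestClassBinning:
    @pytest.mark.parametrize(
        "count, denominator, expected",
        [
            (646, 3_703_018, 1),   # 1:5,732
            (65, 3_703_018, 2),    # 1:56,970
            (30, 3_703_018, 3),
            (15, 3_703_018, 4),
            (11, 3_703_018, 5),
            (8, 3_703_018, 6),
            (5, 3_703_018, 7),
            (0, 3_703_018, 7),
        ],
    )
    def test_seven_classes(self, count, denominator, expected):
        assert bin_prevalence_class(count, denominator) == expected

    def test_exact_boundary_goes_to_more_frequent_class(self):
        assert bin_prevalence_class(2, 100_000) == 1  # exactly 1:50,000
        assert bin_prevalence_class(1, 100_000) == 2  # exactly 1:100,000

    def test_class_count_is_monotone_in_cases(self):
        denominator = 3_703_018
        classes = [bin_prevalence_class(n, denominator) for n in range(0, 200)]
        assert classes == sorted(classes, reverse=True)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            ClassScheme(thresholds=(100, 50), labels=("a", "b", "c"))


class TestXLMalePrevalence:
    @pytest.mark.parametrize(
        "count, expected",
        [(226, 12.21), (124, 6.70), (78, 4.21), (55, 2.97), (51, 2.75), (0, 0.0)],
    )
    def test_half_population_convention(self, count, expected):
        assert xl_male_prevalence(count, 3_703_018, male_fraction=0.5) == expected

    def test_observed_male_share(self):
        assert xl_male_prevalence(78, 3_703_018, male_fraction=0.4644) == 4.54

    def test_invalid_fraction(self):
        with pytest.raises(ValueError, match="male_fraction"):
            xl_male_prevalence(10, 1000, male_fraction=1.5)


class TestCumulativePrevalence:
    def toy(self):
        patients = [make_patient(f"P{i}") for i in range(3)]
        patients.append(make_patient("C1", age=AgeClass.CHILD))
        return make_toy_registry(patients)

    def test_all_stratum(self):
        estimate = cumulative_prevalence(self.toy(), "all")
        assert estimate.case_count == 4
        assert estimate.rate_per_100k == point_prevalence(4, REGION.population_total)

    def test_children_stratum_uses_child_denominator(self):
        estimate = cumulative_prevalence(self.toy(), "children")
        assert estimate.case_count == 1
        assert estimate.denominator == REGION.population_children

    def test_region_stratum(self):
        estimate = cumulative_prevalence(self.toy(), ("region", "R01"))
        assert estimate.case_count == 4

    def test_zero_patient_stratum(self):
        registry = make_toy_registry([make_patient("P1", sex=Sex.MALE)])
        estimate = cumulative_prevalence(registry, "female")
        assert estimate.rate_per_100k == 0.0 and estimate.one_in_n is None

    def test_missing_demography_errors(self):
        registry = make_toy_registry([make_patient("P1")], demography=())
        with pytest.raises(ValueError, match="demography"):
            cumulative_prevalence(registry, "all")


class TestTables:
    def test_class_table_conserves_counts(self, simulated_bundle):
        registry, _ = simulated_bundle
        table = build_class_table(registry)
        body = table[table["prevalence_class"] > 0]
        total = table[table["prevalence_class"] == 0].iloc[0]
        for mode in ("AD", "AR", "XL", "Total"):
            assert body[f"{mode}_patients"].sum() == total[f"{mode}_patients"]
            assert body[f"{mode}_diseases"].sum() == total[f"{mode}_diseases"]
        assert total["Total_patients"] == registry.n_patients

    def test_class_table_cells_match_full_scan(self, simulated_bundle):
        registry, _ = simulated_bundle
        table = build_class_table(registry).set_index("prevalence_class")
        per_disease = disease_prevalences(registry)
        for klass in range(1, 8):
            subset = per_disease[per_disease["prevalence_class"] == klass]
            ad = subset[subset["inheritance"] == "AD"]
            assert table.loc[klass, "AD_patients"] == ad["n_patients"].sum()
            assert table.loc[klass, "AD_diseases"] == len(ad)

    def test_single_patient_registry_class_table(self):
        registry = make_toy_registry([make_patient("P1")])
        table = build_class_table(registry)
        body = table[table["prevalence_class"] > 0]
        assert body["Total_patients"].sum() == 1
        nonzero = body[body["Total_patients"] > 0]
        assert len(nonzero) == 1
        assert nonzero["AD_patients_pct"].iloc[0] == 100.0

    def test_specialty_table_conserves_and_percentages_sum(self, simulated_bundle):
        registry, _ = simulated_bundle
        table = build_specialty_table(registry)
        assert table["n_patients"].sum() == registry.n_patients
        assert abs(table["patients_pct"].sum() - 100.0) <= 0.05
        assert abs(table["diseases_pct"].sum() - 100.0) <= 0.05

    def test_specialty_table_requires_catalogue_assignment(self):
        patients = [make_patient("P1", disease="#uncatalogued")]
        registry = make_toy_registry(patients)
        with pytest.raises((ValueError, Exception)):
            build_specialty_table(registry)

    def test_region_table_single_district(self):
        from rareg import RegionDemography

        demography = RegionDemography("R01", 36_100, 18_000, 18_100, 7_000, n_districts=1)
        patients = [
            make_patient(f"P{i}", district="R01-D01") for i in range(100)
        ]
        registry = make_toy_registry(patients, demography=(demography,))
        table = build_region_table(registry)
        assert table["ratio_range"].iloc[0] == "1:361-1:361"

    def test_region_table_min_max_match_brute_force(self, simulated_bundle):
        registry, _ = simulated_bundle
        table = build_region_table(registry).set_index("region_id")
        pat = registry.patients
        for region in registry.demography.itertuples():
            per_district_pop = round(region.population_total / region.n_districts)
            counts = pat[pat["region_id"] == region.region_id].groupby("district_id").size()
            ratios = [one_in_n(int(c), per_district_pop) for c in counts if c > 0]
            assert table.loc[region.region_id, "min_one_in_n"] == min(ratios)
            assert table.loc[region.region_id, "max_one_in_n"] == max(ratios)

    def test_region_table_requires_districts(self):
        registry = make_toy_registry([make_patient("P1")])
        with pytest.raises(ValueError, match="district"):
            build_region_table(registry)
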