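"""Synthetic-registry simulator: determinism, ascertainment, recovery."""

import numpy as np
import pytest
from scipy import stats

from rareg import (
    DiseaseSpec,
    Inheritance,
    RegionSpec,
    SimulationConfig,
    SourceSpec,
    Specialty,
    default_config,
    point_prevalence,
    simulate_population,
    simulate_sibships,
)
from rareg.simulate import zero_truncated_poisson


def full_registration_config(**overrides):
    kwargs = dict(
        regions=(RegionSpec("R01", 1_000_000, n_districts=3),),
        diseases=(
            DiseaseSpec("#1", "d1", Inheritance.AD, Specialty.SKELETAL, 20.0),
            DiseaseSpec("#2", "d2", Inheritance.AR, Specialty.OTHER, 12.0),
            DiseaseSpec("#3", "d3", Inheritance.XL, Specialty.OPHTHALMIC, 6.0),
        ),
        sources=(SourceSpec("S1", 1.0),),
        ascertainment_pi={k: 1.0 for k in Inheritance},
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


class TestSibshipSimulator:
    def test_full_penetrance_full_ascertainment(self):
        sibs, truth = simulate_sibships(200, p=1.0, pi=1.0, seed=0)
        assert len(sibs) == 200
        assert all(f.affected_a == f.size_s and f.probands_b == f.affected_a for f in sibs)

    def test_zero_segregation_gives_empty_list(self):
        sibs, truth = simulate_sibships(200, p=0.0, pi=0.5, seed=0)
        assert sibs == []
        assert truth.n_segregating == 0

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="invalid probability"):
            simulate_sibships(10, p=1.5, pi=0.5)
        with pytest.raises(ValueError, match="invalid probability"):
            simulate_sibships(10, p=0.5, pi=0.0)

    def test_all_returned_sibships_are_ascertained(self):
        sibs, _ = simulate_sibships(5000, p=0.25, pi=0.4, seed=1)
        assert all(f.probands_b >= 1 for f in sibs)

    def test_ascertained_fraction_matches_enumeration_oracle(self):
        # Independent oracle: exhaustive enumeration over (s, a) of
        # P(ascertained | segregating) = E[1 - (1-pi)^a | a >= 1] under
        # zero-truncated Poisson sibship sizes and binomial affection.
        p, pi, lam, n = 0.25, 0.83, 2.5, 20_000
        smax = 30
        sizes = np.arange(1, smax + 1)
        size_pmf = stats.poisson.pmf(sizes, lam) / (1 - np.exp(-lam))
        num = den = 0.0
        for s, ps in zip(sizes, size_pmf):
            a = np.arange(1, s + 1)
            pa = stats.binom.pmf(a, s, p)
            den += ps * pa.sum()
            num += ps * (pa * (1 - (1 - pi) ** a)).sum()
        oracle = num / den
        _, truth = simulate_sibships(n, p=p, pi=pi, sibship_lambda=lam, seed=2024)
        observed = truth.ascertained_fraction_of_segregating
        se = np.sqrt(oracle * (1 - oracle) / truth.n_segregating)
        assert abs(observed - oracle) < 4 * se

    def test_zero_truncated_poisson_support_and_mean(self):
        rng = np.random.default_rng(0)
        draws = zero_truncated_poisson(rng, 2.5, 50_000)
        assert draws.min() >= 1
        expected_mean = 2.5 / (1 - np.exp(-2.5))
        assert abs(draws.mean() - expected_mean) < 0.03


class TestPopulationSimulator:
    def test_determinism_byte_identical(self, tmp_path):
        config = default_config(seed=5)
        for run in ("a", "b"):
            registry, _ = simulate_population(config, seed=5)
            registry.to_csv_dir(tmp_path / run)
        for name in ("patients.csv", "sibships.csv", "diseases.csv", "regions.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_full_registration_recovers_true_counts_exactly(self):
        config = full_registration_config()
        registry, truth = simulate_population(config, seed=9)
        observed = registry.patients.groupby("disease_id").size()
        for disease_id, group in truth.placement.groupby("disease_id"):
            assert int(observed.get(disease_id, 0)) == int(group["n_true"].sum())
        # prevalence recovery: estimated rate equals the placed-case rate
        population = config.regions[0].population_total
        for disease_id, group in truth.placement.groupby("disease_id"):
            n_true = int(group["n_true"].sum())
            assert point_prevalence(
                int(observed.get(disease_id, 0)), population
            ) == point_prevalence(n_true, population)

    def test_two_source_overlap_matches_conditional_probability(self):
        # sensitivities 0.9/0.9: P(both | observed) = 0.81 / (1 - 0.01)
        config = full_registration_config(
            regions=(RegionSpec("R01", 4_000_000, n_districts=2),),
            diseases=(DiseaseSpec("#1", "d1", Inheritance.AD, Specialty.SKELETAL, 25.0),),
            sources=(SourceSpec("S1", 0.9), SourceSpec("S2", 0.9)),
        )
        registry, _ = simulate_population(config, seed=17)
        n_sources = registry.patients["sources"].str.count(";") + 1
        observed = float((n_sources == 2).mean())
        expected = 0.81 / (1 - 0.01)
        se = np.sqrt(expected * (1 - expected) / len(registry.patients))
        assert abs(observed - expected) < 4 * se

    def test_unregistered_cases_are_unobserved(self):
        config = full_registration_config(
            ascertainment_pi={k: 0.5 for k in Inheritance},
        )
        registry, truth = simulate_population(config, seed=21)
        assert registry.n_patients < truth.n_true_cases
        assert registry.n_patients == int(truth.placement["n_registered"].sum())

    def test_xl_cases_are_male(self, simulated_bundle):
        registry, _ = simulated_bundle
        merged = registry.patients_with_inheritance()
        xl = merged[merged["inheritance"] == "XL"]
        assert len(xl) and (xl["sex"] == "male").all()

    def test_sibships_link_to_registered_patients(self, simulated_bundle):
        registry, _ = simulated_bundle
        assert registry.validate() == []
        assert set(registry.sibships["family_id"]) <= set(registry.patients["family_id"])

    def test_low_rate_flagged_not_fatal(self):
        config = full_registration_config(
            diseases=(DiseaseSpec("#1", "d1", Inheritance.AD, Specialty.SKELETAL, 0.01),),
        )
        _, truth = simulate_population(config, seed=1)
        assert truth.low_expectation_flags

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="sensitivity"):
            SourceSpec("S1", 0.0)
        with pytest.raises(ValueError, match="true_rate"):
            DiseaseSpec("#1", "d", Inheritance.AD, Specialty.OTHER, 0.0)
        with pytest.raises(ValueError, match="at least one region"):
            SimulationConfig(regions=(), diseases=(), sources=())

    def test_config_yaml_round_trip(self, tmp_path):
        config = default_config(seed=3)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        loaded = SimulationConfig.from_yaml(path)
        assert loaded.regions == config.regions
        assert loaded.diseases == config.diseases
        assert loaded.sources == config.sources
        registry_a, _ = simulate_population(config, seed=3)
        registry_b, _ = simulate_population(loaded, seed=3)
        assert registry_a.patients.equals(registry_b.patients)
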