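"""Seeded simulator of Mendelian case registries with known ground truth.

Two generators are provided:

* :func:`simulate_sibships` — the generative sibship model used to
  validate the segregation estimators: sibship sizes follow a
  zero-truncated Poisson law, each child is affected with segregation
  frequency ``p``, each affected is independently a proband with
  registration probability ``pi``, and only sibships with at least one
  proband are observed (multiple incomplete ascertainment).

* :func:`simulate_population` — a registry-scale simulator: true cases
  are placed per disease and region at a configured rate, a configurable
  fraction of cases is clustered into familial groups of 2-3 same-disease
  cases, each case is registered with its inheritance mode's probability
  ``pi`` and then reported by each information source independently with
  that source's sensitivity (a case reported by no source stays
  unobserved).  The returned truth object records everything needed to
  check downstream estimates against the generating parameters.

Everything is a deterministic function of (config, seed); per-stage random
substreams are derived from a single seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .registry import Registry
from .types import (
    AgeClass,
    DiseaseEntry,
    Inheritance,
    PatientRecord,
    RegionDemography,
    Sex,
    Sibship,
    Specialty,
)

logger = logging.getLogger(__name__)

_BIRTH_YEAR = {AgeClass.CHILD: 2012, AgeClass.REPRODUCTIVE: 1992, AgeClass.POST_REPRODUCTIVE: 1965}


@dataclass(frozen=True)
class RegionSpec:
    region_id: str
    population_total: int
    male_fraction: float = 0.4644
    child_fraction: float = 0.2064
    n_districts: int = 3

    def __post_init__(self) -> None:
        if self.population_total <= 0:
            raise ValueError(f"region {self.region_id!r}: population_total must be > 0")
        for name in ("male_fraction", "child_fraction"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"region {self.region_id!r}: {name} must lie in (0, 1)")
        if self.n_districts < 1:
            raise ValueError(f"region {self.region_id!r}: n_districts must be >= 1")

    def demography(self) -> RegionDemography:
        male = int(round(self.male_fraction * self.population_total))
        return RegionDemography(
            region_id=self.region_id,
            population_total=self.population_total,
            population_male=male,
            population_female=self.population_total - male,
            population_children=int(round(self.child_fraction * self.population_total)),
            n_districts=self.n_districts,
        )


@dataclass(frozen=True)
class DiseaseSpec:
    disease_id: str
    name: str
    inheritance: Inheritance
    specialty: Specialty
    true_rate_per_100k: float

    def __post_init__(self) -> None:
        if self.true_rate_per_100k <= 0:
            raise ValueError(f"disease {self.disease_id!r}: true_rate_per_100k must be > 0")

    def entry(self) -> DiseaseEntry:
        return DiseaseEntry(
            disease_id=self.disease_id,
            name=self.name,
            inheritance=self.inheritance,
            specialty=self.specialty,
        )


@dataclass(frozen=True)
class SourceSpec:
    source_id: str
    sensitivity: float

    def __post_init__(self) -> None:
        if not (0.0 < self.sensitivity <= 1.0):
            raise ValueError(f"source {self.source_id!r}: sensitivity must lie in (0, 1]")


def _check_prob_map(name: str, mapping: Mapping[Inheritance, float], closed_zero: bool = False) -> None:
    for mode in Inheritance:
        value = mapping[mode]
        low_ok = value >= 0.0 if closed_zero else value > 0.0
        if not (low_ok and value <= 1.0):
            raise ValueError(f"{name}[{mode.value}] = {value} outside the valid range")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the population simulator.

    Defaults emulate the statistical structure of a multi-region survey of
    rare Mendelian disease: Mendelian segregation frequencies (0.5 AD,
    0.25 AR, 0.5 in sons for XL), registration probabilities of 0.72 (AD)
    and 0.83 (AR, also adopted for XL), familial-case fractions of 0.75 /
    0.30 / 0.175 for AD / AR / XL, a zero-truncated Poisson(2.5) sibship
    size law, and three overlapping registration sources whose
    sensitivities put roughly 80% of observed cases in more than one
    source.
    """

    regions: Tuple[RegionSpec, ...]
    diseases: Tuple[DiseaseSpec, ...]
    sources: Tuple[SourceSpec, ...] = (
        SourceSpec("questionnaire_cards", 0.85),
        SourceSpec("disability_lists", 0.70),
        SourceSpec("special_schools", 0.55),
    )
    seed: int = 0
    sibship_lambda: float = 2.5
    segregation_frequency: Mapping[Inheritance, float] = field(
        default_factory=lambda: {Inheritance.AD: 0.5, Inheritance.AR: 0.25, Inheritance.XL: 0.5}
    )
    ascertainment_pi: Mapping[Inheritance, float] = field(
        default_factory=lambda: {Inheritance.AD: 0.72, Inheritance.AR: 0.83, Inheritance.XL: 0.83}
    )
    familial_fraction: Mapping[Inheritance, float] = field(
        default_factory=lambda: {Inheritance.AD: 0.75, Inheritance.AR: 0.30, Inheritance.XL: 0.175}
    )
    age_class_fractions: Mapping[AgeClass, float] = field(
        default_factory=lambda: {
            AgeClass.CHILD: 0.433,
            AgeClass.REPRODUCTIVE: 0.372,
            AgeClass.POST_REPRODUCTIVE: 0.195,
        }
    )

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("at least one region required")
        if not self.diseases:
            raise ValueError("at least one disease required")
        if not self.sources:
            raise ValueError("at least one source required")
        if self.sibship_lambda <= 0:
            raise ValueError("sibship_lambda must be > 0")
        _check_prob_map("segregation_frequency", self.segregation_frequency)
        _check_prob_map("ascertainment_pi", self.ascertainment_pi)
        _check_prob_map("familial_fraction", self.familial_fraction, closed_zero=True)
        total = sum(self.age_class_fractions[a] for a in AgeClass)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("age_class_fractions must sum to 1")

    # -- YAML round trip ----------------------------------------------

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            regions=tuple(RegionSpec(**r) for r in raw["regions"]),
            diseases=tuple(
                DiseaseSpec(
                    disease_id=d["disease_id"],
                    name=d.get("name", d["disease_id"]),
                    inheritance=Inheritance(d["inheritance"]),
                    specialty=Specialty(d["specialty"]),
                    true_rate_per_100k=float(d["true_rate_per_100k"]),
                )
                for d in raw["diseases"]
            ),
            sources=tuple(SourceSpec(**s) for s in raw.get("sources", []))
            or cls.__dataclass_fields__["sources"].default,
            seed=int(raw.get("seed", 0)),
            sibship_lambda=float(raw.get("sibship_lambda", 2.5)),
            segregation_frequency={
                Inheritance(k): float(v)
                for k, v in raw.get(
                    "segregation_frequency", {"AD": 0.5, "AR": 0.25, "XL": 0.5}
                ).items()
            },
            ascertainment_pi={
                Inheritance(k): float(v)
                for k, v in raw.get(
                    "ascertainment_pi", {"AD": 0.72, "AR": 0.83, "XL": 0.83}
                ).items()
            },
            familial_fraction={
                Inheritance(k): float(v)
                for k, v in raw.get(
                    "familial_fraction", {"AD": 0.75, "AR": 0.30, "XL": 0.175}
                ).items()
            },
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        payload = {
            "seed": self.seed,
            "sibship_lambda": self.sibship_lambda,
            "segregation_frequency": {k.value: v for k, v in self.segregation_frequency.items()},
            "ascertainment_pi": {k.value: v for k, v in self.ascertainment_pi.items()},
            "familial_fraction": {k.value: v for k, v in self.familial_fraction.items()},
            "regions": [asdict(r) for r in self.regions],
            "diseases": [
                {
                    "disease_id": d.disease_id,
                    "name": d.name,
                    "inheritance": d.inheritance.value,
                    "specialty": d.specialty.value,
                    "true_rate_per_100k": d.true_rate_per_100k,
                }
                for d in self.diseases
            ],
            "sources": [asdict(s) for s in self.sources],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def default_config(seed: int = 0) -> SimulationConfig:
    """A desk-scale three-region, twelve-disease study configuration."""
    regions = (
        RegionSpec("R01", 450_000, n_districts=6),
        RegionSpec("R02", 300_000, n_districts=4),
        RegionSpec("R03", 250_000, n_districts=5),
    )
    diseases = (
        DiseaseSpec("#146700", "Ichthyosis vulgaris", Inheritance.AD, Specialty.GENODERMATOSIS, 17.45),
        DiseaseSpec("PS130000", "Ehlers-Danlos syndrome", Inheritance.AD, Specialty.HEREDITARY_SYNDROME, 12.40),
        DiseaseSpec("PS118220", "Charcot-Marie-Tooth disease", Inheritance.AD, Specialty.NEUROLOGICAL_PSYCHIATRIC, 6.27),
        DiseaseSpec("PS116200", "Congenital hereditary cataract", Inheritance.AD, Specialty.OPHTHALMIC, 5.81),
        DiseaseSpec("#146000", "Hypochondroplasia", Inheritance.AD, Specialty.SKELETAL, 4.43),
        DiseaseSpec("PS220290", "Deafness, autosomal recessive", Inheritance.AR, Specialty.OTHER, 20.96),
        DiseaseSpec("PS249500", "Intellectual disability, AR", Inheritance.AR, Specialty.NEUROLOGICAL_PSYCHIATRIC, 11.64),
        DiseaseSpec("#261600", "Phenylketonuria", Inheritance.AR, Specialty.OTHER, 3.92),
        DiseaseSpec("PS268000", "Retinitis pigmentosa", Inheritance.AR, Specialty.OPHTHALMIC, 4.05),
        DiseaseSpec("PS309530", "Intellectual disability, XL", Inheritance.XL, Specialty.NEUROLOGICAL_PSYCHIATRIC, 6.10),
        DiseaseSpec("#308100", "Ichthyosis, X-linked", Inheritance.XL, Specialty.GENODERMATOSIS, 3.35),
        DiseaseSpec("#306700", "Hemophilia A", Inheritance.XL, Specialty.OTHER, 2.11),
    )
    return SimulationConfig(regions=regions, diseases=diseases, seed=seed)


# -- sibship generator -------------------------------------------------


def zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Draw sibship sizes from a Poisson(lam) conditioned on being >= 1."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    p0 = np.exp(-lam)
    u = p0 + (1.0 - p0) * rng.random(size)
    return np.maximum(stats.poisson.ppf(u, lam).astype(np.int64), 1)


@dataclass
class SibshipTruth:
    """Ground truth for a simulated sibship cohort."""

    n_families: int
    n_segregating: int
    n_ascertained: int
    sizes: np.ndarray
    affected: np.ndarray
    probands: np.ndarray

    @property
    def ascertained_fraction_of_segregating(self) -> float:
        if self.n_segregating == 0:
            return 0.0
        return self.n_ascertained / self.n_segregating


def simulate_sibships(
    n_families: int,
    p: float,
    pi: float,
    sibship_lambda: float = 2.5,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    inheritance: Inheritance = Inheritance.AR,
    family_prefix: str = "SIMFAM",
) -> Tuple[List[Sibship], SibshipTruth]:
    """Simulate sibships under multiple incomplete ascertainment.

    For each of ``n_families`` families a sibship size is drawn from a
    zero-truncated Poisson(``sibship_lambda``); each child is affected
    with probability ``p`` and each affected child is independently a
    proband with probability ``pi``.  Only ascertained sibships (at least
    one proband) are returned; the truth object keeps the full cohort.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("invalid probability: p must lie in [0, 1]")
    if not (0.0 < pi <= 1.0):
        raise ValueError("invalid probability: pi must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    sizes = zero_truncated_poisson(rng, sibship_lambda, n_families)
    affected = rng.binomial(sizes, p)
    probands = rng.binomial(affected, pi)
    ascertained = probands >= 1
    sibships = [
        Sibship(
            family_id=f"{family_prefix}{index:06d}",
            size_s=int(sizes[index]),
            affected_a=int(affected[index]),
            probands_b=int(probands[index]),
            inheritance=inheritance,
        )
        for index in np.flatnonzero(ascertained)
    ]
    truth = SibshipTruth(
        n_families=n_families,
        n_segregating=int(np.sum(affected >= 1)),
        n_ascertained=int(np.sum(ascertained)),
        sizes=sizes,
        affected=affected,
        probands=probands,
    )
    return sibships, truth


# -- population simulator ----------------------------------------------


@dataclass
class SimulationTruth:
    """Ground truth for a simulated registry.

    ``placement`` has one row per (disease, region) with the true and
    observed case counts; ``records_by_source`` re-expresses the observed
    registry as raw per-source case lists for merge/deduplication tests.
    """

    config: SimulationConfig
    seed: int
    placement: pd.DataFrame
    n_true_cases: int
    n_registered_cases: int
    low_expectation_flags: List[str]
    records_by_source: Dict[str, List[Dict[str, object]]]

    def true_rate_per_100k(self, disease_id: str) -> float:
        rows = self.placement[self.placement["disease_id"] == disease_id]
        total_pop = sum(r.population_total for r in self.config.regions)
        return float(rows["n_true"].sum()) / total_pop * 100_000


def simulate_population(
    config: SimulationConfig, seed: Optional[int] = None
) -> Tuple[Registry, SimulationTruth]:
    """Simulate a multi-source case registry with known ground truth.

    True cases are placed per (disease, region) as Poisson counts at the
    configured rate.  A ``familial_fraction`` share of each disease's
    cases is grouped into same-family clusters of 2-3; every case is
    registered with its inheritance mode's ``pi`` and reported by each
    source independently with the source's sensitivity — cases reported by
    no source remain unobserved.  Sibships (true affected count, observed
    proband count) are emitted for every family with at least one
    registered case.  XL cases are male (X-linked recessive convention);
    other cases follow the region's sex split.
    """
    if seed is None:
        seed = config.seed
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_place, rng_family, rng_register, rng_sources, rng_person = (
        np.random.default_rng(s) for s in streams
    )

    sensitivities = np.array([s.sensitivity for s in config.sources])
    source_ids = [s.source_id for s in config.sources]

    patients: List[PatientRecord] = []
    sibships: List[Sibship] = []
    placement_rows: List[Dict[str, object]] = []
    flags: List[str] = []
    records_by_source: Dict[str, List[Dict[str, object]]] = {sid: [] for sid in source_ids}

    age_classes = list(AgeClass)
    age_probs = np.array([config.age_class_fractions[a] for a in age_classes])

    patient_counter = 0
    family_counter = 0

    for disease in config.diseases:
        pi = config.ascertainment_pi[disease.inheritance]
        familial_fraction = config.familial_fraction[disease.inheritance]
        for region in config.regions:
            expected = disease.true_rate_per_100k * region.population_total / 100_000
            if expected < 1:
                flags.append(
                    f"{disease.disease_id}@{region.region_id}: expected count {expected:.2f} < 1"
                )
            n_true = int(rng_place.poisson(expected))

            n_familial = int(round(familial_fraction * n_true))
            n_clusters, remainder = divmod(n_familial, 2)
            cluster_sizes = [2] * n_clusters
            if remainder and n_clusters:
                cluster_sizes[0] = 3
            n_singletons = n_true - sum(cluster_sizes)
            families = cluster_sizes + [1] * n_singletons

            n_registered_here = 0
            for a_members in families:
                family_counter += 1
                family_id = f"FAM{family_counter:06d}"
                size = int(
                    max(zero_truncated_poisson(rng_family, config.sibship_lambda, 1)[0], a_members)
                )
                registered_flags: List[List[str]] = []
                for _ in range(a_members):
                    if rng_register.random() < pi:
                        hits = rng_sources.random(len(sensitivities)) < sensitivities
                        registered_flags.append(
                            [source_ids[k] for k in np.flatnonzero(hits)]
                        )
                    else:
                        registered_flags.append([])
                registered = [srcs for srcs in registered_flags if srcs]
                b = len(registered)
                if b == 0:
                    continue
                sibships.append(
                    Sibship(
                        family_id=family_id,
                        size_s=size,
                        affected_a=a_members,
                        probands_b=b,
                        inheritance=disease.inheritance,
                    )
                )
                for member_sources in registered:
                    patient_counter += 1
                    n_registered_here += 1
                    if disease.inheritance is Inheritance.XL:
                        sex = Sex.MALE
                    else:
                        sex = (
                            Sex.MALE
                            if rng_person.random() < region.male_fraction
                            else Sex.FEMALE
                        )
                    age_class = age_classes[rng_person.choice(len(age_classes), p=age_probs)]
                    district = f"{region.region_id}-D{rng_person.integers(region.n_districts) + 1:02d}"
                    record = PatientRecord(
                        patient_id=f"SIM{patient_counter:06d}",
                        family_id=family_id,
                        region_id=region.region_id,
                        sex=sex,
                        age_class=age_class,
                        disease_id=disease.disease_id,
                        is_proband=True,
                        sources=frozenset(member_sources),
                        district_id=district,
                    )
                    patients.append(record)
                    raw = {
                        "name": f"person {record.patient_id}",
                        "birth_year": _BIRTH_YEAR[age_class],
                        "region_id": region.region_id,
                        "district_id": district,
                        "sex": sex.value,
                        "age_class": age_class.value,
                        "disease_id": disease.disease_id,
                        "family_id": family_id,
                        "is_proband": True,
                        "patient_id": record.patient_id,
                    }
                    for source_id in member_sources:
                        records_by_source[source_id].append(dict(raw))

            placement_rows.append(
                {
                    "disease_id": disease.disease_id,
                    "region_id": region.region_id,
                    "inheritance": disease.inheritance.value,
                    "n_true": n_true,
                    "n_familial_true": sum(cluster_sizes),
                    "n_registered": n_registered_here,
                }
            )

    registry = Registry.from_records(
        patients=patients,
        sibships=sibships,
        diseases=[d.entry() for d in config.diseases],
        demography=[r.demography() for r in config.regions],
    )
    placement = pd.DataFrame(
        placement_rows,
        columns=["disease_id", "region_id", "inheritance", "n_true", "n_familial_true", "n_registered"],
    )
    for flag in flags:
        logger.info("low expected count: %s", flag)
    truth = SimulationTruth(
        config=config,
        seed=seed,
        placement=placement,
        n_true_cases=int(placement["n_true"].sum()),
        n_registered_cases=len(patients),
        low_expectation_flags=flags,
        records_by_source=records_by_source,
    )
    return registry, truth
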