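"""Domain types for rare-hereditary-disease (RHD) case registries.

The registry model follows the structure of population-based surveys of
monogenic disease: patients are registered through one or more overlapping
information sources, grouped into families, assigned a catalogued disease
with a Mendelian inheritance mode (autosomal dominant, autosomal recessive,
X-linked) and a medical-specialty group, and counted against regional
census denominators.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import FrozenSet, Optional


class Inheritance(str, enum.Enum):
    """Mendelian inheritance mode of a catalogued disease."""

    AD = "AD"
    AR = "AR"
    XL = "XL"


class Specialty(str, enum.Enum):
    """Medical-specialty grouping by main clinical manifestation."""

    NEUROLOGICAL_PSYCHIATRIC = "neurological_psychiatric"
    OPHTHALMIC = "ophthalmic"
    GENODERMATOSIS = "genodermatosis"
    SKELETAL = "skeletal"
    HEREDITARY_SYNDROME = "hereditary_syndrome"
    OTHER = "other"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class AgeClass(str, enum.Enum):
    """Age bands used for patient stratification.

    ``child`` covers 0-17 years inclusive, ``reproductive`` 18-45,
    ``post_reproductive`` 46 and older.
    """

    CHILD = "child"
    REPRODUCTIVE = "reproductive"
    POST_REPRODUCTIVE = "post_reproductive"


@dataclass(frozen=True)
class PatientRecord:
    """One registered case after multi-source unification.

    ``sources`` is the set of registration channels (questionnaire cards,
    disability lists, special schools / genetic counseling, ...) through
    which the person was reported; it is non-empty for any registered case.
    """

    patient_id: str
    family_id: str
    region_id: str
    sex: Sex
    age_class: AgeClass
    disease_id: str
    is_proband: bool
    sources: FrozenSet[str]
    district_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError(f"patient {self.patient_id!r}: sources must be non-empty")


@dataclass(frozen=True)
class DiseaseEntry:
    """Catalogue row for one clinical form.

    ``disease_id`` accepts OMIM-style identifiers ("#NNNNNN") and
    phenotypic-series identifiers ("PSNNNNNN"), as well as plain strings.
    """

    disease_id: str
    name: str
    inheritance: Inheritance
    specialty: Specialty


@dataclass(frozen=True)
class Sibship:
    """Segregation-analysis unit: one sibship of ``size_s`` children with
    ``affected_a`` affected, of whom ``probands_b`` were independently
    registered (probands)."""

    family_id: str
    size_s: int
    affected_a: int
    probands_b: int
    inheritance: Inheritance

    def __post_init__(self) -> None:
        if not (0 <= self.probands_b <= self.affected_a <= self.size_s):
            raise ValueError(
                f"sibship {self.family_id!r}: need 0 <= b <= a <= s, "
                f"got b={self.probands_b}, a={self.affected_a}, s={self.size_s}"
            )
        if self.size_s < 1:
            raise ValueError(f"sibship {self.family_id!r}: size_s must be >= 1")


@dataclass(frozen=True)
class RegionDemography:
    """Census denominators for one surveyed region."""

    region_id: str
    population_total: int
    population_male: int
    population_female: int
    population_children: int
    n_districts: int = 1

    def __post_init__(self) -> None:
        if self.population_total <= 0:
            raise ValueError(f"region {self.region_id!r}: population_total must be > 0")
        if self.population_male + self.population_female != self.population_total:
            raise ValueError(
                f"region {self.region_id!r}: male + female "
                f"({self.population_male} + {self.population_female}) "
                f"!= total ({self.population_total})"
            )
        if self.population_children > self.population_total:
            raise ValueError(
                f"region {self.region_id!r}: children exceed total population"
            )
        if self.n_districts < 1:
            raise ValueError(f"region {self.region_id!r}: n_districts must be >= 1")


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A point- or cumulative-prevalence figure.

    ``rate_per_100k`` is ``case_count / denominator * 100000`` rounded
    half-away-from-zero to 2 decimals; ``one_in_n`` is the "1:N" form
    (``None`` when the count is zero); ``prevalence_class`` is the 1-7
    frequency class, when a class scheme applies.
    """

    label: str
    case_count: int
    denominator: int
    rate_per_100k: float
    one_in_n: Optional[int] = None
    prevalence_class: Optional[int] = None

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError(f"{self.label!r}: denominator must be > 0")
        if self.case_count < 0:
            raise ValueError(f"{self.label!r}: case_count must be >= 0")


def parse_sources(cell: str) -> FrozenSet[str]:
    """Parse a semicolon-joined sources cell from patients.csv."""
    parts = [p.strip() for p in str(cell).split(";") if p.strip()]
    return frozenset(parts)


def format_sources(sources: FrozenSet[str]) -> str:
    return ";".join(sorted(sources))
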