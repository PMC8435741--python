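"""Case-registry container, multi-source merge/deduplication, and summaries.

A :class:`Registry` bundles four tables — patients, sibships, disease
catalogue, region demography — as pandas DataFrames with a fixed CSV
schema.  :func:`merge_sources` implements "multiple registration": the same
person may be reported by several overlapping information sources and must
appear in the database as a single case whose ``sources`` field records
every contributing channel.  Disease conflicts between sources are
surfaced, never silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .types import (
    AgeClass,
    DiseaseEntry,
    Inheritance,
    PatientRecord,
    RegionDemography,
    Sex,
    Sibship,
    Specialty,
    format_sources,
    parse_sources,
)

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = [
    "patient_id",
    "family_id",
    "region_id",
    "sex",
    "age_class",
    "disease_id",
    "is_proband",
    "sources",
    "district_id",
]
SIBSHIP_COLUMNS = ["family_id", "size_s", "affected_a", "probands_b", "inheritance"]
DISEASE_COLUMNS = ["disease_id", "name", "inheritance", "specialty"]
REGION_COLUMNS = [
    "region_id",
    "population_total",
    "population_male",
    "population_female",
    "population_children",
    "n_districts",
]

STRATA_COLUMNS = {
    "region": "region_id",
    "inheritance": "inheritance",
    "specialty": "specialty",
    "age_class": "age_class",
    "sex": "sex",
    "disease": "disease_id",
}


class RegistryValidationError(ValueError):
    """Raised when a registry violates its schema invariants.

    ``problems`` holds one message per violation so callers can produce an
    itemized validation report.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "registry validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


def _empty_frame(columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class Registry:
    """A case registry: patients, sibships, disease catalogue, demography."""

    patients: pd.DataFrame = field(default_factory=lambda: _empty_frame(PATIENT_COLUMNS))
    sibships: pd.DataFrame = field(default_factory=lambda: _empty_frame(SIBSHIP_COLUMNS))
    diseases: pd.DataFrame = field(default_factory=lambda: _empty_frame(DISEASE_COLUMNS))
    demography: pd.DataFrame = field(default_factory=lambda: _empty_frame(REGION_COLUMNS))

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(
        cls,
        patients: Iterable[PatientRecord] = (),
        sibships: Iterable[Sibship] = (),
        diseases: Iterable[DiseaseEntry] = (),
        demography: Iterable[RegionDemography] = (),
    ) -> "Registry":
        pat = pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "family_id": p.family_id,
                    "region_id": p.region_id,
                    "sex": p.sex.value,
                    "age_class": p.age_class.value,
                    "disease_id": p.disease_id,
                    "is_proband": bool(p.is_proband),
                    "sources": format_sources(p.sources),
                    "district_id": p.district_id,
                }
                for p in patients
            ],
            columns=PATIENT_COLUMNS,
        )
        sib = pd.DataFrame(
            [
                {
                    "family_id": s.family_id,
                    "size_s": s.size_s,
                    "affected_a": s.affected_a,
                    "probands_b": s.probands_b,
                    "inheritance": s.inheritance.value,
                }
                for s in sibships
            ],
            columns=SIBSHIP_COLUMNS,
        )
        dis = pd.DataFrame(
            [
                {
                    "disease_id": d.disease_id,
                    "name": d.name,
                    "inheritance": d.inheritance.value,
                    "specialty": d.specialty.value,
                }
                for d in diseases
            ],
            columns=DISEASE_COLUMNS,
        )
        dem = pd.DataFrame(
            [
                {
                    "region_id": r.region_id,
                    "population_total": r.population_total,
                    "population_male": r.population_male,
                    "population_female": r.population_female,
                    "population_children": r.population_children,
                    "n_districts": r.n_districts,
                }
                for r in demography
            ],
            columns=REGION_COLUMNS,
        )
        return cls(patients=pat, sibships=sib, diseases=dis, demography=dem)

    @classmethod
    def from_csv_dir(cls, directory: Union[str, Path], strict: bool = False) -> "Registry":
        """Load ``patients.csv``, ``sibships.csv``, ``diseases.csv`` and
        ``regions.csv`` from ``directory``.

        ``patients.csv`` and ``regions.csv`` are required; the other two
        tables default to empty when their file is absent.
        """
        directory = Path(directory)
        missing = [
            name for name in ("patients.csv", "regions.csv") if not (directory / name).exists()
        ]
        if missing:
            raise RegistryValidationError(
                [f"required registry file missing: {directory / name}" for name in missing]
            )

        def _read(name: str, columns: Sequence[str]) -> pd.DataFrame:
            path = directory / name
            if not path.exists():
                return _empty_frame(columns)
            frame = pd.read_csv(path, dtype=str, keep_default_na=False)
            lacking = [c for c in columns if c not in frame.columns and c != "district_id"]
            if lacking:
                raise RegistryValidationError(
                    [f"{path}: missing required column {c!r}" for c in lacking]
                )
            return frame

        pat = _read("patients.csv", PATIENT_COLUMNS)
        if "district_id" not in pat.columns:
            pat["district_id"] = None
        pat["is_proband"] = pat["is_proband"].astype(str).str.lower().isin(["true", "1", "yes"])
        sib = _read("sibships.csv", SIBSHIP_COLUMNS)
        for col in ("size_s", "affected_a", "probands_b"):
            if col in sib.columns and len(sib):
                sib[col] = sib[col].astype(int)
        dis = _read("diseases.csv", DISEASE_COLUMNS)
        dem = _read("regions.csv", REGION_COLUMNS)
        for col in REGION_COLUMNS[1:]:
            if len(dem):
                dem[col] = dem[col].astype(int)
        registry = cls(patients=pat, sibships=sib, diseases=dis, demography=dem)
        registry.validate(strict=strict)
        return registry

    def to_csv_dir(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(directory / "patients.csv", index=False)
        self.sibships.to_csv(directory / "sibships.csv", index=False)
        self.diseases.to_csv(directory / "diseases.csv", index=False)
        self.demography.to_csv(directory / "regions.csv", index=False)

    # -- validation ----------------------------------------------------

    def validate(self, strict: bool = False) -> List[str]:
        """Check registry invariants.

        Returns a list of problem messages (empty when valid).  With
        ``strict=True`` any problem raises :class:`RegistryValidationError`.
        """
        problems: List[str] = []
        pat = self.patients
        if len(pat):
            dup = pat["patient_id"][pat["patient_id"].duplicated()]
            problems += [f"duplicate patient_id {pid!r}" for pid in dup.unique()]
            bad_age = set(pat["age_class"]) - {a.value for a in AgeClass}
            problems += [f"unknown age_class {a!r}" for a in sorted(bad_age)]
            bad_sex = set(pat["sex"]) - {s.value for s in Sex}
            problems += [f"unknown sex {s!r}" for s in sorted(bad_sex)]
            empty_sources = pat["patient_id"][pat["sources"].astype(str).str.strip() == ""]
            problems += [f"patient {pid!r} has empty sources" for pid in empty_sources]
            if len(self.diseases):
                known = set(self.diseases["disease_id"])
                bad = set(pat["disease_id"]) - known
                problems += [f"patient disease_id {d!r} not in catalogue" for d in sorted(bad)]
            if len(self.demography):
                known_regions = set(self.demography["region_id"])
                bad = set(pat["region_id"]) - known_regions
                problems += [f"patient region_id {r!r} not in demography" for r in sorted(bad)]
        if len(self.diseases):
            dup = self.diseases["disease_id"][self.diseases["disease_id"].duplicated()]
            problems += [f"duplicate disease_id {d!r}" for d in dup.unique()]
            bad_inh = set(self.diseases["inheritance"]) - {i.value for i in Inheritance}
            problems += [f"unknown inheritance {i!r}" for i in sorted(bad_inh)]
            bad_spec = set(self.diseases["specialty"]) - {s.value for s in Specialty}
            problems += [f"unknown specialty {s!r}" for s in sorted(bad_spec)]
        if len(self.demography):
            for row in self.demography.itertuples():
                if row.population_male + row.population_female != row.population_total:
                    problems.append(
                        f"region {row.region_id!r}: male+female != total population"
                    )
                if row.population_children > row.population_total:
                    problems.append(f"region {row.region_id!r}: children > total population")
        if len(self.sibships):
            bad = self.sibships[
                ~(
                    (self.sibships["probands_b"] <= self.sibships["affected_a"])
                    & (self.sibships["affected_a"] <= self.sibships["size_s"])
                )
            ]
            problems += [f"sibship {fid!r}: violates b <= a <= s" for fid in bad["family_id"]]
            if len(pat):
                known_families = set(pat["family_id"])
                orphans = set(self.sibships["family_id"]) - known_families
                problems += [
                    f"orphan sibship family_id {fid!r} (no registered patient)"
                    for fid in sorted(orphans)
                ]
        if strict and problems:
            raise RegistryValidationError(problems)
        return problems

    # -- summaries -----------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patients_with_inheritance(self) -> pd.DataFrame:
        """Patients joined with their catalogue inheritance and specialty."""
        if not len(self.diseases):
            raise RegistryValidationError(["disease catalogue required for this operation"])
        return self.patients.merge(
            self.diseases[["disease_id", "inheritance", "specialty"]],
            on="disease_id",
            how="left",
            validate="many_to_one",
        )


# -- multi-source merge -----------------------------------------------


def default_identity_key(record: Mapping[str, object]) -> Hashable:
    """Default person-identity key: normalized name + birth year + region.

    The name is case-folded with whitespace collapsed; no phonetic or
    fuzzy matching is attempted.
    """
    name = " ".join(str(record.get("name", "")).split()).casefold()
    return (name, str(record.get("birth_year", "")), str(record.get("region_id", "")))


@dataclass
class MergeReport:
    """Bookkeeping from a multi-source merge."""

    per_source_counts: Dict[str, int]
    multiplicity_histogram: Dict[int, int]
    n_identities: int
    n_patients: int
    n_conflicts: int
    conflicts: pd.DataFrame

    @property
    def multi_source_fraction(self) -> float:
        """Fraction of merged patients registered by more than one source."""
        total = sum(self.multiplicity_histogram.values())
        if total == 0:
            return 0.0
        multi = sum(n for k, n in self.multiplicity_histogram.items() if k >= 2)
        return multi / total


@dataclass
class MergeResult:
    registry: Registry
    report: MergeReport


def merge_sources(
    records_by_source: Mapping[str, Sequence[Mapping[str, object]]],
    identity_key: Callable[[Mapping[str, object]], Hashable] = default_identity_key,
    diseases: Optional[Iterable[DiseaseEntry]] = None,
    demography: Optional[Iterable[RegionDemography]] = None,
) -> MergeResult:
    """Unify raw per-source case lists into one registry record per person.

    Each raw record is a mapping with at least ``name``, ``birth_year``,
    ``region_id``, ``sex``, ``age_class`` and ``disease_id`` (``family_id``
    and ``is_proband`` optional).  Records sharing an identity key collapse
    to a single :class:`~rareg.types.PatientRecord` whose ``sources`` field
    is the union of contributing source identifiers.  Identities reported
    with more than one distinct ``disease_id`` are *conflicts*: they are
    excluded from the merged patient table and itemized in the report.
    """
    groups: Dict[Hashable, Dict[str, object]] = {}
    per_source_counts: Dict[str, int] = {}
    for source_id in sorted(records_by_source):
        records = records_by_source[source_id]
        per_source_counts[source_id] = len(records)
        for record in records:
            key = identity_key(record)
            entry = groups.setdefault(key, {"records": [], "sources": set()})
            entry["records"].append(dict(record))
            entry["sources"].add(source_id)

    patients: List[PatientRecord] = []
    conflict_rows: List[Dict[str, object]] = []
    histogram: Dict[int, int] = {}
    for index, key in enumerate(sorted(groups, key=repr)):
        entry = groups[key]
        records = entry["records"]
        sources = frozenset(entry["sources"])
        disease_ids = sorted({str(r["disease_id"]) for r in records})
        if len(disease_ids) > 1:
            conflict_rows.append(
                {
                    "identity": repr(key),
                    "disease_ids": ";".join(disease_ids),
                    "sources": format_sources(sources),
                    "n_records": len(records),
                }
            )
            continue
        first = records[0]
        patient_id = str(first.get("patient_id") or f"P{index + 1:06d}")
        patients.append(
            PatientRecord(
                patient_id=patient_id,
                family_id=str(first.get("family_id") or patient_id),
                region_id=str(first.get("region_id", "")),
                sex=Sex(str(first.get("sex", "female"))),
                age_class=AgeClass(str(first.get("age_class", "reproductive"))),
                disease_id=disease_ids[0],
                is_proband=bool(first.get("is_proband", True)),
                sources=sources,
                district_id=first.get("district_id"),
            )
        )
        histogram[len(sources)] = histogram.get(len(sources), 0) + 1

    registry = Registry.from_records(
        patients=patients,
        diseases=diseases or (),
        demography=demography or (),
    )
    conflicts = pd.DataFrame(
        conflict_rows, columns=["identity", "disease_ids", "sources", "n_records"]
    )
    if len(conflicts):
        logger.warning("merge_sources: %d conflicting identities excluded", len(conflicts))
    report = MergeReport(
        per_source_counts=per_source_counts,
        multiplicity_histogram=dict(sorted(histogram.items())),
        n_identities=len(groups),
        n_patients=len(patients),
        n_conflicts=len(conflicts),
        conflicts=conflicts,
    )
    return MergeResult(registry=registry, report=report)


# -- registry summaries ------------------------------------------------


def familial_case_rate(
    registry: Registry, breakdown: bool = False
) -> Union[float, Dict[str, float]]:
    """Fraction of patients whose family holds >= 2 cases of the same disease.

    Sporadic cases — sole patients of their disease within a family — count
    as non-familial regardless of inheritance mode.  With
    ``breakdown=True`` a dict is returned with the overall rate under
    ``"overall"`` plus one rate per inheritance mode present.
    """
    pat = registry.patients
    if not len(pat):
        raise ValueError("familial_case_rate undefined for an empty registry")
    sizes = pat.groupby(["family_id", "disease_id"])["patient_id"].transform("size")
    familial = sizes >= 2
    overall = float(familial.sum() / len(pat))
    if not breakdown:
        return overall
    merged = registry.patients_with_inheritance()
    merged["familial"] = familial.to_numpy()
    out: Dict[str, float] = {"overall": overall}
    for inheritance, group in merged.groupby("inheritance"):
        out[str(inheritance)] = float(group["familial"].mean())
    return out


def count_by(registry: Registry, strata: Sequence[str]) -> pd.Series:
    """Contingency table of patient counts over the requested strata.

    ``strata`` is a subset of ``{region, inheritance, specialty, age_class,
    sex, disease}``.  The result covers the full cross product of stratum
    levels (catalogue/demography levels included even at count zero), so
    cell counts always sum to the registry total.
    """
    unknown = [s for s in strata if s not in STRATA_COLUMNS]
    if unknown:
        raise ValueError(f"unknown strata: {unknown}; choose from {sorted(STRATA_COLUMNS)}")
    if not strata:
        raise ValueError("at least one stratum required")

    needs_catalogue = any(s in ("inheritance", "specialty") for s in strata)
    frame = registry.patients_with_inheritance() if needs_catalogue else registry.patients.copy()

    levels: Dict[str, List[str]] = {}
    for stratum in strata:
        column = STRATA_COLUMNS[stratum]
        if stratum == "inheritance":
            values = [i.value for i in Inheritance]
        elif stratum == "specialty":
            values = [s.value for s in Specialty]
        elif stratum == "age_class":
            values = [a.value for a in AgeClass]
        elif stratum == "sex":
            values = [s.value for s in Sex]
        elif stratum == "region" and len(registry.demography):
            values = list(registry.demography["region_id"])
        elif stratum == "disease" and len(registry.diseases):
            values = list(registry.diseases["disease_id"])
        else:
            values = sorted(set(frame[column])) if len(frame) else []
        levels[column] = values

    columns = [STRATA_COLUMNS[s] for s in strata]
    for column in columns:
        frame[column] = pd.Categorical(
            frame[column] if len(frame) else [], categories=levels[column]
        )
    if not len(frame):
        index = pd.MultiIndex.from_product(
            [levels[c] for c in columns], names=columns
        ) if len(columns) > 1 else pd.Index(levels[columns[0]], name=columns[0])
        return pd.Series(0, index=index, name="count")
    counts = frame.groupby(columns, observed=False).size()
    counts.name = "count"
    return counts
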