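"""Synthetic reference registry reproducing published survey marginals.

This module builds a fully synthetic case registry whose *marginal* counts
match the headline figures of a large multi-region survey of rare
hereditary disease: 10,265 patients with 554 clinical forms in a surveyed
population of 3,703,018 (764,260 children), with the published per-class
(prevalence class x inheritance) cell counts, per-specialty totals and
per-region totals.  All detail the published tables do not print —
per-disease region, sex, age and district splits, patient identities —
is filled deterministically (no randomness), so the fixture is a synthetic
stand-in, not a reconstruction of individual-level data.

Published figures that are internally inconsistent are reconciled here in
favour of the headline totals; every such correction is listed in the
package methods note.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .prevalence import SEVEN_CLASS_SCHEME, ClassScheme
from .registry import Registry
from .types import (
    AgeClass,
    DiseaseEntry,
    Inheritance,
    PatientRecord,
    RegionDemography,
    Sex,
    Specialty,
)

TOTAL_POPULATION = 3_703_018
CHILD_POPULATION = 764_260
MALE_POPULATION = 1_716_298
TOTAL_PATIENTS = 10_265
TOTAL_DISEASES = 554
CHILD_PATIENTS = 4_270
REPRODUCTIVE_PATIENTS = 3_819  # 37.2% of patients; remainder is post-reproductive
MALE_PATIENT_FRACTION = 0.4635

#: (patients, diseases) per prevalence class 1..7, per inheritance mode.
#: The AD class-4/class-5 disease split is (35, 21) rather than the
#: published (34, 22): 22 diseases cannot carry 214 patients inside the
#: class-5 count range on this denominator (see methods note).
CLASS_CELLS: Dict[Inheritance, List[Tuple[int, int]]] = {
    Inheritance.AD: [(3358, 17), (742, 16), (643, 26), (481, 35), (214, 21), (56, 7), (404, 144)],
    Inheritance.AR: [(2253, 11), (205, 5), (363, 10), (193, 14), (110, 11), (64, 8), (370, 170)],
    Inheritance.XL: [(534, 5), (76, 3), (72, 6), (43, 6), (10, 2), (4, 1), (70, 36)],
}

SPECIALTY_PATIENTS: Dict[Specialty, int] = {
    Specialty.NEUROLOGICAL_PSYCHIATRIC: 2418,
    Specialty.OPHTHALMIC: 1524,
    Specialty.GENODERMATOSIS: 1510,
    Specialty.SKELETAL: 1205,
    Specialty.HEREDITARY_SYNDROME: 1852,
    Specialty.OTHER: 1756,
}
SPECIALTY_DISEASES: Dict[Specialty, int] = {
    Specialty.NEUROLOGICAL_PSYCHIATRIC: 102,
    Specialty.OPHTHALMIC: 73,
    Specialty.GENODERMATOSIS: 39,
    Specialty.SKELETAL: 87,
    Specialty.HEREDITARY_SYNDROME: 204,
    Specialty.OTHER: 49,
}

#: region_id, population_total, population_children, n_districts, patient count
#: (population/children figures reconciled so the columns sum exactly to the
#: headline denominators; patient counts are the published per-region figures,
#: later rescaled so they sum to the patient total).
REGIONS: List[Tuple[str, int, int, int, int]] = [
    ("kostroma", 444_476, 80_895, 10, 673),
    ("kirov", 286_600, 51_051, 11, 589),
    ("bryansk", 88_200, 14_906, 1, 133),
    ("tver", 75_000, 15_188, 2, 131),
    ("mari_el", 276_000, 51_051, 7, 630),
    ("chuvash", 264_419, 67_863, 6, 679),
    ("udmurtia", 267_655, 60_197, 6, 794),
    ("tatarstan", 264_098, 57_648, 8, 1516),
    ("bashkortostan", 250_110, 64_935, 8, 1192),
    ("arkhangelsk", 40_000, 7_440, 5, 104),
    ("krasnodar", 426_600, 78_921, 6, 740),
    ("rostov", 497_460, 101_845, 12, 1481),
    ("adygea", 112_400, 21_581, 4, 233),
    ("karachay_cherkessia", 410_000, 90_739, 10, 1857),
]

_N = Specialty.NEUROLOGICAL_PSYCHIATRIC
_O = Specialty.OPHTHALMIC
_G = Specialty.GENODERMATOSIS
_S = Specialty.SKELETAL
_H = Specialty.HEREDITARY_SYNDROME
_X = Specialty.OTHER

#: Named catalogue entries seeding the frequent-class cells:
#: (inheritance, class) -> [(disease_id, name, specialty, published count)].
#: Counts are seeds only; they are clipped into the class count range and
#: adjusted so each cell's patient total is exact.
NAMED_DISEASES: Dict[Tuple[Inheritance, int], List[Tuple[str, str, Specialty, int]]] = {
    (Inheritance.AD, 1): [
        ("#146700", "Ichthyosis vulgaris", _G, 646),
        ("PS130000", "Ehlers-Danlos syndrome", _H, 459),
        ("#148700", "Keratosis palmoplantaris", _G, 304),
        ("PS118220", "Charcot-Marie-Tooth disease", _N, 232),
        ("PS116200", "Congenital hereditary cataract", _O, 215),
        ("#162200", "Neurofibromatosis, type I", _N, 199),
        ("PS156200", "Undifferentiated intellectual disability", _N, 177),
        ("#146000", "Hypochondroplasia", _S, 164),
        ("PS124900", "Deafness, autosomal dominant", _X, 133),
        ("178300", "Ptosis, hereditary congenital", _O, 126),
        ("PS268000", "Retinitis pigmentosa", _O, 122),
        ("PS174200", "Polydactyly, postaxial, type A1", _S, 112),
        ("151900", "Lipomatosis, multiple", _X, 108),
        ("#154700", "Marfan syndrome", _H, 105),
        ("PS166200", "Osteogenesis imperfecta", _S, 100),
        ("#185900", "Syndactyly, type I", _S, 84),
        ("PS163950", "Noonan syndrome 1", _H, 72),
    ],
    (Inheritance.AD, 2): [
        ("181800", "Scoliosis, idiopathic", _S, 69),
        ("#160900", "Dystrophia myotonica 1", _N, 65),
        ("#133700", "Exostoses, multiple, type I", _S, 56),
        ("#100800", "Achondroplasia", _S, 54),
        ("#143100", "Huntington disease", _N, 51),
        ("#120200", "Coloboma, ocular", _O, 49),
        ("PS310700", "Nystagmus, congenital", _O, 49),
        ("PS183600", "Split-hand/foot malformation 1", _S, 45),
        ("PS174400", "Polydactyly, preaxial I", _S, 44),
        ("PS303350", "Spastic paraplegia, autosomal dominant", _N, 42),
        ("#110100", "Blepharophimosis, ptosis", _O, 41),
        ("126070", "Albinoidism, oculocutaneous", _G, 39),
        ("#158900", "Facioscapulohumeral muscular dystrophy 1A", _N, 39),
        ("PS165500", "Optic atrophy 1", _O, 38),
        ("#186000", "Synpolydactyly 1", _S, 37),
        ("#106210", "Aniridia", _O, 37),
    ],
    (Inheritance.AR, 1): [
        ("PS220290", "Deafness, autosomal recessive", _X, 776),
        ("PS249500", "Undifferentiated intellectual disability, AR", _N, 431),
        ("PS251200", "Microcephaly, primary autosomal recessive", _N, 155),
        ("PS268000-AR", "Retinitis pigmentosa, AR", _O, 150),
        ("#261600", "Phenylketonuria", _X, 145),
        ("PS116200-AR", "Congenital hereditary cataract, AR", _O, 105),
        ("#242100", "Ichthyosiform erythroderma, congenital", _G, 84),
        ("PS253600", "Muscular dystrophy, limb-girdle", _N, 83),
        ("PS203100", "Albinism, oculocutaneous", _G, 81),
        ("#253300", "Spinal muscular atrophy, types I-III", _N, 72),
        ("PS262400", "Growth hormone deficiency", _X, 72),
    ],
    (Inheritance.AR, 2): [
        ("PS276900", "Usher syndrome", _X, 52),
        ("PS204000", "Leber congenital amaurosis", _O, 44),
        ("#248200", "Stargardt disease 1", _O, 43),
        ("#604379", "Hypotrichosis, total, Mari type", _G, 39),
        ("#219700", "Cystic fibrosis", _X, 37),
    ],
    (Inheritance.XL, 1): [
        ("PS309530", "Undifferentiated intellectual disability, X-linked", _N, 226),
        ("#308100", "Ichthyosis, X-linked", _G, 124),
        ("#306700", "Hemophilia A", _X, 78),
        ("#310200", "Muscular dystrophy, Duchenne type", _N, 55),
        ("PS310700-XL", "Nystagmus, congenital, X-linked", _O, 51),
    ],
    (Inheritance.XL, 2): [
        ("#305400", "Faciogenital dysplasia", _H, 32),
        ("#300376", "Muscular dystrophy, Becker type", _N, 24),
        ("#302800", "Charcot-Marie-Tooth disease, X-linked", _N, 20),
    ],
}


#: Showcase diseases whose published patient counts must survive the
#: cell-total reconciliation (residuals go to other entries instead).
LOCKED_DISEASE_IDS = frozenset(
    {"#146700", "#261600", "PS309530", "#308100", "#306700", "#310200", "PS310700-XL"}
)


def class_count_range(
    klass: int, denominator: int, scheme: ClassScheme = SEVEN_CLASS_SCHEME
) -> Tuple[int, Optional[int]]:
    """Inclusive case-count range [cmin, cmax] of a prevalence class.

    ``cmax`` is ``None`` for the most frequent class (unbounded above).
    """
    thresholds = scheme.thresholds
    if not (1 <= klass <= scheme.n_classes):
        raise ValueError(f"class {klass} outside scheme")
    if klass == 1:
        return -(-denominator // thresholds[0]), None
    if klass == scheme.n_classes:
        return 1, -(-denominator // thresholds[-1]) - 1
    cmin = -(-denominator // thresholds[klass - 1])
    cmax = -(-denominator // thresholds[klass - 2]) - 1
    return cmin, cmax


def _allocate(
    total: int,
    k: int,
    cmin: int,
    cmax: Optional[int],
    seeds: Optional[Sequence[int]] = None,
    locked: frozenset = frozenset(),
) -> List[int]:
    """Deterministically pick k integer counts in [cmin, cmax] summing to total.

    Seeds are clipped into range; any residual is concentrated on the
    largest unlocked entries so that ``locked`` seed counts survive intact
    whenever the cell admits it.
    """

    def clip(value: int) -> int:
        value = max(value, cmin)
        return value if cmax is None else min(value, cmax)

    if seeds is not None:
        if len(seeds) != k:
            raise ValueError("seed length mismatch")
        counts = [clip(int(s)) for s in seeds]
    else:
        counts = [clip(total // k) for _ in range(k)]
    diff = total - sum(counts)
    if diff:
        order = sorted(range(k), key=lambda i: (i in locked, -counts[i]))
        for index in order:
            if diff == 0:
                break
            if diff > 0:
                take = diff if cmax is None else min(diff, cmax - counts[index])
            else:
                take = -min(-diff, counts[index] - cmin)
            counts[index] += take
            diff -= take
        if diff:
            raise ValueError(
                f"infeasible allocation: total={total}, k={k}, range=[{cmin}, {cmax}]"
            )
    return counts


def _largest_remainder(weights: Sequence[float], total: int) -> List[int]:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    raw = [w * total / sum(weights) for w in weights]
    floors = [int(f) for f in raw]
    shortfall = total - sum(floors)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - floors[i], -i), reverse=True)
    for i in order[:shortfall]:
        floors[i] += 1
    return floors


class _FixtureDisease:
    __slots__ = ("disease_id", "name", "inheritance", "klass", "count", "cmin", "cmax", "specialty", "named")

    def __init__(self, disease_id, name, inheritance, klass, count, cmin, cmax, specialty, named):
        self.disease_id = disease_id
        self.name = name
        self.inheritance = inheritance
        self.klass = klass
        self.count = count
        self.cmin = cmin
        self.cmax = cmax
        self.specialty = specialty
        self.named = named


def _build_diseases() -> List[_FixtureDisease]:
    """Disease list with exact (inheritance x class) patient/disease cells."""
    diseases: List[_FixtureDisease] = []
    synthetic_serial = 0
    for inheritance, cells in CLASS_CELLS.items():
        denominator = MALE_POPULATION if inheritance is Inheritance.XL else TOTAL_POPULATION
        for klass, (cell_patients, cell_diseases) in enumerate(cells, start=1):
            cmin, cmax = class_count_range(klass, denominator)
            named = NAMED_DISEASES.get((inheritance, klass), [])
            if len(named) > cell_diseases:
                raise ValueError("more named diseases than the cell admits")
            base = max(cell_patients // cell_diseases, cmin)
            seeds = [entry[3] for entry in named] + [base] * (cell_diseases - len(named))
            locked = frozenset(
                i for i, entry in enumerate(named) if entry[0] in LOCKED_DISEASE_IDS
            )
            counts = _allocate(cell_patients, cell_diseases, cmin, cmax, seeds, locked)
            for index in range(cell_diseases):
                if index < len(named):
                    disease_id, name, specialty, _ = named[index]
                    is_named = True
                else:
                    synthetic_serial += 1
                    disease_id = f"#9{synthetic_serial:05d}"
                    name = (
                        f"Synthetic {inheritance.value} disorder, class {klass}, "
                        f"no. {synthetic_serial} (synthetic)"
                    )
                    specialty = None
                    is_named = False
                diseases.append(
                    _FixtureDisease(
                        disease_id,
                        name,
                        inheritance,
                        klass,
                        counts[index],
                        cmin,
                        cmax,
                        specialty,
                        is_named,
                    )
                )
    return diseases


def _assign_specialties(diseases: List[_FixtureDisease]) -> None:
    """Assign specialties so per-specialty disease AND patient totals are exact.

    Named diseases keep their clinical specialty.  Synthetic diseases are
    assigned greedily to track the remaining patients-per-disease ratio of
    each specialty, then a repair pass moves patients between same-cell
    diseases (and swaps synthetic labels) until every specialty total
    matches.
    """
    remaining_diseases = dict(SPECIALTY_DISEASES)
    remaining_patients = dict(SPECIALTY_PATIENTS)
    for disease in diseases:
        if disease.named:
            remaining_diseases[disease.specialty] -= 1
            remaining_patients[disease.specialty] -= disease.count
    if any(v < 0 for v in remaining_diseases.values()):
        raise ValueError("named diseases exceed a specialty disease quota")

    for disease in sorted(
        (d for d in diseases if not d.named), key=lambda d: -d.count
    ):
        best, best_score = None, None
        for specialty, quota in remaining_diseases.items():
            if quota <= 0:
                continue
            mean_target = remaining_patients[specialty] / quota
            score = abs(mean_target - disease.count)
            if best_score is None or score < best_score:
                best, best_score = specialty, score
        if best is None:
            raise ValueError("ran out of specialty disease quota")
        disease.specialty = best
        remaining_diseases[best] -= 1
        remaining_patients[best] -= disease.count

    # Repair patient totals with quota-preserving moves.
    def deltas() -> Dict[Specialty, int]:
        sums = {s: 0 for s in Specialty}
        for d in diseases:
            sums[d.specialty] += d.count
        return {s: SPECIALTY_PATIENTS[s] - sums[s] for s in Specialty}

    by_cell: Dict[Tuple[Inheritance, int], List[_FixtureDisease]] = {}
    for d in diseases:
        by_cell.setdefault((d.inheritance, d.klass), []).append(d)

    for _ in range(20_000):
        delta = deltas()
        under = [s for s in Specialty if delta[s] > 0]
        over = [s for s in Specialty if delta[s] < 0]
        if not under:
            break
        moved = False
        under.sort(key=lambda s: -delta[s])
        over.sort(key=lambda s: delta[s])
        for j_plus in under:
            for j_minus in over:
                # Count shift: +1..k to a j_plus disease, -same from a
                # j_minus disease in the same cell (keeps cell sums exact).
                for cell_diseases in by_cell.values():
                    gainers = [
                        d
                        for d in cell_diseases
                        if d.specialty == j_plus
                        and d.disease_id not in LOCKED_DISEASE_IDS
                        and (d.cmax is None or d.count < d.cmax)
                    ]
                    losers = [
                        d
                        for d in cell_diseases
                        if d.specialty == j_minus
                        and d.disease_id not in LOCKED_DISEASE_IDS
                        and d.count > d.cmin
                    ]
                    if not gainers or not losers:
                        continue
                    gainers.sort(key=lambda d: d.named)  # synthetic first
                    losers.sort(key=lambda d: d.named)
                    gainer, loser = gainers[0], losers[0]
                    head_gain = (
                        delta[j_plus]
                        if gainer.cmax is None
                        else min(delta[j_plus], gainer.cmax - gainer.count)
                    )
                    amount = min(head_gain, -delta[j_minus], loser.count - loser.cmin)
                    if amount <= 0:
                        continue
                    gainer.count += amount
                    loser.count -= amount
                    moved = True
                    break
                if moved:
                    break
            if moved:
                break
        if moved:
            continue
        # Label swap fallback between same-cell synthetic diseases.
        best_swap = None
        delta = deltas()
        for j_plus in under:
            for j_minus in over:
                for cell_diseases in by_cell.values():
                    plus_side = [d for d in cell_diseases if not d.named and d.specialty == j_plus]
                    minus_side = [d for d in cell_diseases if not d.named and d.specialty == j_minus]
                    for d_plus in plus_side:
                        for d_minus in minus_side:
                            change = d_minus.count - d_plus.count
                            if change <= 0:
                                continue
                            if change <= min(delta[j_plus], -delta[j_minus]):
                                if best_swap is None or change > best_swap[0]:
                                    best_swap = (change, d_plus, d_minus)
        if best_swap is None:
            raise ValueError("specialty repair stalled; fixture quotas infeasible")
        _, d_plus, d_minus = best_swap
        d_plus.specialty, d_minus.specialty = d_minus.specialty, d_plus.specialty
    else:
        raise ValueError("specialty repair did not converge")

    final = deltas()
    if any(final.values()):
        raise ValueError(f"specialty totals not met: {final}")


def _cumulative_flags(total: int, positives: int) -> List[bool]:
    """Deterministic evenly spread boolean sequence with an exact count."""
    flags = []
    acc = 0
    for index in range(total):
        nxt = (index + 1) * positives // total
        flags.append(nxt > acc)
        acc = nxt
    return flags


def make_reference_registry() -> Registry:
    """Build the synthetic reference registry (marginals match the survey).

    Deterministic: repeated calls return identical registries.
    """
    diseases = _build_diseases()
    _assign_specialties(diseases)

    region_ids = [r[0] for r in REGIONS]
    region_totals = [r[1] for r in REGIONS]
    region_children = [r[2] for r in REGIONS]
    region_districts = [r[3] for r in REGIONS]
    region_patient_quota = _largest_remainder([r[4] for r in REGIONS], TOTAL_PATIENTS)
    region_male = _largest_remainder(region_totals, MALE_POPULATION)

    demography = [
        RegionDemography(
            region_id=region_ids[i],
            population_total=region_totals[i],
            population_male=region_male[i],
            population_female=region_totals[i] - region_male[i],
            population_children=region_children[i],
            n_districts=region_districts[i],
        )
        for i in range(len(REGIONS))
    ]

    catalogue = [
        DiseaseEntry(
            disease_id=d.disease_id,
            name=d.name,
            inheritance=d.inheritance,
            specialty=d.specialty,
        )
        for d in diseases
    ]

    child_flags = _cumulative_flags(TOTAL_PATIENTS, CHILD_PATIENTS)
    non_child_total = TOTAL_PATIENTS - CHILD_PATIENTS
    repro_flags = _cumulative_flags(non_child_total, REPRODUCTIVE_PATIENTS)

    # Transportation of patients onto regions: walk diseases in order and
    # fill region quotas sequentially (northwest-corner rule).
    patients: List[PatientRecord] = []
    region_cursor = 0
    region_left = list(region_patient_quota)
    district_cursor = [0] * len(REGIONS)
    male_count = 0
    patient_index = 0
    non_child_index = 0
    for disease in diseases:
        for _ in range(disease.count):
            while region_left[region_cursor] == 0:
                region_cursor += 1
            region_left[region_cursor] -= 1
            region_pos = region_cursor
            district_no = district_cursor[region_pos] % region_districts[region_pos] + 1
            district_cursor[region_pos] += 1

            if child_flags[patient_index]:
                age_class = AgeClass.CHILD
            else:
                age_class = (
                    AgeClass.REPRODUCTIVE
                    if repro_flags[non_child_index]
                    else AgeClass.POST_REPRODUCTIVE
                )
                non_child_index += 1

            if disease.inheritance is Inheritance.XL:
                sex = Sex.MALE
            else:
                target_males = int(round(MALE_PATIENT_FRACTION * (patient_index + 1)))
                sex = Sex.MALE if male_count < target_males else Sex.FEMALE
            if sex is Sex.MALE:
                male_count += 1

            patient_id = f"REF{patient_index + 1:05d}"
            patients.append(
                PatientRecord(
                    patient_id=patient_id,
                    family_id=patient_id,
                    region_id=region_ids[region_pos],
                    sex=sex,
                    age_class=age_class,
                    disease_id=disease.disease_id,
                    is_proband=True,
                    sources=frozenset({"questionnaire_cards"}),
                    district_id=f"{region_ids[region_pos]}-D{district_no:02d}",
                )
            )
            patient_index += 1

    return Registry.from_records(
        patients=patients, diseases=catalogue, demography=demography
    )


def write_reference_fixture(directory: Union[str, Path]) -> Registry:
    """Write the reference registry CSVs to ``directory`` and return it."""
    registry = make_reference_registry()
    registry.to_csv_dir(directory)
    return registry
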