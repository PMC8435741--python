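import pytest

from rareg import (
    AgeClass,
    DiseaseEntry,
    Inheritance,
    PatientRecord,
    RegionDemography,
    Registry,
    Sex,
    Specialty,
    default_config,
    make_reference_registry,
    simulate_population,
)


def make_patient(
    pid,
    disease="#100001",
    family=None,
    region="R01",
    sex=Sex.FEMALE,
    age=AgeClass.REPRODUCTIVE,
    sources=("questionnaire_cards",),
    district=None,
):
    return PatientRecord(
        patient_id=pid,
        family_id=family or pid,
        region_id=region,
        sex=sex,
        age_class=age,
        disease_id=disease,
        is_proband=True,
        sources=frozenset(sources),
        district_id=district,
    )


DISEASES = [
    DiseaseEntry("#100001", "Toy dominant disorder", Inheritance.AD, Specialty.SKELETAL),
    DiseaseEntry("#200001", "Toy recessive disorder", Inheritance.AR, Specialty.OTHER),
    DiseaseEntry("#300001", "Toy X-linked disorder", Inheritance.XL, Specialty.NEUROLOGICAL_PSYCHIATRIC),
]

REGION = RegionDemography(
    region_id="R01",
    population_total=1_000_000,
    population_male=480_000,
    population_female=520_000,
    population_children=200_000,
    n_districts=2,
)


def make_toy_registry(patients, sibships=(), diseases=DISEASES, demography=(REGION,)):
    return Registry.from_records(
        patients=patients, sibships=sibships, diseases=diseases, demography=demography
    )


@pytest.fixture(scope="session")
def reference_registry():
    """The synthetic reference registry (built once per session)."""
    return make_reference_registry()


@pytest.fixture(scope="session")
def simulated_bundle():
    """A desk-scale simulated registry with its ground truth."""
    config = default_config(seed=11)
    return simulate_population(config, seed=11)
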