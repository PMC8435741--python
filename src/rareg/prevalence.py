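"""Point and cumulative prevalence estimation and stratified rate tables.

Conventions used throughout:

* rates are reported per 100,000 population, rounded half-away-from-zero
  to two decimals;
* the "1:N" ratio form is the denominator over the case count, rounded to
  the nearest integer;
* diseases are binned into seven point-prevalence classes with clean
  half-open boundaries at 1:50,000 ... 1:500,000 (boundary rates assigned
  to the more frequent class);
* X-linked prevalence uses a male denominator — by default half the total
  population for rate columns, and the census male population for class
  binning when demography is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .registry import Registry
from .types import Inheritance, PrevalenceEstimate, Specialty

logger = logging.getLogger(__name__)


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (so 17.445 -> 17.45, -0.005 -> -0.01).

    Python's built-in ``round`` is banker's rounding; rate tables follow
    the half-away-from-zero convention instead.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def point_prevalence(case_count: int, denominator: int, per: int = 100_000) -> float:
    """Reported cases per ``per`` (default 100,000) people, 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if case_count < 0:
        raise ValueError("case_count must be >= 0")
    return round_half_away(case_count / denominator * per, 2)


def one_in_n(case_count: int, denominator: int) -> int:
    """The "1:N" ratio form of a prevalence (N people per case)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if case_count <= 0:
        raise ValueError("ratio undefined for zero cases")
    return int(round_half_away(denominator / case_count, 0))


@dataclass(frozen=True)
class ClassScheme:
    """Ordered point-prevalence classes as half-open rate intervals.

    ``thresholds`` are the "1:T" boundaries in increasing T; class ``i``
    (1-based) holds rates in ``[1/thresholds[i-1], 1/thresholds[i-2])``,
    the first class is ``>= 1/thresholds[0]`` and the last class (index
    ``len(thresholds) + 1``) is everything rarer than ``1/thresholds[-1]``,
    including zero counts.
    """

    thresholds: Tuple[int, ...]
    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("need exactly one label per class (thresholds + 1)")

    @property
    def n_classes(self) -> int:
        return len(self.thresholds) + 1


#: The seven-class scheme used for RHD diversity analysis.
SEVEN_CLASS_SCHEME = ClassScheme(
    thresholds=(50_000, 100_000, 200_000, 300_000, 400_000, 500_000),
    labels=(
        "1:50,000 and more",
        "1:50,001-1:100,000",
        "1:100,001-1:200,000",
        "1:200,001-1:300,000",
        "1:300,001-1:400,000",
        "1:400,001-1:500,000",
        "1:500,001 and less",
    ),
)


def bin_prevalence_class(
    case_count: int,
    denominator: int,
    scheme: ClassScheme = SEVEN_CLASS_SCHEME,
) -> int:
    """Assign a point prevalence to its frequency class (1-based).

    Comparisons are exact integer cross-multiplications, so a rate of
    exactly 1:50,000 lands in class 1 (boundary assigned upward, to the
    more frequent class).  A zero count falls in the rarest class.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if case_count < 0:
        raise ValueError("case_count must be >= 0")
    for index, threshold in enumerate(scheme.thresholds):
        if case_count * threshold >= denominator:
            return index + 1
    return scheme.n_classes


def xl_male_prevalence(
    case_count: int,
    population_total: int,
    male_fraction: float = 0.5,
) -> float:
    """X-linked prevalence per 100,000 males.

    The male denominator is ``male_fraction * population_total``; the 0.5
    default is the conventional equal-sex approximation (the observed male
    share in the surveyed regions, ~0.464, can be passed instead).
    """
    if not (0.0 < male_fraction < 1.0):
        raise ValueError("male_fraction must lie in (0, 1)")
    if population_total <= 0:
        raise ValueError("population_total must be > 0")
    if case_count < 0:
        raise ValueError("case_count must be >= 0")
    return round_half_away(case_count / (male_fraction * population_total) * 100_000, 2)


# -- registry-level estimates ------------------------------------------


def _stratum_counts(registry: Registry, stratum: Union[str, Tuple[str, str]]) -> Tuple[str, int, int]:
    """Resolve (label, case_count, denominator) for a cumulative stratum."""
    pat = registry.patients
    dem = registry.demography
    if not len(dem):
        raise ValueError("demography required for cumulative prevalence")
    if isinstance(stratum, tuple):
        kind, region_id = stratum
        if kind != "region":
            raise ValueError(f"unknown stratum {stratum!r}")
        rows = dem[dem["region_id"] == region_id]
        if not len(rows):
            raise ValueError(f"region {region_id!r} missing from demography")
        count = int((pat["region_id"] == region_id).sum())
        return f"region:{region_id}", count, int(rows["population_total"].iloc[0])
    if stratum == "all":
        return "all", len(pat), int(dem["population_total"].sum())
    if stratum == "children":
        count = int((pat["age_class"] == "child").sum())
        return "children", count, int(dem["population_children"].sum())
    if stratum in ("male", "female"):
        count = int((pat["sex"] == stratum).sum())
        return stratum, count, int(dem[f"population_{stratum}"].sum())
    raise ValueError(f"unknown stratum {stratum!r}")


def cumulative_prevalence(
    registry: Registry,
    stratum: Union[str, Tuple[str, str]] = "all",
    scheme: ClassScheme = SEVEN_CLASS_SCHEME,
) -> PrevalenceEstimate:
    """Cumulative prevalence of all registered disease in a stratum.

    ``stratum`` is one of ``"all"``, ``"children"``, ``"male"``,
    ``"female"`` or ``("region", region_id)``.  Children are counted
    against the child population, regions against their own total.
    """
    label, count, denominator = _stratum_counts(registry, stratum)
    return PrevalenceEstimate(
        label=label,
        case_count=count,
        denominator=denominator,
        rate_per_100k=point_prevalence(count, denominator),
        one_in_n=one_in_n(count, denominator) if count > 0 else None,
        prevalence_class=bin_prevalence_class(count, denominator, scheme),
    )


def disease_prevalences(
    registry: Registry,
    scheme: ClassScheme = SEVEN_CLASS_SCHEME,
    xl_male_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-disease counts, rates and prevalence classes.

    AD/AR rates and classes use the total population.  XL rates follow the
    male-referenced convention with ``xl_male_fraction`` of the total as
    denominator, while XL class binning uses the census male population
    (the denominator actually surveyed for X-linked pathology).
    """
    merged = registry.patients_with_inheritance()
    if not len(registry.demography):
        raise ValueError("demography required for disease prevalences")
    total = int(registry.demography["population_total"].sum())
    male = int(registry.demography["population_male"].sum())
    counts = merged.groupby("disease_id").size()
    catalogue = registry.diseases.set_index("disease_id")
    rows = []
    for disease_id, count in counts.items():
        inheritance = catalogue.loc[disease_id, "inheritance"]
        is_xl = inheritance == Inheritance.XL.value
        denominator = male if is_xl else total
        rate = (
            xl_male_prevalence(int(count), total, xl_male_fraction)
            if is_xl
            else point_prevalence(int(count), total)
        )
        rows.append(
            {
                "disease_id": disease_id,
                "name": catalogue.loc[disease_id, "name"],
                "inheritance": inheritance,
                "specialty": catalogue.loc[disease_id, "specialty"],
                "n_patients": int(count),
                "rate_per_100k": rate,
                "one_in_n": one_in_n(int(count), denominator),
                "prevalence_class": bin_prevalence_class(int(count), denominator, scheme),
            }
        )
    return pd.DataFrame(rows).sort_values("n_patients", ascending=False).reset_index(drop=True)


def build_class_table(
    registry: Registry,
    scheme: ClassScheme = SEVEN_CLASS_SCHEME,
) -> pd.DataFrame:
    """Patients and diseases per (prevalence class x inheritance mode).

    Rows are the classes of ``scheme`` plus a ``Total`` row; columns carry,
    per inheritance mode and overall, the patient count, its percentage of
    the mode's patients, the disease count and its percentage of the
    mode's diseases.  Row sums reproduce the inheritance totals exactly.
    """
    per_disease = disease_prevalences(registry, scheme)
    modes = [i.value for i in Inheritance]
    patients_total = {m: int(per_disease.loc[per_disease["inheritance"] == m, "n_patients"].sum()) for m in modes}
    diseases_total = {m: int((per_disease["inheritance"] == m).sum()) for m in modes}
    patients_total["Total"] = sum(patients_total.values())
    diseases_total["Total"] = sum(diseases_total.values())

    records = []
    for klass in range(1, scheme.n_classes + 1):
        in_class = per_disease[per_disease["prevalence_class"] == klass]
        row: Dict[str, object] = {"prevalence_class": klass, "label": scheme.labels[klass - 1]}
        for mode in modes + ["Total"]:
            subset = in_class if mode == "Total" else in_class[in_class["inheritance"] == mode]
            n_pat = int(subset["n_patients"].sum())
            n_dis = int(len(subset))
            row[f"{mode}_patients"] = n_pat
            row[f"{mode}_patients_pct"] = (
                round_half_away(100.0 * n_pat / patients_total[mode], 2) if patients_total[mode] else 0.0
            )
            row[f"{mode}_diseases"] = n_dis
            row[f"{mode}_diseases_pct"] = (
                round_half_away(100.0 * n_dis / diseases_total[mode], 2) if diseases_total[mode] else 0.0
            )
        records.append(row)
    total_row: Dict[str, object] = {"prevalence_class": 0, "label": "Total"}
    for mode in modes + ["Total"]:
        total_row[f"{mode}_patients"] = patients_total[mode]
        total_row[f"{mode}_patients_pct"] = 100.0 if patients_total[mode] else 0.0
        total_row[f"{mode}_diseases"] = diseases_total[mode]
        total_row[f"{mode}_diseases_pct"] = 100.0 if diseases_total[mode] else 0.0
    records.append(total_row)
    return pd.DataFrame(records)


def build_specialty_table(registry: Registry) -> pd.DataFrame:
    """Patients, rates and disease counts per medical-specialty group.

    Rates use the total surveyed population.  Raises when any registered
    disease lacks a specialty assignment.
    """
    merged = registry.patients_with_inheritance()
    missing = merged.loc[merged["specialty"].isna(), "disease_id"].unique()
    if len(missing):
        raise ValueError(
            "diseases without specialty assignment: " + ", ".join(sorted(map(str, missing)))
        )
    if not len(registry.demography):
        raise ValueError("demography required for specialty rates")
    total_pop = int(registry.demography["population_total"].sum())
    n_patients = len(merged)
    n_diseases = merged["disease_id"].nunique()
    rows = []
    for specialty in Specialty:
        subset = merged[merged["specialty"] == specialty.value]
        n_pat = int(len(subset))
        n_dis = int(subset["disease_id"].nunique())
        rows.append(
            {
                "specialty": specialty.value,
                "n_patients": n_pat,
                "patients_pct": round_half_away(100.0 * n_pat / n_patients, 2) if n_patients else 0.0,
                "rate_per_100k": point_prevalence(n_pat, total_pop),
                "n_diseases": n_dis,
                "diseases_pct": round_half_away(100.0 * n_dis / n_diseases, 2) if n_diseases else 0.0,
            }
        )
    return pd.DataFrame(rows)


def build_region_table(registry: Registry) -> pd.DataFrame:
    """Per-region patient counts with min/max district cumulative prevalence.

    Requires district assignment on patients.  District denominators are
    the region population split evenly over its districts.  Districts with
    zero cases are excluded from the min/max with a warning.
    """
    pat = registry.patients
    dem = registry.demography
    if not len(dem):
        raise ValueError("demography required for the region table")
    if "district_id" not in pat.columns or pat["district_id"].isna().all() or (
        len(pat) and (pat["district_id"].astype(str) == "").all()
    ):
        raise ValueError("district-level assignment missing from patients")
    rows = []
    for region in dem.itertuples():
        if region.n_districts < 1:
            raise ValueError(f"region {region.region_id!r} has no districts")
        district_pop = region.population_total / region.n_districts
        in_region = pat[pat["region_id"] == region.region_id]
        counts = in_region.groupby("district_id").size()
        ratios: List[int] = []
        for district, count in counts.items():
            if count == 0:
                continue
            ratios.append(one_in_n(int(count), int(round(district_pop))))
        n_empty = region.n_districts - len(counts[counts > 0])
        if n_empty > 0:
            logger.warning(
                "region %s: %d district(s) without cases excluded from min/max",
                region.region_id,
                n_empty,
            )
        rows.append(
            {
                "region_id": region.region_id,
                "n_patients": int(len(in_region)),
                "n_districts": int(region.n_districts),
                "population_total": int(region.population_total),
                "rate_per_100k": point_prevalence(int(len(in_region)), int(region.population_total)),
                "min_one_in_n": min(ratios) if ratios else None,
                "max_one_in_n": max(ratios) if ratios else None,
                "ratio_range": (
                    f"1:{min(ratios)}-1:{max(ratios)}" if ratios else ""
                ),
            }
        )
    return pd.DataFrame(rows)
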