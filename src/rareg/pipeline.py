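"""End-to-end orchestration: simulate or ingest, then analyze and report.

:func:`run_pipeline` runs the full analysis on either a registry loaded
from CSV files or a simulated registry, producing a
:class:`ReportBundle` with every stratified table, the segregation and
ascertainment estimates, and headline cumulative-prevalence figures.  The
bundle can be written to an output directory as TSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd

from . import prevalence as prev
from .registry import Registry, RegistryValidationError, familial_case_rate
from .segregation import SegregationReportEntry, segregation_report
from .simulate import SimulationConfig, SimulationTruth, simulate_population
from .types import Inheritance

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline run configuration.

    Exactly one of ``registry_dir`` (CSV ingestion) or ``simulation``
    must be supplied.
    """

    registry_dir: Optional[Union[str, Path]] = None
    simulation: Optional[SimulationConfig] = None
    out_dir: Optional[Union[str, Path]] = None
    seed: Optional[int] = None
    strict: bool = False

    def __post_init__(self) -> None:
        if (self.registry_dir is None) == (self.simulation is None):
            raise ValueError("supply exactly one of registry_dir or simulation config")


@dataclass
class ReportBundle:
    """All pipeline outputs for one run."""

    registry: Registry
    headline: Dict[str, object]
    class_table: pd.DataFrame
    specialty_table: pd.DataFrame
    region_table: Optional[pd.DataFrame]
    disease_table: pd.DataFrame
    segregation: Dict[str, Dict[str, object]]
    familial_rate: Optional[Dict[str, float]]
    truth: Optional[SimulationTruth] = None
    log_lines: List[str] = field(default_factory=list)

    def write(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.class_table.to_csv(directory / "class_table.tsv", sep="\t", index=False)
        self.specialty_table.to_csv(directory / "specialty_table.tsv", sep="\t", index=False)
        self.disease_table.to_csv(directory / "disease_table.tsv", sep="\t", index=False)
        if self.region_table is not None:
            self.region_table.to_csv(directory / "region_table.tsv", sep="\t", index=False)
        summary = {
            "headline": self.headline,
            "segregation": self.segregation,
            "familial_rate": self.familial_rate,
            "log": self.log_lines,
        }
        (directory / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def _segregation_to_dict(entries: Dict[Inheritance, SegregationReportEntry]) -> Dict[str, Dict[str, object]]:
    out: Dict[str, Dict[str, object]] = {}
    for inheritance, entry in entries.items():
        payload: Dict[str, object] = dataclasses.asdict(entry.segregation)
        if entry.ascertainment is not None:
            payload["ascertainment"] = dataclasses.asdict(entry.ascertainment)
        out[inheritance.value] = payload
    return out


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the registry analysis pipeline; deterministic given inputs + seed."""
    log_lines: List[str] = []
    truth: Optional[SimulationTruth] = None
    if config.registry_dir is not None:
        registry = Registry.from_csv_dir(config.registry_dir, strict=config.strict)
        log_lines.append(f"ingest: loaded registry from {config.registry_dir}")
    else:
        registry, truth = simulate_population(config.simulation, seed=config.seed)
        log_lines.append(
            f"simulate: seed={truth.seed}, true cases={truth.n_true_cases}, "
            f"registered={truth.n_registered_cases}"
        )
    problems = registry.validate(strict=config.strict)
    for problem in problems:
        log_lines.append(f"validation: {problem}")
    log_lines.append(
        f"registry: {registry.n_patients} patients, "
        f"{registry.patients['disease_id'].nunique()} diseases, "
        f"{len(registry.demography)} regions, {len(registry.sibships)} sibships"
    )

    headline: Dict[str, object] = {}
    for stratum in ("all", "children"):
        estimate = prev.cumulative_prevalence(registry, stratum)
        headline[stratum] = {
            "case_count": estimate.case_count,
            "denominator": estimate.denominator,
            "rate_per_100k": estimate.rate_per_100k,
            "one_in_n": estimate.one_in_n,
        }
    total_pop = int(registry.demography["population_total"].sum())
    child_pop = int(registry.demography["population_children"].sum())
    headline["child_population_share_pct"] = prev.round_half_away(
        100.0 * child_pop / total_pop, 2
    )

    class_table = prev.build_class_table(registry)
    specialty_table = prev.build_specialty_table(registry)
    disease_table = prev.disease_prevalences(registry)
    log_lines.append(
        f"tables: class rows={len(class_table)}, specialties={len(specialty_table)}, "
        f"diseases={len(disease_table)}"
    )
    try:
        region_table: Optional[pd.DataFrame] = prev.build_region_table(registry)
    except ValueError as exc:
        region_table = None
        log_lines.append(f"region table skipped: {exc}")

    if len(registry.sibships):
        segregation = _segregation_to_dict(segregation_report(registry))
        log_lines.append(f"segregation: analyzed {len(registry.sibships)} sibships")
    else:
        segregation = {}
        log_lines.append("segregation skipped: no sibships in registry")

    familial: Optional[Dict[str, float]]
    try:
        familial = familial_case_rate(registry, breakdown=True)
    except (ValueError, RegistryValidationError) as exc:
        familial = None
        log_lines.append(f"familial rate skipped: {exc}")

    bundle = ReportBundle(
        registry=registry,
        headline=headline,
        class_table=class_table,
        specialty_table=specialty_table,
        region_table=region_table,
        disease_table=disease_table,
        segregation=segregation,
        familial_rate=familial,
        truth=truth,
        log_lines=log_lines,
    )
    if config.out_dir is not None:
        bundle.write(config.out_dir)
        if truth is not None:
            registry.to_csv_dir(Path(config.out_dir) / "registry")
    return bundle
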