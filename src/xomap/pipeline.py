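"""End-to-end experiment orchestration.

``run_experiment`` drives simulate -> call -> statistics -> coincidence for
one or more population groups and writes every table plus a JSON report;
``reanalyze_co_table`` recomputes the downstream statistics (counts,
inter-CO distances, CoC curve) from an existing crossover table without any
calling step, e.g. from a published supplementary table converted to this
package's TSV dialect.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd
import yaml

from . import __version__
from .calling import CallerConfig, call_population, recovery_metrics
from .crossovers import COTable, read_co_table, write_co_table
from .errors import ValidationError
from .genome import GenomeMap, read_genome_yaml, write_genome_yaml, write_markers_tsv
from .genotypes import write_genotype_table
from .interference import CoCConfig, assign_intervals, coc_curve, coc_pairwise
from .simulate import SimulationConfig, default_genome, simulate_population
from .stats import inter_co_distances, landscape, per_gamete_counts

__all__ = ["GroupSpec", "ExperimentConfig", "run_experiment", "reanalyze_co_table"]

log = logging.getLogger("xomap")


@dataclass(frozen=True)
class GroupSpec:
    """One population group of the experiment (e.g. WT male, n = 100)."""

    group: str
    sex: str
    n_individuals: int
    lambda_c: float | None = None  # override of the base simulation rate
    nu: float | None = None


@dataclass(frozen=True)
class ExperimentConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    coc: CoCConfig = field(default_factory=CoCConfig)
    groups: tuple[GroupSpec, ...] = ()
    chromosomes: tuple[str, ...] | None = None
    outdir: str = "xomap_run"

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim_doc = dict(doc.get("simulation") or {})
        genome = default_genome()
        if "genome" in sim_doc:
            g = sim_doc.pop("genome")
            genome = GenomeMap(
                {str(k): int(v) for k, v in g["chromosomes"].items()},
                {str(k): tuple(v) for k, v in (g.get("centromeres") or {}).items()},
            )
        sim = SimulationConfig(genome=genome, **sim_doc)
        caller = CallerConfig(**(doc.get("caller") or {}))
        coc_doc = dict(doc.get("coc") or {})
        if "chromosomes" in coc_doc and coc_doc["chromosomes"] is not None:
            coc_doc["chromosomes"] = tuple(coc_doc["chromosomes"])
        coc = CoCConfig(**coc_doc)
        groups = tuple(GroupSpec(**g) for g in (doc.get("groups") or []))
        chroms = doc.get("chromosomes")
        return cls(
            simulation=sim,
            caller=caller,
            coc=coc,
            groups=groups,
            chromosomes=tuple(chroms) if chroms else None,
            outdir=str(doc.get("outdir", "xomap_run")),
        )

    def to_yaml(self, path: str) -> None:
        sim = dataclasses.asdict(self.simulation)
        sim.pop("rate_map", None)
        genome = sim.pop("genome")
        sim["genome"] = {
            "chromosomes": dict(self.simulation.genome.chromosomes),
            "centromeres": {k: list(v) for k, v in self.simulation.genome.centromeres.items()},
        }
        doc = {
            "xomap_version": __version__,
            "simulation": sim,
            "caller": dataclasses.asdict(self.caller),
            "coc": {
                "interval_size": self.coc.interval_size,
                "chromosomes": list(self.coc.chromosomes) if self.coc.chromosomes else None,
                "distance_bins": list(self.coc.distance_bins) if self.coc.distance_bins else None,
            },
            "groups": [dataclasses.asdict(g) for g in self.groups],
            "chromosomes": list(self.chromosomes) if self.chromosomes else None,
            "outdir": self.outdir,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _concat_tables(tables: Iterable[COTable]) -> COTable:
    tables = list(tables)
    events = pd.concat([t.events for t in tables], ignore_index=True)
    individuals = pd.concat([t.individuals for t in tables], ignore_index=True)
    return COTable(events, individuals)


def _statistics_report(
    table: COTable, genome: GenomeMap, coc_config: CoCConfig,
    chromosomes: tuple[str, ...] | None,
) -> dict:
    """The shared statistics branch of run_experiment and reanalyze_co_table."""
    counts = per_gamete_counts(table, chromosomes)
    distances = inter_co_distances(
        table if chromosomes is None else table.restrict_chromosomes(chromosomes)
    )
    inc = assign_intervals(table, genome, coc_config)
    curve = coc_curve(coc_pairwise(inc))
    by_group = {}
    for (group, sex), sub in distances.groupby(["group", "sex"]):
        by_group[f"{group}/{sex}"] = {
            "n_double_co": int(len(sub)),
            "mean_distance": float(sub["distance"].mean()),
        }
    return {
        "counts": counts.summary.to_dict(orient="records"),
        "total_cos": int(len(table)),
        "double_co": by_group,
        "coc_curve": curve.to_dict(orient="records"),
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Simulate, call, and analyse a full BC1 experiment; write all outputs.

    Returns the machine-readable report (also written as report.json).
    Deterministic given the configuration, including its seed.
    """
    os.makedirs(config.outdir, exist_ok=True)
    config.to_yaml(os.path.join(config.outdir, "config.yaml"))
    genome = config.simulation.genome
    groups = config.groups or (
        GroupSpec(config.simulation.group, config.simulation.sex,
                  config.simulation.n_individuals),
    )
    called_tables = []
    truth_tables = []
    for gi, spec in enumerate(groups):
        sim = replace(
            config.simulation,
            group=spec.group,
            sex=spec.sex,
            n_individuals=spec.n_individuals,
            lambda_c=spec.lambda_c if spec.lambda_c is not None else config.simulation.lambda_c,
            nu=spec.nu if spec.nu is not None else config.simulation.nu,
            seed=(config.simulation.seed + 7919 * gi) % (2**31),
        )
        log.info("simulating group %s/%s (n=%d)", spec.group, spec.sex, sim.n_individuals)
        matrix, truth, _ = simulate_population(sim)
        prefix = os.path.join(config.outdir, f"{spec.group}_{spec.sex}")
        write_genotype_table(matrix, prefix + "_genotypes.tsv")
        write_markers_tsv(matrix.markers, prefix + "_markers.tsv")
        called = call_population(matrix, matrix.markers, genome, config.caller)
        log.info(
            "group %s/%s: %d true COs, %d called", spec.group, spec.sex,
            len(truth), len(called),
        )
        called_tables.append(called)
        truth_tables.append(truth)
    called_all = _concat_tables(called_tables)
    truth_all = _concat_tables(truth_tables)
    write_co_table(
        called_all,
        os.path.join(config.outdir, "co_table.tsv"),
        os.path.join(config.outdir, "individuals.tsv"),
    )
    write_co_table(truth_all, os.path.join(config.outdir, "truth_co.tsv"))
    write_genome_yaml(genome, os.path.join(config.outdir, "genome.yaml"))

    land = landscape(called_all, genome)
    land_frames = []
    for chrom, frame in land.chromosomes.items():
        frame = frame.copy()
        frame.insert(0, "chromosome", chrom)
        land_frames.append(frame)
    pd.concat(land_frames, ignore_index=True).to_csv(
        os.path.join(config.outdir, "landscape.tsv"), sep="\t", index=False
    )

    report = {
        "xomap_version": __version__,
        "seed": config.simulation.seed,
        "called": _statistics_report(called_all, genome, config.coc, config.chromosomes),
        "truth": _statistics_report(truth_all, genome, config.coc, config.chromosomes),
        "recovery": recovery_metrics(
            called_all, truth_all, tolerance=config.caller.window_size
        ),
    }
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def reanalyze_co_table(
    co_table: str | COTable,
    genome: GenomeMap | str,
    coc_config: CoCConfig | None = None,
    chromosomes: Iterable[str] | None = None,
    individuals_path: str | None = None,
) -> dict:
    """Recompute counts, distances and CoC from an existing crossover table."""
    if isinstance(co_table, str):
        co_table = read_co_table(co_table, individuals_path)
    if isinstance(genome, str):
        genome = read_genome_yaml(genome)
    unknown = set(co_table.events["chromosome"]) - set(genome.chromosomes)
    if unknown:
        raise ValidationError(f"CO table references unknown chromosomes {sorted(unknown)}")
    return _statistics_report(
        co_table, genome, coc_config or CoCConfig(),
        tuple(chromosomes) if chromosomes else None,
    )
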