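"""End-to-end orchestration: detect → composition → spacing → classify → report.

A run takes one :class:`AnalysisConfig` and a set of organoid tables (read
from CSV or generated synthetically), executes every stage per organoid,
pools the spacing statistics across organoids and assembles one deterministic
JSON report. Any stage failure aborts the run with the failing stage named;
reports are byte-identical for identical config + seed.
"""

from __future__ import annotations

import math
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .architecture import ArchitectureCall, classify_architecture
from .clusters import Cluster, detect_clusters, size_distribution
from .composition import rgc_adjacency, summarize_compositions
from .config import AnalysisConfig
from .errors import PipelineStageError
from .io import OrganoidTable, write_report
from .spacing import (
    DistanceSet,
    count_modes,
    kde,
    neighbor_filter,
    pairwise_distances,
    partition_substacks,
    pooled_spacing_summary,
)
from .synthetic import GeneratorParams, GroundTruth, generate_cohort


@dataclass
class OrganoidResult:
    """All per-organoid intermediate products of one pipeline run."""

    table: OrganoidTable
    clusters: list[Cluster]
    distance_sets: list[DistanceSet]
    rgc_adjacent_fraction: float
    call: ArchitectureCall


@dataclass
class RunManifest:
    """Reproducibility record of a run (config echo, seed, stages, versions)."""

    config: dict
    seed: int
    inputs: list[str]
    stages: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    version: str = __version__
    python: str = platform.python_version()
    started: str = ""
    finished: str = ""

    def as_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "inputs": self.inputs,
            "stages": self.stages,
            "outputs": self.outputs,
            "version": self.version,
            "python": self.python,
            "started": self.started,
            "finished": self.finished,
        }


def _stage(manifest: RunManifest, name: str):
    manifest.stages.append(name)


def analyze_organoid(table: OrganoidTable, cfg: AnalysisConfig) -> OrganoidResult:
    """Run all analysis stages on a single organoid table."""
    try:
        clusters = detect_clusters(table, cfg.linkage_radius_um)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("detect", str(exc)) from exc

    try:
        substacks = partition_substacks(clusters, cfg)
        by_id = {c.cluster_id: c for c in clusters}
        distance_sets = []
        for ss in substacks:
            centroids = np.array([by_id[i].centroid for i in ss.cluster_ids])
            ds = pairwise_distances(centroids, substack=ss)
            distance_sets.append(neighbor_filter(ds))
    except Exception as exc:
        raise PipelineStageError("spacing", str(exc)) from exc

    try:
        adj_fraction, _ = rgc_adjacency(clusters, table, cfg.adjacency_radius_um)
    except Exception as exc:
        raise PipelineStageError("composition", str(exc)) from exc

    try:
        call = classify_architecture(table, cfg)
    except Exception as exc:
        raise PipelineStageError("classify", str(exc)) from exc

    return OrganoidResult(
        table=table,
        clusters=clusters,
        distance_sets=distance_sets,
        rgc_adjacent_fraction=adj_fraction,
        call=call,
    )


def build_report(
    results: Sequence[OrganoidResult], cfg: AnalysisConfig
) -> dict:
    """Aggregate per-organoid results into the report document."""
    all_clusters = [c for r in results for c in r.clusters]
    all_sets = [ds for r in results for ds in r.distance_sets]
    tables = [r.table for r in results]

    sizes = size_distribution(all_clusters)
    try:
        composition = summarize_compositions(all_clusters, tables)
    except Exception as exc:
        raise PipelineStageError("composition", str(exc)) from exc
    spacing = pooled_spacing_summary(all_sets)

    kde_section: dict = {"n_modes": 0, "bandwidth_um": None}
    pooled = np.concatenate(
        [ds.filtered for ds in all_sets if ds.filtered is not None and len(ds.filtered)]
    ) if any(ds.filtered is not None and len(ds.filtered) for ds in all_sets) else np.empty(0)
    if len(pooled) >= 2 and float(np.std(pooled)) > 0:
        de = kde(pooled, bandwidth=cfg.kde_bandwidth)
        kde_section = {
            "n_modes": count_modes(de, cfg.mode_prominence),
            "bandwidth_um": de.bandwidth,
        }

    per_organoid = {}
    for r in results:
        per_organoid[r.table.organoid_id] = {
            "n_cells": r.table.n_cells,
            "n_clusters": len(r.clusters),
            "n_substacks": len({ds.substack for ds in r.distance_sets if ds.substack}),
            "rgc_adjacent_fraction": r.rgc_adjacent_fraction,
            "architecture": r.call.as_dict(),
        }

    labels = [r.call.label for r in results]
    return {
        "config": cfg.model_dump(),
        "rng_seed": cfg.rng_seed,
        "n_organoids": len(results),
        "clusters": {
            "n_clusters": sizes.n,
            "size_distribution": sizes.as_dict(),
        },
        "composition": composition.as_dict(),
        "spacing": {
            **spacing.as_dict(),
            "kde": kde_section,
            "substack_bounds": [
                {
                    "organoid_id": ds.substack.organoid_id if ds.substack else None,
                    "z_lo": ds.substack.z_lo if ds.substack else None,
                    "z_hi": ds.substack.z_hi if ds.substack else None,
                    "n_clusters": ds.n_clusters,
                    "lo": None if math.isnan(ds.lo) else ds.lo,
                    "hi": None if math.isnan(ds.hi) else ds.hi,
                    "n_filtered": 0 if ds.filtered is None else int(len(ds.filtered)),
                }
                for ds in all_sets
            ],
        },
        "architecture": {
            "labels": {r.table.organoid_id: r.call.label for r in results},
            "counts": {
                label: labels.count(label)
                for label in ("laminated", "clustered", "indeterminate")
            },
        },
        "per_organoid": per_organoid,
    }


def run_pipeline(
    cfg: AnalysisConfig,
    tables: Sequence[OrganoidTable] | None = None,
    generator: GeneratorParams | None = None,
    n_organoids: int = 1,
    out: str | Path | None = None,
) -> tuple[dict, RunManifest]:
    """Execute the full pipeline on given tables or a simulated cohort.

    Exactly one of ``tables`` / ``generator`` must be provided. Returns the
    report dict and the run manifest; if ``out`` is given the report is also
    written there as JSON.
    """
    if (tables is None) == (generator is None):
        raise ValueError("provide exactly one of tables or generator")
    manifest = RunManifest(
        config=cfg.model_dump(),
        seed=cfg.rng_seed,
        inputs=[],
        started=datetime.now(timezone.utc).isoformat(),
    )
    truths: list[GroundTruth] = []
    if generator is not None:
        _stage(manifest, "simulate")
        params = generator.model_copy(update={"seed": cfg.rng_seed})
        pairs = generate_cohort(params, n_organoids)
        tables = [t for t, _ in pairs]
        truths = [g for _, g in pairs]
        manifest.inputs = [f"generator:{params.mode}:n={n_organoids}"]
    else:
        manifest.inputs = [t.organoid_id for t in tables]

    results = []
    for table in tables:
        results.append(analyze_organoid(table, cfg))
    for name in ("detect", "composition", "spacing", "classify"):
        _stage(manifest, name)

    report = build_report(results, cfg)
    _stage(manifest, "report")
    manifest.finished = datetime.now(timezone.utc).isoformat()
    if out is not None:
        write_report(report, out)
        manifest.outputs["report"] = str(out)
    # expose intermediates for callers that need them (tests, acceptance)
    report["_results"] = results
    report["_truths"] = truths
    return report, manifest


def report_for_output(report: dict) -> dict:
    """Strip in-memory intermediates, returning only the JSON document."""
    return {k: v for k, v in report.items() if not k.startswith("_")}
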