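"""End-to-end orchestration: simulate -> classify -> cluster -> profile ->
express -> enrich -> coordinate, with a manifest of checksummed outputs and a
JSON report of the headline tables."""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coordination, enrichment, expression, io, lineage, maxgap, segmentation
from .simulate import (
    ExpressionSimConfig,
    GenomeSimConfig,
    simulate_counts,
    simulate_genome,
    simulate_hits,
)

log = logging.getLogger("genecluster")

DEFAULT_OUTGROUPS = ("Podospora_anserina", "Chaetomium_globosum", "S_cerevisiae")


@dataclass
class RunConfig:
    genome: GenomeSimConfig = field(default_factory=GenomeSimConfig)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    max_gaps: list[int] = field(default_factory=lambda: [5, 1, 0])
    n_perm: int = 1999
    criterion: str = "BIC"
    max_segments: int = 20
    fold: float = 5.0
    alpha: float = 0.05
    cluster_alpha: float = 0.01
    coordination_r: float = 0.5
    detect_threshold: float = 1.0
    seed: int = 42
    outdir: str = "genecluster_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        genome = GenomeSimConfig(**raw.pop("genome", {}))
        expr_raw = raw.pop("expression", {})
        if "fold_change_range" in expr_raw:
            expr_raw["fold_change_range"] = tuple(expr_raw["fold_change_range"])
        expr = ExpressionSimConfig(**expr_raw)
        return cls(genome=genome, expression=expr, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the run report.

    Writes all stage outputs under ``config.outdir`` along with
    ``manifest.json`` (sha256 per file) and ``report.json``.  A stage failure
    aborts with the stage name; files written so far stay on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    report: dict = {"seed": config.seed, "stages": {}}
    t_start = time.time()

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest[name] = _sha256(path)

    def stage(name: str):
        log.info("stage %s starting", name)
        report["stages"][name] = {"t": round(time.time() - t_start, 2)}
        return name

    current = "simulate_genome"
    try:
        stage(current)
        config.genome.seed = config.seed
        layouts, truth = simulate_genome(config.genome)
        emit("genes.gff3", lambda p: io.write_gff3(layouts, p))
        emit("labels.tsv", lambda p: io.write_labels(layouts, p))
        emit("truth.json", lambda p: io.write_json(truth, p))

        current = "simulate_hits"
        stage(current)
        hits = simulate_hits(layouts, DEFAULT_OUTGROUPS, seed=config.seed + 1)
        emit("hits.tsv", lambda p: io.write_tsv(hits, p))

        current = "classify"
        stage(current)
        assignments = lineage.classify_lineage(hits)
        emit("assignments.tsv", lambda p: io.write_tsv(lineage.assignments_to_frame(assignments), p))
        census = lineage.stratum_census(assignments)
        emit("census.json", lambda p: io.write_json(census, p))

        current = "cluster"
        stage(current)
        n_focal = sum(
            1 for lay in layouts for g in lay.genes if g.label in ("LSG", "HET_LSG")
        )
        clusters_by_gap: dict[int, list[maxgap.GeneCluster]] = {}
        for g in config.max_gaps:
            clusters = maxgap.assign_cluster_pvalues(
                layouts, g, n_perm=config.n_perm, seed=config.seed + 10 + g
            )
            clusters_by_gap[g] = clusters
            emit(
                f"clusters_mg{g}.bed",
                lambda p, c=clusters: io.write_bed(io.clusters_to_bed(c, layouts), p),
            )
            summary = maxgap.summarize_clusters(clusters, n_focal)
            emit(f"cluster_summary_mg{g}.tsv", lambda p, s=summary: io.write_tsv(s, p))
        report["cluster_summary"] = {
            g: maxgap.summarize_clusters(cl, n_focal).to_dict("records")
            for g, cl in clusters_by_gap.items()
        }

        current = "profile"
        stage(current)
        profile_frames = []
        for lay in layouts:
            prof = segmentation.dp_model_average(
                lay.label_vector(),
                criterion=config.criterion,
                max_segments=config.max_segments,
            )
            frame = segmentation.profile_to_frame(prof, lay.gene_ids)
            frame.insert(0, "chromosome", lay.chromosome)
            profile_frames.append(frame)
        emit(
            "profile.tsv",
            lambda p: io.write_tsv(pd.concat(profile_frames, ignore_index=True), p),
        )

        current = "express"
        stage(current)
        config.expression.seed = config.seed + 2
        primary_gap = config.max_gaps[0]
        coordinated_ids = [t["cluster_id"] for t in truth[: min(3, len(truth))]]
        config.expression.coordinated_cluster_ids = coordinated_ids
        counts, sheet, expr_truth = simulate_counts(layouts, config.expression, truth)
        emit("counts.tsv", lambda p: io.write_tsv(counts, p, index=True))
        emit("samples.tsv", lambda p: io.write_tsv(sheet, p))
        emit("expression_truth.json", lambda p: io.write_json(expr_truth, p))
        rel = expression.relative_expression(
            counts, sheet, detect_threshold=config.detect_threshold
        )
        emit("relative_expression.tsv", lambda p: io.write_tsv(rel.to_frame(), p))
        status = expression.status_across_stages(rel)
        emit("status.tsv", lambda p: io.write_tsv(status, p))
        dynamic = expression.call_dynamic(rel, fold=config.fold, alpha=config.alpha)
        emit("dynamic.tsv", lambda p: io.write_tsv(dynamic, p))
        report["n_dynamic"] = int(dynamic["dynamic"].sum())

        current = "enrich"
        stage(current)
        labels_df = io.read_tsv(outdir / "labels.tsv")
        if labels_df["class"].isin(["LSG", "HET_LSG"]).any():
            enr = enrichment.class_state_tables(labels_df, status)
            emit(
                "enrichment.tsv",
                lambda p: io.write_tsv(enrichment.results_to_frame(enr), p),
            )
            report["enrichment"] = enrichment.results_to_frame(enr).to_dict("records")
        else:
            report["enrichment"] = []

        current = "coordinate"
        stage(current)
        coord = coordination.screen_clusters(
            clusters_by_gap[primary_gap], rel, threshold=config.coordination_r
        )
        emit(
            "coordination.tsv",
            lambda p: io.write_tsv(coordination.results_to_frame(coord), p),
        )
        report["coordination"] = coordination.results_to_frame(coord).head(20).to_dict(
            "records"
        )
        report["n_coordinated"] = int(sum(r.coordinated for r in coord))
    except Exception as exc:
        io.write_json({"failed_stage": current, "manifest": manifest}, outdir / "manifest.json")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    report["manifest"] = manifest
    report["wall_time_s"] = round(time.time() - t_start, 2)
    io.write_json(manifest, outdir / "manifest.json")
    io.write_json(report, outdir / "report.json")
    return report
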