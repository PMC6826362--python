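"""End-to-end orchestration: simulate or ingest, filter, test, classify,
enrich, and report — driven by one YAML configuration.

The pipeline is a single in-process run at desk scale; stages can be toggled
individually, later stages consume the outputs of earlier ones, and a fixed
seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .data import (
    CROSS_GROUPS,
    CountMatrix,
    SampleSheet,
    ValidationError,
    read_count_matrix,
    read_gmt,
    read_phenotypes,
    read_sample_sheet,
    write_count_matrix,
    write_phenotypes,
    write_sample_sheet,
)
from .de import compute_fpkm, filter_low_expression, run_contrasts
from .enrichment import hypergeom_ora, significant_sets
from .heterosis import heterosis_report
from .modes import (
    calls_to_frame,
    classify_all,
    shared_category_genes,
    summarize_calls,
)
from .simulate import SimulationConfig, generate_counts, generate_phenotypes, write_truth_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    outdir: str = "hetexpress_run"
    seed: int = 0
    alpha: float = 0.05
    fpkm_threshold: float = 1.0
    enrichment_fdr: float = 0.05
    t_variant: str = "delta"
    sex: str = "F"
    group_map: dict[str, str] = field(default_factory=dict)
    # stage toggles
    simulate: bool = True
    heterosis: bool = True
    de: bool = True
    classify: bool = True
    enrich: bool = False
    # input paths (used when simulate is False, or for the GMT)
    counts_path: str | None = None
    lengths_path: str | None = None
    samples_path: str | None = None
    phenotypes_path: str | None = None
    gmt_path: str | None = None
    enrich_category: str = "over"
    # simulation parameters forwarded to SimulationConfig
    simulation: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Machine-readable record of what each stage saw and produced."""

    config: dict[str, Any]
    version: str = __version__
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, **info: Any) -> None:
        self.stages[stage] = info

    def to_json(self) -> str:
        return json.dumps({"version": self.version, "config": self.config,
                           "stages": self.stages}, indent=2, default=str)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order and write all outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())

    counts: CountMatrix | None = None
    samples: SampleSheet | None = None
    phenotypes = None

    def timed(stage):
        start = time.perf_counter()
        return lambda **info: report.record(
            stage, wall_seconds=round(time.perf_counter() - start, 3), **info
        )

    if config.simulate:
        done = timed("simulate")
        sim = SimulationConfig(seed=config.seed, **config.simulation)
        counts, samples, truth = generate_counts(sim)
        phenotypes = generate_phenotypes(sim)
        write_count_matrix(counts, outdir / "counts.tsv", outdir / "lengths.tsv")
        write_sample_sheet(samples, outdir / "samples.tsv")
        write_phenotypes(phenotypes, outdir / "phenotypes.tsv")
        write_truth_table(truth, outdir / "truth.tsv")
        done(n_genes=len(counts.gene_ids), n_samples=len(counts.sample_ids),
             modes=truth["mode"].value_counts().to_dict())
        logger.info("simulate: %d genes x %d samples", len(counts.gene_ids),
                    len(counts.sample_ids))
    else:
        if config.de or config.classify or config.enrich:
            if not (config.counts_path and config.lengths_path and config.samples_path):
                raise ValidationError(
                    "simulate=false: counts_path, lengths_path and samples_path required"
                )
            counts = read_count_matrix(config.counts_path, config.lengths_path)
            samples = read_sample_sheet(config.samples_path, config.group_map)
        if config.heterosis:
            if not config.phenotypes_path:
                raise ValidationError("simulate=false: phenotypes_path required for heterosis")
            phenotypes = read_phenotypes(config.phenotypes_path, config.group_map)

    if config.heterosis:
        done = timed("heterosis")
        results = heterosis_report(phenotypes, sex=config.sex, t_variant=config.t_variant)
        frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
        frame.insert(1, "sex", config.sex)
        frame.to_csv(outdir / "heterosis.tsv", sep="\t", index=False)
        done(results={r.cross: {"heterosis_pct": r.heterosis_pct, "p_value": r.p_value}
                      for r in results})
        logger.info("heterosis: %s", {r.cross: round(r.heterosis_pct, 2) for r in results})

    contrasts = None
    retained: list[str] = []
    if config.de:
        done = timed("de")
        samples.validate_against(counts)
        fpkm = compute_fpkm(counts)
        retained = filter_low_expression(fpkm, config.fpkm_threshold)
        filtered = counts.subset_genes(retained)
        contrasts = run_contrasts(filtered, samples)
        de_dir = outdir / "de"
        de_dir.mkdir(exist_ok=True)
        deg_counts = {}
        for name, res in contrasts.items():
            res.table.rename_axis("gene_id").to_csv(de_dir / f"{name}.tsv", sep="\t")
            deg_counts[name] = int((res.table["padj"] < config.alpha).sum())
        n_in = len(counts.gene_ids)
        assert n_in - len(retained) + len(retained) == n_in  # report consistency
        done(genes_in=n_in, genes_filtered=n_in - len(retained),
             genes_retained=len(retained), degs_per_contrast=deg_counts)
        logger.info("de: %d/%d genes retained; DEGs %s", len(retained), n_in, deg_counts)

    calls_by_cross: dict[str, list] = {}
    if config.classify:
        if contrasts is None:
            raise ValidationError("classify stage requires the de stage")
        done = timed("classify")
        summaries = {}
        for cross in CROSS_GROUPS:
            calls = classify_all(contrasts, cross=cross, alpha=config.alpha)
            calls_by_cross[cross] = calls
            calls_to_frame(calls).to_csv(outdir / f"modes_{cross}.tsv", sep="\t", index=False)
            summary = summarize_calls(calls, cross)
            summaries[cross] = {
                "counts": summary.counts,
                "proportions": summary.proportions,
            }
        shared_over = shared_category_genes(
            calls_by_cross["F1A"], calls_by_cross["F1B"], "over"
        )
        (outdir / "shared_over.txt").write_text("\n".join(sorted(shared_over)) + "\n")
        done(category_summaries=summaries, shared_over=sorted(shared_over))
        logger.info("classify: shared over-dominant genes: %d", len(shared_over))

    if config.enrich:
        if not config.gmt_path:
            raise ValidationError("enrich stage requires gmt_path")
        if not calls_by_cross:
            raise ValidationError("enrich stage requires the classify stage")
        done = timed("enrich")
        collection = read_gmt(config.gmt_path)
        universe = set(retained)
        enrich_out = {}
        for cross, calls in calls_by_cross.items():
            study = {c.gene_id for c in calls if c.category == config.enrich_category}
            if not study:
                enrich_out[cross] = []
                continue
            results = hypergeom_ora(study, universe, collection)
            frame = pd.DataFrame(
                [
                    {
                        "set_name": r.set_name, "k": r.k, "K": r.K, "n_study": r.n_study,
                        "N": r.N, "p_value": r.p_value, "fdr": r.fdr,
                    }
                    for r in results
                ]
            )
            frame.to_csv(outdir / f"enrichment_{cross}.tsv", sep="\t", index=False)
            enrich_out[cross] = significant_sets(results, config.enrichment_fdr)
        done(significant_sets=enrich_out)
        logger.info("enrich: %s", enrich_out)

    (outdir / "report.json").write_text(report.to_json() + "\n")
    (outdir / "report.txt").write_text(_human_report(report))
    return report


def _human_report(report: RunReport) -> str:
    lines = [f"hetexpress {report.version} run report", "=" * 48]
    for stage, info in report.stages.items():
        lines.append(f"[{stage}] ({info.get('wall_seconds', '?')} s)")
        for key, value in info.items():
            if key == "wall_seconds":
                continue
            lines.append(f"  {key}: {value}")
    lines.append("=" * 48)
    return "\n".join(lines) + "\n"
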