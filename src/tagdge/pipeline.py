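"""End-to-end pipeline orchestration with a reproducible run manifest.

``run_pipeline`` executes: (optional) simulate -> build reference -> clean
-> quantify -> Venn accounting -> DEG screen -> category aggregation, and
writes every table plus a JSON manifest (package version, seed, thresholds,
per-stage tallies) sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .categories import DEFAULT_MIN_TOTAL, CategoryMap, aggregate, filter_categories
from .cleaning import DEFAULT_QUALITY_THRESHOLD, clean_reads, TagCountTable
from .degs import DEFAULT_FDR, DEFAULT_MIN_LOG2FC
from .errors import ConfigError, InputError
from .model import DGEModel
from .quantify import map_tags, merge_profiles
from .reads import RawTagReads
from .reference import GeneCatalog, TagIndex
from .stagesets import percentages

logger = logging.getLogger("tagdge")


@dataclass
class RunConfig:
    """Paths, thresholds and seed for one pipeline run."""

    catalog_path: str
    reads_paths: Mapping[str, str]  # stage -> FASTQ or tag-count TSV
    output_dir: str
    category_map_path: str | None = None
    min_count: int = 1
    fdr: float = DEFAULT_FDR
    min_log2fc: float = DEFAULT_MIN_LOG2FC
    quality_threshold: int = DEFAULT_QUALITY_THRESHOLD
    remove_singletons: bool = True
    min_category_total: int = DEFAULT_MIN_TOTAL
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.fdr <= 1:
            raise ConfigError(f"fdr must lie in (0, 1], got {self.fdr}")
        if self.min_log2fc < 0:
            raise ConfigError("min_log2fc must be non-negative")
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")
        if self.quality_threshold < 0:
            raise ConfigError("quality_threshold must be non-negative")
        if len(self.reads_paths) != 4:
            raise ConfigError("exactly 4 stage read files required")
        if not Path(self.catalog_path).exists():
            raise InputError(f"catalog not found: {self.catalog_path}")
        for stage, path in self.reads_paths.items():
            if not Path(path).exists():
                raise InputError(f"{stage}: reads not found: {path}")


def _load_table(stage: str, path: str, config: RunConfig) -> tuple[TagCountTable, dict]:
    """Load one stage library from FASTQ or pre-tabulated tag counts."""
    if path.endswith((".fastq", ".fq")):
        reads = RawTagReads.from_fastq(path, library_id=stage)
        table, stats = clean_reads(
            reads,
            quality_threshold=config.quality_threshold,
            remove_singletons=config.remove_singletons,
        )
        return table, stats.as_dict()
    table = TagCountTable.from_tsv(path, library_id=stage)
    return table, {"n_clean": table.total_clean, "pretabulated": True}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tagdge_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_count": config.min_count,
            "fdr": config.fdr,
            "min_log2fc": config.min_log2fc,
            "quality_threshold": config.quality_threshold,
            "remove_singletons": config.remove_singletons,
        },
        "inputs": {
            "catalog": str(config.catalog_path),
            "reads": dict(config.reads_paths),
            "category_map": config.category_map_path,
        },
        "stages": {},
    }

    stage = "build-ref"
    try:
        logger.info("building tag reference from %s", config.catalog_path)
        catalog = GeneCatalog.from_fasta(config.catalog_path)
        index = TagIndex.build(catalog)
        index.to_tsv(out / "tag_index.tsv")
        manifest["reference"] = vars(index.stats)

        stages = list(config.reads_paths)
        profiles = []
        for stage_label in stages:
            stage = f"clean+quantify:{stage_label}"
            table, clean_stats = _load_table(
                stage_label, str(config.reads_paths[stage_label]), config
            )
            table.to_tsv(out / f"clean_tags_{stage_label}.tsv")
            profile = map_tags(table, index, gene_universe=index.gene_ids)
            profile.to_tsv(out / f"expression_{stage_label}.tsv")
            profiles.append(profile)
            manifest["stages"][stage_label] = {
                "cleaning": clean_stats,
                "mapping": profile.tallies.as_dict(),
                "total_clean": profile.total_clean,
                "genes_detected": int((profile.counts >= config.min_count).sum()),
            }

        stage = "model"
        merged = merge_profiles(profiles)
        merged.to_csv(out / "expression_matrix.tsv", sep="\t")
        model = DGEModel.from_profiles(profiles, genome_size=len(catalog))
        results = model.fit(
            fdr=config.fdr, min_log2fc=config.min_log2fc, min_count=config.min_count
        )

        stage = "venn"
        venn_df = percentages(results.venn())
        venn_df.to_csv(out / "venn_partition.tsv", sep="\t", index=False)

        stage = "deg"
        deg_summaries = {}
        cat_tables = []
        cmap = (
            CategoryMap.from_tsv(config.category_map_path)
            if config.category_map_path
            else None
        )
        for label, s1, s2 in model.transitions:
            results.tests[label].to_csv(out / f"deg_tests_{label}.tsv", sep="\t")
            results.degs(label).to_csv(out / f"degs_{label}.tsv", sep="\t")
            ts = results.transition_summary(label)
            deg_summaries[label] = {
                "earlier": s1,
                "later": s2,
                "n_total": ts.n_total,
                "n_up": ts.n_up,
                "n_down": ts.n_down,
                "n_on": ts.n_on,
                "n_off": ts.n_off,
                "pct_up": ts.pct_up,
            }
            if cmap is not None:
                cat_tables.append(aggregate(results.degs(label), cmap))
        if cmap is not None:
            stage = "categories"
            for (label, _s1, _s2), table_ in zip(
                model.transitions, filter_categories(cat_tables, config.min_category_total)
            ):
                table_.to_csv(out / f"categories_{label}.tsv", sep="\t")
        manifest["deg_summaries"] = deg_summaries

        stage = "report"
        (out / "summary.txt").write_text(results.summary() + "\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest
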