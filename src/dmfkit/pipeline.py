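"""End-to-end pipeline: digestion -> aggregation -> testing -> comparison.

``run_pipeline`` realises the standard fragment-level analysis flow on any
combination of inputs (real coverage files or a seeded simulation): in-silico
digestion and size selection, per-sample aggregation, the complete-coverage
filter, the all-groups ANOVA layer, pairwise DMF calling, annotation, and
the two-contrast comparison (common fragments, divergent subset,
concordance).  Every stage's input/output counts are logged and written to a
JSON manifest whose fragment counts shrink monotonically along the chain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import comparative, stats
from .annotation import annotate_catalog, load_gene_models
from .coverage import (
    SampleSheet,
    build_matrix,
    filter_complete,
    global_summaries,
    read_bismark_coverage,
)
from .digest import Genome, digest, size_select
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and contrasts for one pipeline run."""

    outdir: Path
    genome_fasta: Path | None = None
    gene_models: Path | None = None
    coverage_dir: Path | None = None
    sample_sheet: Path | None = None
    simulate: SimulationConfig | None = None
    min_len: int = 40
    max_len: int = 220
    min_total_reads: int = 10
    min_cpgs: int = 2
    p_thresh: float = 0.05
    min_diff: float = 10.0
    min_cross_diff: float = 10.0
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("LC", "HC"), ("ME", "HC")]
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for t in (self.p_thresh, self.min_diff, self.min_cross_diff):
            if t <= 0:
                raise ValueError("thresholds must be positive")
        if self.simulate is None and (
            self.genome_fasta is None
            or self.coverage_dir is None
            or self.sample_sheet is None
        ):
            raise ValueError(
                "either a simulation config or genome/coverage/sample-sheet "
                "paths are required"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    if config.simulate is not None:
        sim = simulate_dataset(config.simulate)
        simdir = out / "simdata"
        sim.write(simdir)
        genome, models = sim.genome, sim.models
        sheet = sim.sheet
        calls = sim.calls_by_sample
        manifest["simulated"] = True
    else:
        genome = Genome.from_fasta(config.genome_fasta)
        models = (
            load_gene_models(config.gene_models) if config.gene_models else []
        )
        sheet = SampleSheet.from_csv(config.sample_sheet)
        calls = {}
        for sample in sheet.samples:
            path = Path(config.coverage_dir) / f"{sample}.cov"
            if not path.exists():
                raise FileNotFoundError(f"stage aggregate: no coverage for {sample}: {path}")
            calls[sample] = read_bismark_coverage(path)
        manifest["simulated"] = False

    # -- digestion ---------------------------------------------------------
    catalog_all = digest(genome)
    catalog = size_select(catalog_all, config.min_len, config.max_len)
    catalog.to_bed(out / "fragments.bed")
    manifest["stages"]["digest"] = {
        "fragments_digested": len(catalog_all),
        "fragments_in_size": len(catalog),
    }
    logger.info("digest: %d fragments, %d in size window", len(catalog_all), len(catalog))

    annotations = annotate_catalog(catalog, models) if models else None
    if annotations is not None:
        annotations.to_csv(out / "annotations.tsv", sep="\t")

    # -- aggregation + complete-coverage filter ----------------------------
    matrix = build_matrix(
        calls, catalog, sheet, config.min_total_reads, config.min_cpgs
    )
    matrix.write(out / "matrix.tsv")
    complete = filter_complete(matrix)
    complete.write(out / "matrix_complete.tsv")
    manifest["stages"]["aggregate"] = {
        "fragments_with_any_data": int(matrix.percent.notna().any(axis=1).sum()),
        "fragments_complete": len(complete),
    }
    summaries = global_summaries(complete, annotations)
    summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)

    # -- all-groups ANOVA layer -------------------------------------------
    anova = stats.test_all_fragments(complete)
    anova.to_csv(out / "anova_all_groups.tsv", sep="\t")
    n_signif = int((anova["p"] < config.p_thresh).sum())
    manifest["stages"]["anova"] = {"fragments_significant": n_signif}

    # -- pairwise DMF calling ---------------------------------------------
    dmf_tables: dict[str, pd.DataFrame] = {}
    manifest["stages"]["dmf"] = {}
    for case, ref in config.contrasts:
        table = stats.call_dmfs(
            complete, case, ref, config.p_thresh, config.min_diff
        )
        if annotations is not None:
            table = table.join(annotations, how="left")
        table.to_csv(out / f"dmf_{case}_vs_{ref}.tsv", sep="\t")
        dmf_tables[case] = table
        manifest["stages"]["dmf"][f"{case}_vs_{ref}"] = int(table["passes"].sum())

    # -- two-contrast comparison ------------------------------------------
    if len(config.contrasts) >= 2:
        case_a, case_b = config.contrasts[0][0], config.contrasts[1][0]
        common, venn = comparative.intersect_dmfs(
            dmf_tables[case_a], dmf_tables[case_b]
        )
        common.to_csv(out / "common_dmfs.tsv", sep="\t")
        divergent = comparative.select_divergent(common, config.min_cross_diff)
        divergent.to_csv(out / "divergent_dmfs.tsv", sep="\t")
        summary = comparative.concordance_summary(common)
        manifest["stages"]["compare"] = {
            "only_" + case_a: venn.only_a,
            "common": venn.common,
            "only_" + case_b: venn.only_b,
            "divergent": len(divergent),
            "both_hyper": summary.both_hyper,
            "both_hypo": summary.both_hypo,
            "opposite": summary.opposite,
        }

    chain = [
        manifest["stages"]["digest"]["fragments_in_size"],
        manifest["stages"]["aggregate"]["fragments_complete"],
        manifest["stages"]["anova"]["fragments_significant"],
    ]
    if "compare" in manifest["stages"]:
        chain += [
            manifest["stages"]["compare"]["common"],
            manifest["stages"]["compare"]["divergent"],
        ]
    manifest["count_chain"] = chain
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
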