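"""End-to-end orchestration: inputs -> fragments -> expression screen ->
joint-block search -> outputs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import dase, evaluation, io_formats, phasing
from .model import Fragment, Gene, PhasedBlock, SNPPanel

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration (mirrors the CLI flags)."""

    vcf: str = ""
    alignments: List[str] = field(default_factory=list)
    fragment_files: List[str] = field(default_factory=list)
    annotation: Optional[str] = None
    truth: Optional[str] = None
    out: Optional[str] = None
    phased_vcf_out: Optional[str] = None
    metrics_out: Optional[str] = None
    sample: Optional[str] = None
    dase_enabled: bool = True
    dase_config: dase.DaseConfig = field(default_factory=dase.DaseConfig)
    search_config: phasing.SearchConfig = field(default_factory=phasing.SearchConfig)
    extraction: io_formats.ExtractionOptions = field(
        default_factory=io_formats.ExtractionOptions
    )
    threads: int = 1
    seed: int = 42

    def validate(self) -> None:
        if not self.vcf:
            raise ValueError("a genotype VCF is required")
        if not self.alignments and not self.fragment_files:
            raise ValueError("at least one alignment or fragment file is required")
        if self.dase_enabled and not self.annotation:
            raise ValueError("expression-based phasing requires a gene annotation")


@dataclass
class RunResult:
    panel: SNPPanel
    genes: List[Gene]
    fragments: List[Fragment]
    analyses: Dict[str, dase.GeneAnalysis]
    blocks: List[PhasedBlock]
    metrics: Optional[evaluation.PhasingMetrics] = None


def run_phase(config: RunConfig) -> RunResult:
    """Execute the pipeline; deterministic given the seed and inputs."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    panel = io_formats.read_het_snps(config.vcf, sample=config.sample)
    log.info("panel: %d het SNPs (%d records skipped)", len(panel), panel.skipped)

    fragments: List[Fragment] = []
    for path in config.alignments:
        fragments.extend(
            io_formats.extract_fragments(path, panel, options=config.extraction)
        )
    for path in config.fragment_files:
        fragments.extend(io_formats.read_fragments(path))
    fragments = io_formats.merge_barcoded_fragments(fragments)
    log.info("fragments: %d after extraction and barcode merging", len(fragments))

    genes: List[Gene] = []
    if config.annotation:
        genes = io_formats.read_gene_model(config.annotation, panel)
        untagged = [f for f in fragments if f.gene_id is None]
        io_formats.assign_gene_ids(untagged, genes)
        log.info("genes: %d (%d with exonic het SNPs)",
                 len(genes), sum(1 for g in genes if not g.inert))

    analyses: Dict[str, dase.GeneAnalysis] = {}
    biases = dase.ReadBiasAssignment()
    if config.dase_enabled and genes:
        analyses = dase.analyze_genes(genes, fragments, config.dase_config, rng)
        biases = dase.assign_read_biases(
            fragments, analyses, p_uniform=config.dase_config.p_uniform
        )
        n_eligible = sum(1 for a in analyses.values() if a.estimate.eligible)
        log.info("expression screen: %d genes analyzed, %d eligible",
                 len(analyses), n_eligible)

    blocks = phasing.phase_all(
        panel, fragments, genes, analyses, biases, config.search_config
    )
    log.info("phased %d blocks covering %d SNPs",
             len(blocks), sum(b.size for b in blocks))

    if config.out:
        io_formats.write_blocks(blocks, panel, config.out)
    if config.phased_vcf_out:
        io_formats.write_phased_vcf(
            blocks, panel, config.vcf, config.phased_vcf_out, sample=config.sample
        )

    metrics = None
    if config.truth:
        if config.truth.endswith(".vcf") or config.truth.endswith(".vcf.gz"):
            truth = io_formats.read_truth_vcf(config.truth)
        else:
            truth = io_formats.read_truth_haplotypes(config.truth)
        metrics = evaluation.switch_error_rate(blocks, truth, panel)
        log.info("evaluation: %s", metrics.summary())
        if config.metrics_out:
            evaluation.metrics_table(metrics).to_csv(
                config.metrics_out, sep="\t", index=False
            )

    return RunResult(
        panel=panel,
        genes=genes,
        fragments=fragments,
        analyses=analyses,
        blocks=blocks,
        metrics=metrics,
    )
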