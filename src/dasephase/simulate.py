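"""Ground-truthed synthetic scenes for end-to-end testing.

The generator emulates the statistical structure the phasing model assumes:
biallelic heterozygous SNPs placed in exons of non-overlapping genes, a
uniformly drawn truth haplotype, per-gene differential haplotypic expression
(each read originates from the gene's higher-expressed haplotype with
probability beta), reads covering contiguous runs of a gene's SNPs (splicing
collapses introns, so transcript-contiguous SNP runs stand in for spliced
reads), and uniform per-base opposite-allele errors.  It does not attempt
isoform mixtures, GC or positional bias, or non-uniform error profiles.

Every scene is fully reproducible from its seed and can be written out as
VCF + GTF + fragment text + truth haplotypes (optionally SAM/BAM), all of
which round-trip through :mod:`dasephase.io_formats`.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import EPS_MIN, phred_to_error
from .model import Fragment, Gene, HetSNP, SNPPanel

_BASES = ("A", "C", "G", "T")


@dataclass
class SimulationConfig:
    """Scene parameters; every rate is a probability, lengths in bp.

    ``beta_values`` are cycled across genes (gene i gets
    beta_values[i % len]) so every stated expression-bias level is
    represented in every scene; each value is the probability that a read of
    the gene comes from its higher-expressed haplotype, with 0.5 the
    point mass of non-differentially-expressed genes.
    """

    n_genes: int = 20
    snps_per_gene: Tuple[int, int] = (4, 8)  # inclusive range
    exons_per_gene: Tuple[int, int] = (2, 4)
    exon_length: Tuple[int, int] = (200, 400)
    intron_length: Tuple[int, int] = (500, 2000)
    intergenic_gap: Tuple[int, int] = (5000, 10000)
    beta_values: Tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
    coverage: float = 100.0  # mean reads covering each SNP
    fragment_size_probs: Dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    base_error: float = 0.01
    barcode_rate: float = 0.0
    cross_gene_read_rate: float = 0.0  # expected cross-gene linking reads per gene
    chrom: str = "chr1"
    sample: str = "SAMPLE"
    seed: int = 42

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.snps_per_gene[0] < 1 or self.snps_per_gene[0] > self.snps_per_gene[1]:
            raise ValueError("invalid snps_per_gene range")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.base_error < 0.5:
            raise ValueError("base_error must lie in [0, 0.5)")
        if any(b < 0.5 or b > 1.0 for b in self.beta_values):
            raise ValueError("beta values must lie in [0.5, 1]")
        total = sum(self.fragment_size_probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("fragment size probabilities must sum to 1")
        if any(k < 1 for k in self.fragment_size_probs):
            raise ValueError("fragment sizes must be >= 1")


@dataclass
class GeneTruth:
    gene_id: str
    beta: float
    overexpressed_hap: int  # which truth haplotype (0/1) is higher-expressed
    n_reads: int
    snp_indices: List[int]


@dataclass
class TruthScene:
    config: SimulationConfig
    panel: SNPPanel
    genes: List[Gene]
    fragments: List[Fragment]
    truth: Dict[Tuple[str, int], int]  # (chrom, 1-based pos) -> h0 allele
    gene_truth: Dict[str, GeneTruth]
    files: Dict[str, str] = field(default_factory=dict)

    def truth_by_index(self) -> Dict[Tuple[str, int], int]:
        """(chrom, panel index) -> truth h0 allele."""
        out = {}
        for (chrom, pos), a in self.truth.items():
            idx = self.panel.index_of_position(chrom, pos)
            out[(chrom, idx)] = a
        return out


def simulate_scene(
    config: Optional[SimulationConfig] = None,
    out_dir: Optional[str] = None,
    write_sam: bool = False,
    write_bam: bool = False,
) -> TruthScene:
    """Draw a full ground-truthed scene; reproducible from ``config.seed``."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    chrom = config.chrom
    snps: List[HetSNP] = []
    genes: List[Gene] = []
    gene_truth: Dict[str, GeneTruth] = {}
    truth_alleles: List[int] = []

    cursor = 1000  # leading pad on the chromosome
    next_index = 0
    mean_size = sum(k * p for k, p in config.fragment_size_probs.items())
    sizes = np.array(sorted(config.fragment_size_probs))
    size_p = np.array([config.fragment_size_probs[int(k)] for k in sizes])

    fragments: List[Fragment] = []
    read_counter = 0

    for gi in range(config.n_genes):
        gene_id = f"G{gi:03d}"
        n_snps = int(rng.integers(config.snps_per_gene[0], config.snps_per_gene[1] + 1))
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))

        exons: List[Tuple[int, int]] = []
        pos0 = cursor
        for _ in range(n_exons):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((pos0, pos0 + length))
            pos0 += length + int(
                rng.integers(config.intron_length[0], config.intron_length[1] + 1)
            )
        cursor = pos0 + int(
            rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1)
        )

        exonic = np.concatenate([np.arange(a, b) for a, b in exons])
        snp_pos0 = np.sort(rng.choice(exonic, size=n_snps, replace=False))
        indices = list(range(next_index, next_index + n_snps))
        for p0 in snp_pos0:
            ref, alt = rng.choice(len(_BASES), size=2, replace=False)
            snps.append(
                HetSNP(
                    chrom=chrom,
                    pos=int(p0) + 1,
                    ref_allele=_BASES[ref],
                    alt_allele=_BASES[alt],
                    index=next_index,
                )
            )
            truth_alleles.append(int(rng.integers(2)))
            next_index += 1

        beta = config.beta_values[gi % len(config.beta_values)]
        over_hap = int(rng.integers(2))
        n_reads = max(1, int(round(config.coverage * n_snps / mean_size)))

        for _ in range(n_reads):
            k = int(sizes[rng.choice(len(sizes), p=size_p)])
            k = min(k, n_snps)
            start = int(rng.integers(0, n_snps - k + 1))
            covered = indices[start : start + k]
            hap = over_hap if rng.random() < beta else 1 - over_hap
            alleles: Dict[int, int] = {}
            errors: Dict[int, float] = {}
            for s in covered:
                a = truth_alleles[s] if hap == 0 else 1 - truth_alleles[s]
                if config.base_error > 0 and rng.random() < config.base_error:
                    a = 1 - a  # opposite-allele error
                alleles[s] = a
                errors[s] = _quantized_eps(config.base_error)
            fragments.append(
                Fragment(
                    id=f"r{read_counter:06d}",
                    chrom=chrom,
                    alleles=alleles,
                    errors=errors,
                    gene_id=gene_id,
                )
            )
            read_counter += 1

        gene_truth[gene_id] = GeneTruth(
            gene_id=gene_id,
            beta=beta,
            overexpressed_hap=over_hap,
            n_reads=n_reads,
            snp_indices=indices,
        )
        genes.append(
            Gene(gene_id=gene_id, chrom=chrom, exons=exons, snp_indices=indices)
        )

    # optional cross-gene linking reads (no gene tag: independent biases)
    n_cross = int(round(config.cross_gene_read_rate * (config.n_genes - 1)))
    for ci in range(n_cross):
        gi = ci % (config.n_genes - 1)
        s1 = genes[gi].snp_indices[-1]
        s2 = genes[gi + 1].snp_indices[0]
        hap = int(rng.integers(2))
        alleles = {}
        errors = {}
        for s in (s1, s2):
            a = truth_alleles[s] if hap == 0 else 1 - truth_alleles[s]
            if config.base_error > 0 and rng.random() < config.base_error:
                a = 1 - a
            alleles[s] = a
            errors[s] = _quantized_eps(config.base_error)
        fragments.append(
            Fragment(f"x{ci:04d}", chrom, alleles, errors, gene_id=None)
        )

    # optional barcode grouping: tagged reads share barcodes within a gene
    if config.barcode_rate > 0:
        by_gene: Dict[Optional[str], List[Fragment]] = {}
        for f in fragments:
            by_gene.setdefault(f.gene_id, []).append(f)
        bc = 0
        for gid, frs in sorted(by_gene.items(), key=lambda kv: kv[0] or ""):
            if gid is None:
                continue
            pool = max(1, int(len(frs) * config.barcode_rate / 2))
            codes = [f"BC{bc + i:05d}" for i in range(pool)]
            bc += pool
            for f in frs:
                if rng.random() < config.barcode_rate:
                    f.barcode = codes[int(rng.integers(pool))]

    panel = SNPPanel(snps)
    truth = {
        (chrom, s.pos): truth_alleles[s.index] for s in panel.snps(chrom)
    }
    scene = TruthScene(
        config=config,
        panel=panel,
        genes=genes,
        fragments=fragments,
        truth=truth,
        gene_truth=gene_truth,
    )
    if out_dir is not None:
        write_scene(scene, out_dir, write_sam=write_sam, write_bam=write_bam)
    return scene


def _quantized_eps(eps: float) -> float:
    """Round-trip epsilon through the Phred scale so SAM output reproduces
    the fragment list exactly (Q = 60 stands in for error-free bases)."""
    q = 60 if eps <= 0 else round(-10.0 * math.log10(eps))
    return phred_to_error(q)


def _phred_char(eps: float) -> str:
    q = min(60, max(2, round(-10.0 * math.log10(max(eps, EPS_MIN)))))
    return chr(q + 33)


# ---------------------------------------------------------------------------
# File emission


def write_scene(
    scene: TruthScene,
    out_dir: str,
    write_sam: bool = False,
    write_bam: bool = False,
) -> Dict[str, str]:
    """Write VCF, GTF, fragment text and truth haplotypes (optionally SAM/BAM)."""
    from . import io_formats

    os.makedirs(out_dir, exist_ok=True)
    cfg = scene.config
    paths = {
        "vcf": os.path.join(out_dir, "scene.vcf"),
        "gtf": os.path.join(out_dir, "scene.gtf"),
        "fragments": os.path.join(out_dir, "scene.fragments.txt"),
        "truth": os.path.join(out_dir, "scene.truth.txt"),
    }

    chrom_len = max(s.pos for s in scene.panel) + 10000
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cfg.chrom},length={chrom_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{cfg.sample}\n"
        )
        for snp in scene.panel:
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t.\t{snp.ref_allele}\t"
                f"{snp.alt_allele}\t.\tPASS\t.\tGT\t0/1\n"
            )

    with open(paths["gtf"], "w") as fh:
        for gene in scene.genes:
            start = gene.exons[0][0] + 1
            end = gene.exons[-1][1]
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{gene.chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\t{attrs}\n"
            )
            for e0, e1 in gene.exons:
                fh.write(
                    f"{gene.chrom}\tsim\texon\t{e0 + 1}\t{e1}\t.\t+\t.\t"
                    f'{attrs} transcript_id "{gene.gene_id}.t1";\n'
                )

    io_formats.write_fragments(scene.fragments, paths["fragments"])
    io_formats.write_truth_haplotypes(scene.truth, paths["truth"])

    if write_sam or write_bam:
        paths["sam"] = os.path.join(out_dir, "scene.sam")
        _write_sam(scene, paths["sam"], chrom_len)
        if write_bam:
            import pysam

            paths["bam"] = os.path.join(out_dir, "scene.bam")
            pysam.sort("-o", paths["bam"], paths["sam"])
            pysam.index(paths["bam"])

    scene.files.update(paths)
    return paths


def _write_sam(scene: TruthScene, path: str, chrom_len: int) -> None:
    """Emit each fragment as one spliced alignment: 1M per SNP base, N-gaps
    between consecutive SNPs (transcript splicing collapsed to the SNPs)."""
    cfg = scene.config
    panel = scene.panel
    rows: List[Tuple[int, str]] = []
    for frag in scene.fragments:
        snp_idx = frag.snp_indices()
        positions = [panel.get(frag.chrom, s).pos for s in snp_idx]
        start = positions[0]
        cigar_parts: List[str] = []
        seq_parts: List[str] = []
        qual_parts: List[str] = []
        prev = None
        for s, pos in zip(snp_idx, positions):
            if prev is not None:
                gap = pos - prev - 1
                if gap > 0:
                    cigar_parts.append(f"{gap}N")
            cigar_parts.append("1M")
            snp = panel.get(frag.chrom, s)
            base = snp.ref_allele if frag.alleles[s] == 0 else snp.alt_allele
            seq_parts.append(base)
            qual_parts.append(_phred_char(frag.errors[s]))
            prev = pos
        tags = []
        if frag.barcode is not None:
            tags.append(f"BX:Z:{frag.barcode}")
        row = "\t".join(
            [
                frag.id,
                "0",
                frag.chrom,
                str(start),
                "60",
                "".join(cigar_parts),
                "*",
                "0",
                "0",
                "".join(seq_parts),
                "".join(qual_parts),
            ]
            + tags
        )
        rows.append((start, row))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{cfg.chrom}\tLN:{chrom_len}\n")
        for _, row in rows:
            fh.write(row + "\n")


def scene_report(scene: TruthScene):
    """Per-gene truth summary for test assertions (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for gid in sorted(scene.gene_truth):
        gt = scene.gene_truth[gid]
        rows.append(
            {
                "gene_id": gid,
                "true_beta": gt.beta,
                "overexpressed_hap": gt.overexpressed_hap,
                "n_reads": gt.n_reads,
                "n_snps": len(gt.snp_indices),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "true_beta", "overexpressed_hap", "n_reads", "n_snps"]
    )
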