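"""Readers and writers for the standard genomics formats the phaser consumes.

VCF positions are 1-based; internal exon intervals are 0-based half-open.
Conversion happens only here, at the I/O boundary.
"""

from __future__ import annotations

import logging
import sys
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, IO, Iterable, List, Optional, Sequence, Tuple, Union

import pysam
from intervaltree import IntervalTree

from .model import Fragment, Gene, HetSNP, PhasedBlock, SNPPanel

log = logging.getLogger(__name__)

# Phred -> error-probability clamp: epsilon must stay inside (0, 0.5)
EPS_MIN = 1e-6
EPS_MAX = 0.49

NUCLEOTIDES = {"A", "C", "G", "T"}


def phred_to_error(q: float) -> float:
    """Base quality Q -> opposite-allele probability 10^(-Q/10), clamped."""
    return min(max(10.0 ** (-q / 10.0), EPS_MIN), EPS_MAX)


# ---------------------------------------------------------------------------
# VCF


def read_het_snps(vcf_path: str, sample: Optional[str] = None) -> SNPPanel:
    """Read the biallelic heterozygous SNPs of one sample into a panel.

    Multi-allelic, homozygous, missing-genotype and non-SNP records are
    skipped and counted.  Any pre-existing phase in the genotype (| vs /)
    is ignored.
    """
    vcf = pysam.VariantFile(vcf_path)
    samples = list(vcf.header.samples)
    if not samples:
        raise ValueError("VCF has no sample columns")
    if sample is None:
        sample = samples[0]
    if sample not in samples:
        raise ValueError(f"sample {sample!r} not in VCF (has {samples})")

    snps: List[HetSNP] = []
    skipped = 0
    for rec in vcf:
        alts = rec.alts or ()
        if (
            len(alts) != 1
            or rec.ref is None
            or len(rec.ref) != 1
            or len(alts[0]) != 1
            or rec.ref.upper() not in NUCLEOTIDES
            or alts[0].upper() not in NUCLEOTIDES
        ):
            skipped += 1
            continue
        gt = rec.samples[sample].get("GT")
        if gt is None or None in gt or len(gt) != 2 or set(gt) != {0, 1}:
            skipped += 1
            continue
        snps.append(
            HetSNP(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref.upper(),
                alt_allele=alts[0].upper(),
                index=0,  # densified by SNPPanel
            )
        )
    if not snps:
        log.warning("no heterozygous biallelic SNPs found in %s", vcf_path)
    return SNPPanel(snps, skipped=skipped)


# ---------------------------------------------------------------------------
# Gene annotation


def read_gene_model(
    annotation_path: str,
    panel: SNPPanel,
    gene_key: str = "gene_id",
) -> List[Gene]:
    """Parse a GTF/GFF annotation into genes with merged exons and panel SNPs.

    Exon records are grouped by the ``gene_key`` attribute (falling back to
    the exon's parent gene feature in GFF3); overlapping exons are merged.
    Records without a resolvable gene identifier are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        annotation_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons_by_gene: Dict[str, Tuple[str, List[Tuple[int, int]]]] = {}

    def gene_id_of(feature) -> Optional[str]:
        if gene_key in feature.attributes:
            return feature.attributes[gene_key][0]
        # GFF3 fallback: walk Parent chain to a gene feature
        try:
            for parent in db.parents(feature, featuretype="gene"):
                if gene_key in parent.attributes:
                    return parent.attributes[gene_key][0]
                return parent.id
        except Exception:
            pass
        return None

    for feature in db.features_of_type("gene"):
        gid = gene_id_of(feature) or feature.id
        exons_by_gene.setdefault(gid, (feature.seqid, []))

    for exon in db.features_of_type("exon"):
        gid = gene_id_of(exon)
        if gid is None:
            log.warning("exon %s:%d-%d has no %s; skipped",
                        exon.seqid, exon.start, exon.end, gene_key)
            continue
        chrom, lst = exons_by_gene.setdefault(gid, (exon.seqid, []))
        # gffutils start is 1-based inclusive -> 0-based half-open
        lst.append((exon.start - 1, exon.end))

    genes: List[Gene] = []
    for gid, (chrom, exons) in exons_by_gene.items():
        merged = merge_intervals(exons)
        tree = IntervalTree.from_tuples(merged) if merged else IntervalTree()
        snp_indices = [
            s.index for s in panel.snps(chrom) if tree.overlaps_point(s.pos - 1)
        ]
        genes.append(Gene(gene_id=gid, chrom=chrom, exons=merged,
                          snp_indices=snp_indices))
    genes.sort(key=lambda g: (g.chrom, g.exons[0][0] if g.exons else 0))
    return genes


def merge_intervals(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    out: List[Tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


# ---------------------------------------------------------------------------
# Alignment -> fragments


@dataclass
class ExtractionOptions:
    min_mapq: int = 20
    min_baseq: int = 10
    barcode_tag: str = "BX"
    # at a SNP where two mates disagree: drop the locus (default) or fragment
    mate_conflict: str = "drop_locus"


def extract_fragments(
    alignment_path: str,
    panel: SNPPanel,
    genes: Optional[List[Gene]] = None,
    options: Optional[ExtractionOptions] = None,
) -> List[Fragment]:
    """Walk a coordinate-sorted SAM/BAM file and emit one Fragment per template.

    For every panel SNP covered by an aligned base, the fragment records
    allele 0 (reference base), allele 1 (alternative base) or nothing (any
    other base).  CIGAR splice and indel operators are honoured via the
    aligned-pairs walk, so spliced RNA-seq reads link SNPs across introns.
    Mates sharing a query name are merged; empty fragments are dropped.
    """
    options = options or ExtractionOptions()
    mode = "rb" if alignment_path.endswith(".bam") else "r"
    af = pysam.AlignmentFile(alignment_path, mode)
    so = (af.header.to_dict().get("HD") or {}).get("SO")
    if so != "coordinate":
        raise ValueError(
            f"{alignment_path}: alignment must be coordinate-sorted (SO={so!r})"
        )

    pos_maps = {chrom: panel.position_index_map(chrom) for chrom in panel.chromosomes}

    # query name -> partial fragment state
    partial: Dict[Tuple[str, str], Tuple[Dict[int, int], Dict[int, float], set]] = {}
    barcodes: Dict[Tuple[str, str], str] = {}

    for read in af.fetch(until_eof=True):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.mapping_quality < options.min_mapq
        ):
            continue
        chrom = read.reference_name
        pos_map = pos_maps.get(chrom)
        if not pos_map:
            continue
        seq = read.query_sequence
        quals = read.query_qualities
        if seq is None:
            continue
        key = (chrom, read.query_name)
        alleles, errors, dropped = partial.setdefault(key, ({}, {}, set()))
        if options.barcode_tag and read.has_tag(options.barcode_tag):
            barcodes[key] = str(read.get_tag(options.barcode_tag))
        snps = panel.snps(chrom)
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            idx = pos_map.get(rpos)
            if idx is None:
                continue
            q = quals[qpos] if quals is not None else 30
            if q < options.min_baseq:
                continue
            base = seq[qpos].upper()
            snp = snps[idx]
            if base == snp.ref_allele:
                allele = 0
            elif base == snp.alt_allele:
                allele = 1
            else:
                continue  # allele not observed in the genotype
            err = phred_to_error(q)
            if idx in dropped:
                continue
            if idx in alleles and alleles[idx] != allele:
                # mate conflict at a shared SNP
                if options.mate_conflict == "drop_fragment":
                    dropped.add("__fragment__")
                else:
                    del alleles[idx]
                    del errors[idx]
                    dropped.add(idx)
                continue
            if idx not in alleles or err < errors[idx]:
                alleles[idx] = allele
                errors[idx] = err

    fragments: List[Fragment] = []
    for (chrom, name), (alleles, errors, dropped) in partial.items():
        if "__fragment__" in dropped or not alleles:
            continue
        frag = Fragment(
            id=name,
            chrom=chrom,
            alleles=dict(alleles),
            errors=dict(errors),
            barcode=barcodes.get((chrom, name)),
        )
        fragments.append(frag)
    fragments.sort(key=lambda f: (f.chrom, min(f.alleles), f.id))
    if genes:
        assign_gene_ids(fragments, genes)
    return fragments


def assign_gene_ids(fragments: Iterable[Fragment], genes: List[Gene]) -> None:
    """Tag each fragment whose SNPs all fall in exactly one gene's SNP set.

    A fragment spanning SNPs of two genes keeps its contiguity evidence but
    gets no gene tag (distinct genes have independent expression biases); a
    fragment ambiguous between overlapping genes is likewise left untagged.
    """
    snp_to_genes: Dict[Tuple[str, int], set] = defaultdict(set)
    gene_snps = {g.gene_id: set(g.snp_indices) for g in genes}
    for g in genes:
        for s in g.snp_indices:
            snp_to_genes[(g.chrom, s)].add(g.gene_id)
    for frag in fragments:
        candidate: set = set()
        first = True
        for s in frag.alleles:
            gset = snp_to_genes.get((frag.chrom, s), set())
            candidate = set(gset) if first else candidate & gset
            first = False
        containing = {
            gid for gid in candidate if set(frag.alleles) <= gene_snps[gid]
        }
        frag.gene_id = next(iter(containing)) if len(containing) == 1 else None


# ---------------------------------------------------------------------------
# Barcode merging


def merge_barcoded_fragments(fragments: List[Fragment]) -> List[Fragment]:
    """Merge fragments sharing a barcode on one chromosome into pseudo-fragments.

    Allele conflicts at a shared SNP are resolved by majority vote; ties drop
    the locus.  Untagged fragments pass through unchanged.  Idempotent.
    """
    groups: Dict[Tuple[str, str], List[Fragment]] = defaultdict(list)
    out: List[Fragment] = []
    for frag in fragments:
        if frag.barcode is None:
            out.append(frag)
        else:
            groups[(frag.chrom, frag.barcode)].append(frag)

    for (chrom, barcode), members in sorted(groups.items()):
        if len(members) == 1:
            out.append(members[0])
            continue
        votes: Dict[int, Dict[int, List[float]]] = defaultdict(lambda: {0: [], 1: []})
        for frag in members:
            for s, a in frag.alleles.items():
                votes[s][a].append(frag.errors[s])
        alleles: Dict[int, int] = {}
        errors: Dict[int, float] = {}
        for s, by_allele in votes.items():
            n0, n1 = len(by_allele[0]), len(by_allele[1])
            if n0 == n1:
                continue  # tie: locus dropped
            winner = 0 if n0 > n1 else 1
            alleles[s] = winner
            errors[s] = min(by_allele[winner])
        if not alleles:
            continue
        gene_ids = {f.gene_id for f in members}
        out.append(
            Fragment(
                id=f"BX:{barcode}",
                chrom=chrom,
                alleles=alleles,
                errors=errors,
                gene_id=gene_ids.pop() if len(gene_ids) == 1 else None,
                barcode=barcode,
            )
        )
    out.sort(key=lambda f: (f.chrom, min(f.alleles), f.id))
    return out


# ---------------------------------------------------------------------------
# Fragment text format (one fragment per line)
#   id chrom [gene=G] [bx=B] index:allele:errprob ...


def write_fragments(fragments: Iterable[Fragment], sink: Union[str, IO[str]]) -> None:
    fh, close = _open_sink(sink)
    try:
        for frag in fragments:
            fields = [frag.id, frag.chrom]
            if frag.gene_id is not None:
                fields.append(f"gene={frag.gene_id}")
            if frag.barcode is not None:
                fields.append(f"bx={frag.barcode}")
            for s in sorted(frag.alleles):
                fields.append(f"{s}:{frag.alleles[s]}:{frag.errors[s]:.6g}")
            fh.write("\t".join(fields) + "\n")
    finally:
        if close:
            fh.close()


def read_fragments(source: Union[str, IO[str]]) -> List[Fragment]:
    fh, close = _open_source(source)
    fragments: List[Fragment] = []
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"fragment line {lineno}: too few fields")
            frag_id, chrom = fields[0], fields[1]
            gene_id = barcode = None
            alleles: Dict[int, int] = {}
            errors: Dict[int, float] = {}
            for tok in fields[2:]:
                if tok.startswith("gene="):
                    gene_id = tok[5:]
                elif tok.startswith("bx="):
                    barcode = tok[3:]
                else:
                    s_str, a_str, e_str = tok.split(":")
                    alleles[int(s_str)] = int(a_str)
                    errors[int(s_str)] = float(e_str)
            fragments.append(
                Fragment(frag_id, chrom, alleles, errors, gene_id, barcode)
            )
    finally:
        if close:
            fh.close()
    return fragments


# ---------------------------------------------------------------------------
# Phased block text (HapCUT-style) and phased VCF


def write_blocks(
    blocks: List[PhasedBlock],
    panel: SNPPanel,
    sink: Union[str, IO[str]],
) -> None:
    """Emit phased blocks as HapCUT-style text.

    Per block: a ``BLOCK:`` header, one line per SNP (panel index, h0 allele,
    h1 allele, chrom, 1-based position), and a ``****`` terminator.
    """
    fh, close = _open_sink(sink)
    try:
        fh.write("# dasephase phased blocks\n")
        for block in blocks:
            first = panel.get(block.chrom, block.snp_indices[0])
            last = panel.get(block.chrom, block.snp_indices[-1])
            fh.write(
                f"BLOCK: id {block.block_id} len {block.size} "
                f"span {last.pos - first.pos} "
                f"evidence {','.join(sorted(block.evidence)) or '.'}\n"
            )
            for s, a in zip(block.snp_indices, block.h0):
                snp = panel.get(block.chrom, s)
                fh.write(f"{s}\t{a}\t{1 - a}\t{block.chrom}\t{snp.pos}\n")
            fh.write("****\n")
    finally:
        if close:
            fh.close()


def read_blocks(source: Union[str, IO[str]]) -> List[PhasedBlock]:
    """Parse HapCUT-style block text written by :func:`write_blocks`."""
    fh, close = _open_source(source)
    blocks: List[PhasedBlock] = []
    cur_id: Optional[int] = None
    cur_evidence: set = set()
    snp_indices: List[int] = []
    h0: List[int] = []
    chrom: Optional[str] = None
    try:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("BLOCK:"):
                fields = line.split()
                cur_id = int(fields[2])
                ev = fields[8]
                cur_evidence = set() if ev == "." else set(ev.split(","))
                snp_indices, h0, chrom = [], [], None
            elif line.startswith("****"):
                assert cur_id is not None and chrom is not None
                blocks.append(
                    PhasedBlock(cur_id, chrom, snp_indices, h0, cur_evidence)
                )
                cur_id = None
            else:
                s, a0, _a1, chrom, _pos = line.split("\t")
                snp_indices.append(int(s))
                h0.append(int(a0))
    finally:
        if close:
            fh.close()
    return blocks


def write_phased_vcf(
    blocks: List[PhasedBlock],
    panel: SNPPanel,
    input_vcf: str,
    output_vcf: str,
    sample: Optional[str] = None,
) -> None:
    """Write the input VCF with each block's SNPs phased and PS-tagged.

    PS equals the 1-based position of the block's first SNP, the common
    convention for read-backed phasers.
    """
    vcf_in = pysam.VariantFile(input_vcf)
    header = vcf_in.header
    if "PS" not in header.formats:
        header.formats.add("PS", "1", "Integer", "Phase set identifier")
    samples = list(header.samples)
    if sample is None:
        sample = samples[0]

    phase: Dict[Tuple[str, int], Tuple[int, int]] = {}
    for block in blocks:
        ps = panel.get(block.chrom, block.snp_indices[0]).pos
        for s, a in zip(block.snp_indices, block.h0):
            snp = panel.get(block.chrom, s)
            phase[(block.chrom, snp.pos)] = (a, ps)

    vcf_out = pysam.VariantFile(output_vcf, "w", header=header)
    for rec in vcf_in:
        hit = phase.get((rec.chrom, rec.pos))
        if hit is not None:
            a, ps = hit
            rec.samples[sample]["GT"] = (a, 1 - a)
            rec.samples[sample].phased = True
            rec.samples[sample]["PS"] = ps
        vcf_out.write(rec)
    vcf_out.close()


# ---------------------------------------------------------------------------
# Truth haplotypes (two-column text keyed by chrom:pos)


def write_truth_haplotypes(
    truth: Dict[Tuple[str, int], int], sink: Union[str, IO[str]]
) -> None:
    """Write ``chrom pos h0_allele h1_allele`` lines, sorted by locus."""
    fh, close = _open_sink(sink)
    try:
        fh.write("#chrom\tpos\th0\th1\n")
        for (chrom, pos), a in sorted(truth.items()):
            fh.write(f"{chrom}\t{pos}\t{a}\t{1 - a}\n")
    finally:
        if close:
            fh.close()


def read_truth_haplotypes(source: Union[str, IO[str]]) -> Dict[Tuple[str, int], int]:
    fh, close = _open_source(source)
    truth: Dict[Tuple[str, int], int] = {}
    try:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, a0, _a1 = line.split()
            truth[(chrom, int(pos))] = int(a0)
    finally:
        if close:
            fh.close()
    return truth


def read_truth_vcf(vcf_path: str, sample: Optional[str] = None) -> Dict[Tuple[str, int], int]:
    """Read an oriented truth haplotype from the phased genotypes of a VCF."""
    vcf = pysam.VariantFile(vcf_path)
    if sample is None:
        sample = list(vcf.header.samples)[0]
    truth: Dict[Tuple[str, int], int] = {}
    for rec in vcf:
        sd = rec.samples[sample]
        gt = sd.get("GT")
        if gt is None or None in gt or len(gt) != 2 or set(gt) != {0, 1}:
            continue
        if not sd.phased:
            continue
        truth[(rec.chrom, rec.pos)] = gt[0]
    return truth


# ---------------------------------------------------------------------------


def _open_sink(sink: Union[str, IO[str]]) -> Tuple[IO[str], bool]:
    if isinstance(sink, str):
        return open(sink, "w"), True
    return sink, False


def _open_source(source: Union[str, IO[str]]) -> Tuple[IO[str], bool]:
    if isinstance(source, str):
        return open(source), True
    return source, False
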