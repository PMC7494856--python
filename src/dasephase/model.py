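"""Core data model for diploid haplotype phasing.

A diploid phase over a set of heterozygous biallelic SNPs is a pair of
complementary binary sequences ``(h0, h1)`` where 0 denotes the reference
allele and 1 the alternative allele.  Reads are sparse binary vectors over
the SNP panel with per-locus error probabilities; loci a read does not cover
(or covers with a base matching neither genotyped allele) are simply absent
from its map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

Node = Tuple[str, int]  # (chromosome, per-chromosome SNP index)


@dataclass(frozen=True)
class HetSNP:
    """A biallelic heterozygous SNP locus.

    ``pos`` is 1-based (VCF convention); ``index`` is the dense 0-based rank
    of the SNP within its chromosome's position-sorted panel.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    index: int


class SNPPanel:
    """The ordered set of heterozygous SNPs to phase, grouped by chromosome.

    Indices are dense and 0-based per chromosome; positions are strictly
    increasing within a chromosome.
    """

    def __init__(self, snps: Iterable[HetSNP] = (), skipped: int = 0):
        self._by_chrom: Dict[str, List[HetSNP]] = {}
        for snp in snps:
            self._by_chrom.setdefault(snp.chrom, []).append(snp)
        for chrom, lst in self._by_chrom.items():
            lst.sort(key=lambda s: s.pos)
            for i, snp in enumerate(lst):
                if snp.index != i:
                    object.__setattr__(snp, "index", i)
            positions = [s.pos for s in lst]
            if len(set(positions)) != len(positions):
                raise ValueError(f"duplicate SNP positions on {chrom}")
        self.skipped = skipped
        self._pos_lookup: Dict[str, Dict[int, int]] = {
            chrom: {s.pos: s.index for s in lst}
            for chrom, lst in self._by_chrom.items()
        }

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._by_chrom)

    def snps(self, chrom: str) -> List[HetSNP]:
        return self._by_chrom.get(chrom, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[HetSNP]:
        for chrom in self.chromosomes:
            yield from self._by_chrom[chrom]

    def get(self, chrom: str, index: int) -> HetSNP:
        return self._by_chrom[chrom][index]

    def index_of_position(self, chrom: str, pos: int) -> Optional[int]:
        """Panel index of the SNP at 1-based ``pos``, or None."""
        return self._pos_lookup.get(chrom, {}).get(pos)

    def position_index_map(self, chrom: str) -> Dict[int, int]:
        """0-based genomic position -> panel index, for alignment walking."""
        return {s.pos - 1: s.index for s in self._by_chrom.get(chrom, [])}


@dataclass
class Fragment:
    """A read (or merged read pair / barcode group) as a sparse allele vector.

    ``alleles`` maps per-chromosome SNP index -> observed allele in {0, 1};
    ``errors`` maps the same keys to the probability of opposite-allele
    information at that locus, in (0, 0.5).  Loci outside the map carry no
    information.
    """

    id: str
    chrom: str
    alleles: Dict[int, int]
    errors: Dict[int, float]
    gene_id: Optional[str] = None
    barcode: Optional[str] = None

    def __post_init__(self) -> None:
        if set(self.alleles) != set(self.errors):
            raise ValueError(f"fragment {self.id}: allele/error keys differ")

    @property
    def size(self) -> int:
        return len(self.alleles)

    def snp_indices(self) -> List[int]:
        return sorted(self.alleles)


@dataclass
class Gene:
    """An annotated gene: merged exon intervals and the panel SNPs they contain.

    Exons are 0-based half-open intervals, non-overlapping after merging;
    ``snp_indices`` are the panel SNPs (by per-chromosome index) falling in
    any exon, sorted by position.  A gene with no exonic het SNPs is inert
    for expression-based phasing but is retained.
    """

    gene_id: str
    chrom: str
    exons: List[Tuple[int, int]]
    snp_indices: List[int] = field(default_factory=list)

    @property
    def inert(self) -> bool:
        return len(self.snp_indices) == 0


@dataclass
class PhasedBlock:
    """A phased haplotype block: one connected component of the joint read graph.

    ``h0`` is the binary assignment over ``snp_indices`` (same order); the
    second haplotype is its complement.  ``evidence`` tags which sources
    linked the block: 'contig', 'dase', and/or 'barcode'.
    """

    block_id: int
    chrom: str
    snp_indices: List[int]
    h0: List[int]
    evidence: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.h0) != len(self.snp_indices):
            raise ValueError("h0 length must match snp_indices")
        if any(a not in (0, 1) for a in self.h0):
            raise ValueError("h0 must be binary")

    @property
    def h1(self) -> List[int]:
        return [1 - a for a in self.h0]

    @property
    def size(self) -> int:
        return len(self.snp_indices)

    def allele_map(self) -> Dict[int, int]:
        return dict(zip(self.snp_indices, self.h0))


class AlleleCounts:
    """Per-SNP allele tallies ``(C_s^0, C_s^1)`` over a restricted read set."""

    def __init__(self, counts: Optional[Dict[int, Tuple[int, int]]] = None):
        self.counts: Dict[int, Tuple[int, int]] = dict(counts or {})

    def c0(self, s: int) -> int:
        return self.counts.get(s, (0, 0))[0]

    def c1(self, s: int) -> int:
        return self.counts.get(s, (0, 0))[1]

    def snps(self) -> List[int]:
        return sorted(self.counts)

    @property
    def minority_total(self) -> int:
        """m = sum over SNPs of min(c0, c1)."""
        return sum(min(c) for c in self.counts.values())

    @property
    def majority_total(self) -> int:
        """M = sum over SNPs of max(c0, c1)."""
        return sum(max(c) for c in self.counts.values())

    @property
    def n_reads(self) -> int:
        return sum(c[0] + c[1] for c in self.counts.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AlleleCounts) and self.counts == other.counts

    def __repr__(self) -> str:
        return f"AlleleCounts({self.counts!r})"


@dataclass
class DHEEstimate:
    """Maximum-likelihood differential haplotypic expression for one gene.

    ``beta`` is the probability that a read of the gene originates from the
    higher-expressed haplotype (so beta >= 0.5 by convention); ``gamma0`` and
    ``gamma1`` fold the gene's representative base-error rate into the
    per-read observation rates: gamma_i = beta_i (1 - eps) + (1 - beta_i) eps.
    """

    gene_id: str
    beta: float
    log_likelihood: float
    nonuniform_pvalue: float
    eligible: bool
    gamma0: float
    gamma1: float
    n_reads: int = 0

    def __post_init__(self) -> None:
        if not (0.5 <= self.beta <= 1.0):
            raise ValueError(f"beta {self.beta} outside [0.5, 1]")


@dataclass
class SNPAssessment:
    """Concordance screen for one SNP: how confidently its observed majority
    allele reflects the gene's higher-expressed haplotype."""

    prob_concordant: float
    phaseable: bool
    tied: bool = False


class ReadBiasAssignment:
    """Expected haplotype-origin probabilities ``(b0, b1)`` per fragment.

    Fragments of ineligible genes, of no gene, or spanning non-phaseable SNPs
    default to the uninformative (0.5, 0.5).
    """

    def __init__(self) -> None:
        self._biases: Dict[str, Tuple[float, float]] = {}

    def set(self, fragment_id: str, b0: float) -> None:
        if not (0.5 <= b0 <= 1.0):
            raise ValueError("b0 must lie in [0.5, 1]")
        self._biases[fragment_id] = (b0, 1.0 - b0)

    def get(self, fragment: "Fragment") -> Tuple[float, float]:
        return self._biases.get(fragment.id, (0.5, 0.5))

    def is_biased(self, fragment: "Fragment") -> bool:
        b0, _ = self.get(fragment)
        return b0 != 0.5

    def __len__(self) -> int:
        return len(self._biases)
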