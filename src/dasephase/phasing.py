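"""Maximum-relative-likelihood haplotype search over joint evidence blocks.

Blocks to phase are the connected components of a joint read graph: SNPs are
vertices, two SNPs are linked if some fragment covers both (contiguity
evidence) or both are expression-phaseable SNPs of the same eligible gene
(allelic-imbalance evidence).  Within a block, a candidate phase H = (h0,
complement) is scored by its relative likelihood

    RL(H) = P(H) * prod_r sum_i b_i^r  prod_{s in A(r,H_i)} (1 - eps_{r,s})
                                        prod_{s in D(r,H_i)} eps_{r,s}

where (b_0^r, b_1^r) is the read's expected haplotype-origin bias, A/D are
the SNPs where the read agrees/disagrees with haplotype i, and the prior
P(H) = rho^P(H) (1-rho)^S(H) counts parallel/switched adjacent SNP pairs.
Biased single-SNP reads make RL asymmetric between a phase and its
complement, which is what lets coverage imbalance orient and link SNPs that
no read pair connects.

Small blocks are solved by exhaustive enumeration; larger ones by a
branch-and-prune beam search in genomic SNP order that maintains, per
candidate prefix, the two partial agreement products of every fragment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .dase import GeneAnalysis
from .model import (
    Fragment,
    Gene,
    Node,
    PhasedBlock,
    ReadBiasAssignment,
    SNPAssessment,
    SNPPanel,
)

_LOG_HALF = math.log(0.5)


@dataclass
class SearchConfig:
    """Branch-and-prune search parameters.

    Candidates whose relative likelihood falls below best * prune_ratio are
    discarded; the beam is capped at beam_width.  Blocks with at most
    exhaustive_cutoff SNPs are enumerated exactly instead.
    """

    beam_width: int = 128
    prune_ratio: float = 0.01
    exhaustive_cutoff: int = 12
    rho: float = 0.5


@dataclass
class ReadGraph:
    """Contiguity graph: SNP vertices, edges between co-covered loci."""

    graph: nx.Graph
    components: List[List[Node]]  # genomic order, each sorted


def _sorted_components(graph: nx.Graph) -> List[List[Node]]:
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: c[0])
    return comps


def build_read_graph(fragments: Sequence[Fragment], panel: SNPPanel) -> ReadGraph:
    """Vertices are (chrom, index) for covered SNPs; an edge joins any two
    SNPs contained in a common fragment."""
    g = nx.Graph()
    for frag in fragments:
        snps = frag.snp_indices()
        nodes = [(frag.chrom, s) for s in snps]
        g.add_nodes_from(nodes)
        for a, b in zip(nodes, nodes[1:]):
            g.add_edge(a, b)
    return ReadGraph(graph=g, components=_sorted_components(g))


def build_joint_blocks(
    graph: ReadGraph,
    genes: Sequence[Gene],
    analyses: Dict[str, GeneAnalysis],
) -> List[List[Node]]:
    """Components of the joint read graph: contiguity edges plus, for each
    eligible gene, a clique over its expression-phaseable SNPs.

    No edge is ever added between SNPs of distinct genes on expression
    evidence alone (independent biases carry no cross-gene correlation).
    """
    g = graph.graph.copy()
    for gene in genes:
        analysis = analyses.get(gene.gene_id)
        if analysis is None or not analysis.estimate.eligible:
            continue
        phaseable = [
            (gene.chrom, s)
            for s in gene.snp_indices
            if analysis.assessments.get(s) and analysis.assessments[s].phaseable
        ]
        g.add_nodes_from(phaseable)
        for a, b in zip(phaseable, phaseable[1:]):
            g.add_edge(a, b)  # a path suffices for connectivity
    return _sorted_components(g)


# ---------------------------------------------------------------------------
# Likelihood pieces


def read_log_likelihood(
    fragment: Fragment,
    h0: Dict[int, int],
    biases: ReadBiasAssignment,
) -> float:
    """log P[r | H, biases, errors] for a single fragment (mixture over the
    two haplotype origins)."""
    b0, b1 = biases.get(fragment)
    lp0 = lp1 = 0.0
    for s, a in fragment.alleles.items():
        eps = fragment.errors[s]
        if h0[s] == a:
            lp0 += math.log(1.0 - eps)
            lp1 += math.log(eps)
        else:
            lp0 += math.log(eps)
            lp1 += math.log(1.0 - eps)
    return float(np.logaddexp(math.log(b0) + lp0, math.log(b1) + lp1))


def phase_log_prior(h0: Sequence[int], rho: float = 0.5) -> float:
    """log P(H) = P(H) log rho + S(H) log(1-rho) over adjacent SNP pairs."""
    if not 0.5 <= rho < 1.0:
        raise ValueError(f"rho {rho} outside [0.5, 1)")
    parallel = sum(1 for a, b in zip(h0, h0[1:]) if a == b)
    switched = len(h0) - 1 - parallel
    return parallel * math.log(rho) + switched * math.log(1.0 - rho)


def relative_likelihood(
    h0: Sequence[int],
    snp_indices: Sequence[int],
    fragments: Sequence[Fragment],
    biases: ReadBiasAssignment,
    rho: float = 0.5,
) -> float:
    """log RL(H) = sum_r log P[r | H] + log P(H) over one block."""
    assignment = dict(zip(snp_indices, h0))
    total = phase_log_prior(list(h0), rho)
    for frag in fragments:
        total += read_log_likelihood(frag, assignment, biases)
    return total


# ---------------------------------------------------------------------------
# Block search


def _enumerate_block(
    snp_indices: List[int],
    fragments: Sequence[Fragment],
    biases: ReadBiasAssignment,
    rho: float,
) -> Tuple[List[int], float]:
    """Exact maximizer of RL by vectorized enumeration of all 2^n phases."""
    n = len(snp_indices)
    pos = {s: i for i, s in enumerate(snp_indices)}
    codes = np.arange(2 ** n, dtype=np.int64)
    h = ((codes[:, None] >> np.arange(n)) & 1).astype(np.int8)  # (2^n, n)

    log_rho, log_sw = math.log(rho), math.log(1.0 - rho) if rho < 1 else -math.inf
    if n > 1:
        parallel = (h[:, :-1] == h[:, 1:]).sum(axis=1)
        scores = parallel * log_rho + (n - 1 - parallel) * log_sw
    else:
        scores = np.zeros(2 ** n)

    for frag in fragments:
        b0, b1 = biases.get(frag)
        lp0 = np.zeros(2 ** n)
        for s, a in frag.alleles.items():
            eps = frag.errors[s]
            match = h[:, pos[s]] == a
            lp0 += np.where(match, math.log(1 - eps), math.log(eps))
        # complement haplotype flips every agreement
        lp_tot = sum(
            math.log(1 - frag.errors[s]) + math.log(frag.errors[s])
            for s in frag.alleles
        )
        lp1 = lp_tot - lp0
        scores += np.logaddexp(math.log(b0) + lp0, math.log(b1) + lp1)

    best = int(np.argmax(scores))
    return list(h[best]), float(scores[best])


@dataclass
class _Candidate:
    h0: List[int]
    score: float  # prior-so-far + sum over touched fragments
    # fragment -> (log agree-product with h0, with complement)
    partial: Dict[int, Tuple[float, float]]


def _beam_search_block(
    snp_indices: List[int],
    fragments: Sequence[Fragment],
    biases: ReadBiasAssignment,
    config: SearchConfig,
) -> Tuple[List[int], float]:
    """Branch-and-prune beam search in genomic SNP order.

    Each candidate prefix keeps, per fragment it has touched, the running
    log-products of per-locus agreement with h0 and with its complement; the
    candidate score uses the completed mixture for those fragments, so
    pruning compares like with like.
    """
    frag_at: Dict[int, List[int]] = {s: [] for s in snp_indices}
    for fi, frag in enumerate(fragments):
        for s in frag.alleles:
            if s in frag_at:
                frag_at[s].append(fi)

    log_rho = math.log(config.rho)
    log_sw = math.log(1.0 - config.rho)
    log_prune = math.log(config.prune_ratio) if config.prune_ratio > 0 else -math.inf

    def mixture(fi: int, lp0: float, lp1: float) -> float:
        b0, b1 = biases.get(fragments[fi])
        return float(np.logaddexp(math.log(b0) + lp0, math.log(b1) + lp1))

    candidates = [_Candidate([], 0.0, {})]
    for depth, s in enumerate(snp_indices):
        new: List[_Candidate] = []
        for cand in candidates:
            for allele in (0, 1):
                partial = dict(cand.partial)
                score = cand.score
                if depth > 0:
                    score += log_rho if cand.h0[-1] == allele else log_sw
                for fi in frag_at[s]:
                    frag = fragments[fi]
                    eps = frag.errors[s]
                    la, ld = math.log(1 - eps), math.log(eps)
                    lp0, lp1 = partial.get(fi, (0.0, 0.0))
                    if lp0 or lp1:
                        score -= mixture(fi, lp0, lp1)
                    if frag.alleles[s] == allele:
                        lp0, lp1 = lp0 + la, lp1 + ld
                    else:
                        lp0, lp1 = lp0 + ld, lp1 + la
                    partial[fi] = (lp0, lp1)
                    score += mixture(fi, lp0, lp1)
                new.append(_Candidate(cand.h0 + [allele], score, partial))
        new.sort(key=lambda c: -c.score)
        best = new[0].score
        new = [c for c in new if c.score >= best + log_prune]
        candidates = new[: config.beam_width]
    return candidates[0].h0, candidates[0].score


def phase_block(
    block: Sequence[Node],
    fragments: Sequence[Fragment],
    biases: ReadBiasAssignment,
    config: Optional[SearchConfig] = None,
    block_id: int = 0,
) -> Optional[PhasedBlock]:
    """Phase one block: exhaustive enumeration up to the cutoff, beam search
    beyond it; the returned h0 is canonicalized to start with allele 0 unless
    expression bias orients the block."""
    config = config or SearchConfig()
    nodes = sorted(block)
    chroms = {c for c, _ in nodes}
    if len(chroms) != 1:
        raise ValueError("a block must lie on a single chromosome")
    chrom = chroms.pop()
    snp_indices = [s for _, s in nodes]
    if len(snp_indices) < 2:
        return None
    block_set = set(snp_indices)
    block_frags = [
        f
        for f in fragments
        if f.chrom == chrom
        and not block_set.isdisjoint(f.alleles)
        # size-1 unbiased reads contribute a constant factor to every phase
        and (len(f.alleles) > 1 or biases.is_biased(f))
    ]
    has_bias = any(biases.is_biased(f) for f in block_frags)
    if not block_frags and not has_bias:
        return None

    if len(snp_indices) <= config.exhaustive_cutoff:
        h0, _ = _enumerate_block(snp_indices, block_frags, biases, config.rho)
    else:
        h0, _ = _beam_search_block(snp_indices, block_frags, biases, config)

    if not has_bias and h0[0] == 1:
        h0 = [1 - a for a in h0]  # complement-symmetric: canonicalize

    evidence: Set[str] = set()
    if any(len(set(f.alleles) & block_set) > 1 for f in block_frags):
        evidence.add("contig")
    if has_bias:
        evidence.add("dase")
    if any(f.barcode is not None for f in block_frags):
        evidence.add("barcode")
    return PhasedBlock(
        block_id=block_id,
        chrom=chrom,
        snp_indices=snp_indices,
        h0=[int(a) for a in h0],
        evidence=evidence,
    )


def phase_all(
    panel: SNPPanel,
    fragments: Sequence[Fragment],
    genes: Sequence[Gene],
    analyses: Dict[str, GeneAnalysis],
    biases: ReadBiasAssignment,
    config: Optional[SearchConfig] = None,
) -> List[PhasedBlock]:
    """Phase every joint block; deterministic given inputs.  Singleton
    components are suppressed (a one-SNP phase is vacuous)."""
    config = config or SearchConfig()
    graph = build_read_graph(fragments, panel)
    blocks = build_joint_blocks(graph, genes, analyses)
    out: List[PhasedBlock] = []
    next_id = 0
    for block in blocks:
        if len(block) < 2:
            continue
        phased = phase_block(block, fragments, biases, config, block_id=next_id)
        if phased is not None:
            out.append(phased)
            next_id += 1
    return out
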