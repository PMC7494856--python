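"""Differential haplotypic expression (DHE): estimation and screening.

A gene transcribed at different rates from its two haplotypes leaves a
signature in RNA-seq allele counts: at every heterozygous SNP the allele on
the higher-expressed haplotype is over-represented.  The probability that a
read originates from the higher-expressed haplotype is the gene's expression
bias ``beta`` (0.5 = balanced, 1 = monoallelic).  With a base-error rate
``eps``, the observable per-read rates are

    gamma_i = beta_i (1 - eps) + (1 - beta_i) eps,   beta_0 + beta_1 = 1.

``beta`` is estimated by maximum likelihood.  Multi-SNP reads break the
per-SNP independence a product likelihood needs, so each read is first
restricted to a single uniformly chosen SNP it covers (the restricted set
R').  The likelihood of R' given beta is then computed exactly by a hidden
Markov model whose hidden states are the two possible phase orientations at
each SNP, with a stay/switch transition controlled by the parallel-bias
prior ``rho``; the forward algorithm sums over all 2^n haplotypes in linear
time.  The likelihood has a unique interior maximum on [0.5, 1], found by
safeguarded Newton-Raphson with a bracketed fallback.

Two screens decide which SNPs the expression signal may phase:

* a two-sided binomial test that the gene's pooled allele counts are
  unlikely under balanced expression (beta = 0.5), and
* a per-SNP concordance probability — the posterior that the observed
  majority allele really lies on the higher-expressed haplotype,
  1 / (1 + (gamma1/gamma0)^|c0 - c1|).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .model import (
    AlleleCounts,
    DHEEstimate,
    Fragment,
    Gene,
    ReadBiasAssignment,
    SNPAssessment,
)


@dataclass
class DaseConfig:
    """Tunable parameters of the expression-based phasing stage.

    p_uniform: prior probability that a gene is uniformly expressed; the
        assigned read bias is the mixture p*0.5 + (1-p)*beta_hat.
    rho: parallel-bias prior on adjacent SNP phase (0.5 = uniform prior).
    alpha_nonuniform: significance level for the balanced-expression test a
        gene must beat to be eligible.
    min_concordance: per-SNP concordance probability required for a SNP to be
        phaseable by expression alone.
    min_gene_reads: minimum restricted reads for a gene to count as expressed.
    normal_approx_cutoff: total count above which binomial tails switch to
        the normal approximation.
    """

    p_uniform: float = 0.5
    rho: float = 0.5
    alpha_nonuniform: float = 0.01
    min_concordance: float = 0.99
    min_gene_reads: int = 10
    normal_approx_cutoff: int = 1000
    seed: int = 42


# ---------------------------------------------------------------------------
# Read restriction


def restrict_reads(
    gene_reads: Sequence[Fragment], rng: np.random.Generator
) -> List[Fragment]:
    """Restrict each multi-SNP read to one uniformly chosen covered SNP.

    Size-1 reads pass through unchanged.  The output R' has only size-1
    reads, so per-SNP read sets are mutually independent.
    """
    out: List[Fragment] = []
    for frag in gene_reads:
        if frag.size == 0:
            raise ValueError(f"fragment {frag.id} covers no SNPs")
        if frag.size == 1:
            out.append(frag)
            continue
        snps = frag.snp_indices()
        s = snps[rng.integers(len(snps))]
        out.append(
            Fragment(
                id=frag.id,
                chrom=frag.chrom,
                alleles={s: frag.alleles[s]},
                errors={s: frag.errors[s]},
                gene_id=frag.gene_id,
                barcode=frag.barcode,
            )
        )
    return out


def compute_allele_counts(restricted_reads: Sequence[Fragment]) -> AlleleCounts:
    """Tally C_s^0, C_s^1 over a size-1 read set."""
    counts: Dict[int, List[int]] = {}
    for frag in restricted_reads:
        if frag.size != 1:
            raise ValueError(f"fragment {frag.id} has size {frag.size}, expected 1")
        (s, a), = frag.alleles.items()
        counts.setdefault(s, [0, 0])[a] += 1
    return AlleleCounts({s: (c[0], c[1]) for s, c in counts.items()})


# ---------------------------------------------------------------------------
# HMM forward likelihood of the restricted reads given beta


def _per_snp_log_emissions(
    restricted_reads: Sequence[Fragment], beta: float
) -> Tuple[List[int], np.ndarray]:
    """Log emission table per SNP for the two hidden states.

    State 0: the higher-expressed haplotype carries allele 0 at the SNP;
    state 1: it carries allele 1.  A read observing the higher-expressed
    allele has probability beta(1-eps) + (1-beta)eps, else the complement.
    """
    by_snp: Dict[int, List[Tuple[int, float]]] = {}
    for frag in restricted_reads:
        (s, a), = frag.alleles.items()
        by_snp.setdefault(s, []).append((a, frag.errors[s]))
    snps = sorted(by_snp)
    logem = np.zeros((len(snps), 2))
    for i, s in enumerate(snps):
        for a, eps in by_snp[s]:
            g_hi = beta * (1.0 - eps) + (1.0 - beta) * eps
            g_lo = (1.0 - beta) * (1.0 - eps) + beta * eps
            # state h: higher-expressed haplotype allele at s is h
            logem[i, a] += math.log(g_hi) if g_hi > 0 else -math.inf
            logem[i, 1 - a] += math.log(g_lo) if g_lo > 0 else -math.inf
    return snps, logem


def forward_log_likelihood(
    restricted_reads: Sequence[Fragment],
    beta: float,
    rho: float = 0.5,
) -> float:
    """log f(beta) = log P[R' | beta, eps] by the HMM forward algorithm.

    Hidden states are the two phase orientations at each SNP (which allele
    sits on the higher-expressed haplotype); the initial distribution is
    uniform and the transition stays with probability rho, switches with
    1 - rho.  Linear in the number of SNPs and reads; carried in log space.
    """
    if not 0.5 <= beta <= 1.0:
        raise ValueError(f"beta {beta} outside [0.5, 1]")
    if not 0.5 <= rho < 1.0:
        raise ValueError(f"rho {rho} outside [0.5, 1)")
    if not restricted_reads:
        return 0.0
    _, logem = _per_snp_log_emissions(restricted_reads, beta)
    log_init = math.log(0.5)
    alpha = log_init + logem[0]  # shape (2,)
    log_rho = math.log(rho)
    log_switch = math.log1p(-rho) if rho < 1.0 else -math.inf
    for i in range(1, logem.shape[0]):
        stay = alpha + log_rho
        switch = alpha[::-1] + log_switch
        alpha = np.logaddexp(stay, switch) + logem[i]
    return float(np.logaddexp(alpha[0], alpha[1]))


# ---------------------------------------------------------------------------
# Maximum-likelihood beta


def maximize_beta(
    gene_reads: Sequence[Fragment],
    rho: float = 0.5,
    gene_id: str = "",
    config: Optional[DaseConfig] = None,
) -> DHEEstimate:
    """Maximum-likelihood expression bias of a gene from its restricted reads.

    log f(beta) has a unique local maximum on [0.5, 1]; Newton-Raphson on its
    derivative starts from the moment estimate M/(m+M) and is safeguarded by
    the bracket, with a bounded scalar search as fallback.  A uniform prior
    on beta makes the posterior mode equal the likelihood mode.
    """
    if not gene_reads:
        raise ValueError("maximize_beta requires at least one read")
    config = config or DaseConfig()
    counts = compute_allele_counts(gene_reads)
    m, M = counts.minority_total, counts.majority_total
    n = m + M

    def negll(b: float) -> float:
        return -forward_log_likelihood(gene_reads, b, rho)

    lo, hi = 0.5, 1.0
    beta0 = min(max(M / n if n else 0.5, lo + 1e-6), hi - 1e-6)

    beta_star = _newton_on_gradient(negll, beta0, lo, hi)
    if beta_star is None:
        res = optimize.minimize_scalar(
            negll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        beta_star = float(res.x)
    # admit boundary maxima
    candidates = [beta_star, lo, hi]
    beta_star = min(candidates, key=negll)
    if negll(lo) <= negll(beta_star):
        beta_star = 0.5
    loglik = -negll(beta_star)

    pval = nonuniform_expression_test(counts, normal_cutoff=config.normal_approx_cutoff)
    eps_bar = float(np.mean([e for f in gene_reads for e in f.errors.values()]))
    gamma0 = beta_star * (1 - eps_bar) + (1 - beta_star) * eps_bar
    eligible = (
        len(gene_reads) >= config.min_gene_reads
        and pval <= config.alpha_nonuniform
        and beta_star > 0.5
    )
    return DHEEstimate(
        gene_id=gene_id,
        beta=beta_star,
        log_likelihood=loglik,
        nonuniform_pvalue=pval,
        eligible=eligible,
        gamma0=gamma0,
        gamma1=1.0 - gamma0,
        n_reads=len(gene_reads),
    )


def _newton_on_gradient(
    negll, x0: float, lo: float, hi: float,
    tol: float = 1e-10, max_iter: int = 50, h: float = 1e-5,
) -> Optional[float]:
    """Newton-Raphson on d(negll)/dx with finite differences; None on failure."""
    x = x0
    for _ in range(max_iter):
        xl, xr = max(x - h, lo), min(x + h, hi)
        g = (negll(xr) - negll(xl)) / (xr - xl)
        g2 = (negll(xr) - 2 * negll(x) + negll(xl)) / ((h) ** 2)
        if not math.isfinite(g) or not math.isfinite(g2) or g2 <= 0:
            return None
        step = g / g2
        x_new = x - step
        if x_new <= lo or x_new >= hi:
            x_new = min(max(x_new, lo + 1e-9), hi - 1e-9)
        if abs(x_new - x) < tol:
            return x_new
        x = x_new
    return None


# ---------------------------------------------------------------------------
# Concordance and non-uniformity screens


def concordance_probability(c0: int, c1: int, estimate: DHEEstimate) -> float:
    """Posterior that the majority allele lies on the higher-expressed
    haplotype: 1 / (1 + (gamma1/gamma0)^|c0-c1|)."""
    gap = abs(c0 - c1)
    if estimate.gamma0 == estimate.gamma1:
        return 0.5
    ratio = estimate.gamma1 / estimate.gamma0
    return 1.0 / (1.0 + ratio ** gap)


def concordance_probability_by_coverage(
    n_reads: int,
    estimate: DHEEstimate,
    normal_cutoff: int = 1000,
) -> Tuple[float, float]:
    """Probability of concordant expression at a SNP with N covering reads,
    plus its Chernoff lower bound.

    Exact value: the binomial majority tail sum_{i=ceil((N+1)/2)}^{N}
    C(N,i) gamma0^i gamma1^(N-i); a normal approximation replaces the sum
    above ``normal_cutoff``.  The bound 1 - exp(-N (gamma0 - 1/2)^2 /
    (2 gamma0)) follows from the multiplicative Chernoff inequality with
    mean N*gamma0.
    """
    if n_reads == 0:
        return 0.5, 0.0
    g0 = estimate.gamma0
    k = math.ceil((n_reads + 1) / 2)
    if n_reads <= normal_cutoff:
        prob = float(stats.binom.sf(k - 1, n_reads, g0))
    else:
        mu = n_reads * g0
        sd = math.sqrt(n_reads * g0 * (1 - g0))
        prob = float(stats.norm.sf(k - 0.5, mu, sd))
    chernoff = 1.0 - math.exp(-n_reads * (g0 - 0.5) ** 2 / (2.0 * g0))
    return prob, chernoff


def binomial_balance_pvalue(m: int, M: int, normal_cutoff: int = 1000) -> float:
    """Two-sided fair-coin tail bound: P[X <= m] + P[X >= M], X ~ B(m+M, 1/2)."""
    n = m + M
    if n == 0:
        return 1.0
    if n <= normal_cutoff:
        p = float(stats.binom.cdf(m, n, 0.5) + stats.binom.sf(M - 1, n, 0.5))
    else:
        mu, sd = n / 2.0, math.sqrt(n) / 2.0
        # continuity-corrected normal tails
        p = float(stats.norm.cdf(m + 0.5, mu, sd) + stats.norm.sf(M - 0.5, mu, sd))
    return min(p, 1.0)


def nonuniform_expression_test(
    counts: AlleleCounts,
    scope: str = "gene",
    snp: Optional[int] = None,
    normal_cutoff: int = 1000,
) -> float:
    """Upper bound on the probability of the observed allelic imbalance under
    balanced expression (beta = 0.5).

    Gene scope pools m = sum_s min(c0, c1) and M = sum_s max(c0, c1); SNP
    scope uses the single SNP's counts.  Returns the two-sided binomial tail,
    capped at 1.
    """
    if scope == "gene":
        m, M = counts.minority_total, counts.majority_total
    elif scope == "snp":
        if snp is None:
            raise ValueError("snp scope requires a SNP index")
        c0, c1 = counts.c0(snp), counts.c1(snp)
        m, M = min(c0, c1), max(c0, c1)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return binomial_balance_pvalue(m, M, normal_cutoff)


def concordant_solution(counts: AlleleCounts) -> Tuple[Dict[int, int], set]:
    """The majority-allele haplotype H+ and the set of tied SNPs.

    H0+ takes the majority allele at each SNP (ties -> allele 0, flagged);
    H1+ is the complement.  Under constant error < 0.5, uniform phase prior
    and size-1 reads, H+ maximizes the relative likelihood.
    """
    h0: Dict[int, int] = {}
    ties: set = set()
    for s in counts.snps():
        c0, c1 = counts.c0(s), counts.c1(s)
        if c0 == c1:
            ties.add(s)
            h0[s] = 0
        else:
            h0[s] = 0 if c0 > c1 else 1
    return h0, ties


# ---------------------------------------------------------------------------
# Gene-level analysis and read-bias assignment


@dataclass
class GeneAnalysis:
    gene: Gene
    estimate: DHEEstimate
    counts: AlleleCounts
    assessments: Dict[int, SNPAssessment]  # SNP index -> screen result


def analyze_gene(
    gene: Gene,
    gene_reads: Sequence[Fragment],
    config: DaseConfig,
    rng: np.random.Generator,
) -> Optional[GeneAnalysis]:
    """Full expression screen for one gene: restriction, beta MLE,
    non-uniformity test and per-SNP concordance assessment."""
    if not gene_reads or len(gene_reads) < config.min_gene_reads:
        return None
    restricted = restrict_reads(gene_reads, rng)
    counts = compute_allele_counts(restricted)
    estimate = maximize_beta(
        restricted, rho=config.rho, gene_id=gene.gene_id, config=config
    )
    _, ties = concordant_solution(counts)
    assessments: Dict[int, SNPAssessment] = {}
    for s in gene.snp_indices:
        c0, c1 = counts.c0(s), counts.c1(s)
        prob = concordance_probability(c0, c1, estimate)
        tied = s in ties or (c0 == 0 and c1 == 0)
        phaseable = (
            estimate.eligible and not tied and prob >= config.min_concordance
        )
        assessments[s] = SNPAssessment(prob_concordant=prob, phaseable=phaseable,
                                       tied=tied)
    return GeneAnalysis(gene=gene, estimate=estimate, counts=counts,
                        assessments=assessments)


def analyze_genes(
    genes: Sequence[Gene],
    fragments: Sequence[Fragment],
    config: DaseConfig,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, GeneAnalysis]:
    """Run the expression screen over every gene with tagged reads."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    by_gene: Dict[str, List[Fragment]] = {}
    for frag in fragments:
        if frag.gene_id is not None:
            by_gene.setdefault(frag.gene_id, []).append(frag)
    out: Dict[str, GeneAnalysis] = {}
    for gene in genes:
        reads = by_gene.get(gene.gene_id, [])
        result = analyze_gene(gene, reads, config, rng)
        if result is not None:
            out[gene.gene_id] = result
    return out


def assign_read_biases(
    fragments: Sequence[Fragment],
    analyses: Dict[str, GeneAnalysis],
    p_uniform: float = 0.5,
) -> ReadBiasAssignment:
    """Expected haplotype-origin bias per fragment.

    A fragment whose SNPs all lie in one eligible gene and are all phaseable
    gets b0 = p*0.5 + (1-p)*beta_hat (the uniform/differential mixture);
    every other fragment gets the uninformative (0.5, 0.5).
    """
    biases = ReadBiasAssignment()
    for frag in fragments:
        if frag.gene_id is None:
            continue
        analysis = analyses.get(frag.gene_id)
        if analysis is None or not analysis.estimate.eligible:
            continue
        if not all(
            s in analysis.assessments and analysis.assessments[s].phaseable
            for s in frag.alleles
        ):
            continue
        b0 = p_uniform * 0.5 + (1.0 - p_uniform) * analysis.estimate.beta
        biases.set(frag.id, b0)
    return biases


def diagnostics_table(analyses: Dict[str, GeneAnalysis]):
    """Per-gene diagnostic table (one row per analyzed gene)."""
    import pandas as pd

    rows = []
    for gid in sorted(analyses):
        a = analyses[gid]
        rows.append(
            {
                "gene_id": gid,
                "n_reads": a.estimate.n_reads,
                "beta": a.estimate.beta,
                "log_lik": a.estimate.log_likelihood,
                "pvalue": a.estimate.nonuniform_pvalue,
                "eligible": a.estimate.eligible,
                "n_phaseable_snps": sum(
                    1 for v in a.assessments.values() if v.phaseable
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_reads", "beta", "log_lik", "pvalue",
            "eligible", "n_phaseable_snps",
        ],
    )
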