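"""Independent straight-line reference implementations used as test oracles.

These deliberately avoid the package's HMM/beam code paths: likelihoods are
computed by explicit enumeration over all haplotypes and plain float
products, and graph components by union-find.
"""

import itertools
import math
from typing import Dict, List, Sequence, Tuple


def enumeration_likelihood(reads, beta: float, rho: float) -> float:
    """P[R' | beta, eps] by summing over all 2^n haplotypes.

    Each haplotype h0 gets prior 0.5 * rho^parallel * (1-rho)^switched
    (uniform initial state), and each size-1 read contributes the
    error-folded rate of the haplotype allele it matches.
    """
    snps = sorted({s for r in reads for s in r.alleles})
    total = 0.0
    for bits in itertools.product([0, 1], repeat=len(snps)):
        h0 = dict(zip(snps, bits))
        prior = 0.5
        for a, b in zip(bits, bits[1:]):
            prior *= rho if a == b else (1.0 - rho)
        like = 1.0
        for r in reads:
            ((s, a),) = r.alleles.items()
            eps = r.errors[s]
            g_hi = beta * (1 - eps) + (1 - beta) * eps
            g_lo = (1 - beta) * (1 - eps) + beta * eps
            like *= g_hi if h0[s] == a else g_lo
        total += prior * like
    return total


def straightline_log_rl(
    h0: Sequence[int],
    snp_indices: Sequence[int],
    fragments,
    biases,
    rho: float,
) -> float:
    """log RL(H) evaluated term by term with plain products."""
    assignment = dict(zip(snp_indices, h0))
    parallel = sum(1 for a, b in zip(h0, h0[1:]) if a == b)
    switched = len(h0) - 1 - parallel
    log_rl = parallel * math.log(rho) + switched * math.log(1.0 - rho)
    for frag in fragments:
        b0, b1 = biases.get(frag)
        p0 = p1 = 1.0
        for s, a in frag.alleles.items():
            eps = frag.errors[s]
            if assignment[s] == a:
                p0 *= 1.0 - eps
                p1 *= eps
            else:
                p0 *= eps
                p1 *= 1.0 - eps
        log_rl += math.log(b0 * p0 + b1 * p1)
    return log_rl


def exhaustive_best_phases(
    snp_indices: Sequence[int], fragments, biases, rho: float
) -> Tuple[float, List[Tuple[int, ...]]]:
    """Global max of log RL and all argmax phases, by full enumeration."""
    best = -math.inf
    argmax: List[Tuple[int, ...]] = []
    for bits in itertools.product([0, 1], repeat=len(snp_indices)):
        v = straightline_log_rl(bits, snp_indices, fragments, biases, rho)
        if v > best + 1e-12:
            best, argmax = v, [bits]
        elif abs(v - best) <= 1e-12:
            argmax.append(bits)
    return best, argmax


def union_find_components(edges, nodes) -> List[frozenset]:
    parent: Dict = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: Dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted((frozenset(g) for g in groups.values()), key=lambda g: sorted(g)[0])
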