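import numpy as np
import pytest

from dasephase.model import DHEEstimate, Fragment
from dasephase.simulate import SimulationConfig, simulate_scene

# The in-paper five-SNP toy gene: per-SNP reference/mutant allele counts
# observed at expression bias 0.9, and the haplotype pair they imply.
TOY_REF_COUNTS = [12, 15, 79, 97, 11]
TOY_MUT_COUNTS = [92, 85, 7, 4, 84]
TOY_PAIR = ((0, 0, 1, 1, 0), (1, 1, 0, 0, 1))


def make_read(rid, s, allele, eps=0.01, chrom="chr1", gene=None):
    return Fragment(rid, chrom, {s: allele}, {s: eps}, gene_id=gene)


def reads_from_counts(counts_per_snp, eps=0.01, gene=None):
    """counts_per_snp: list of (c0, c1) per SNP index -> size-1 read list."""
    reads = []
    k = 0
    for s, (c0, c1) in enumerate(counts_per_snp):
        for _ in range(c0):
            reads.append(make_read(f"r{k}", s, 0, eps, gene=gene))
            k += 1
        for _ in range(c1):
            reads.append(make_read(f"r{k}", s, 1, eps, gene=gene))
            k += 1
    return reads


def toy_gene_reads(eps=0.01, gene="TOY"):
    return reads_from_counts(
        list(zip(TOY_REF_COUNTS, TOY_MUT_COUNTS)), eps=eps, gene=gene
    )


def random_restricted_reads(rng, n_snps, n_reads, eps_range=(1e-4, 0.4)):
    reads = []
    for i in range(n_reads):
        s = int(rng.integers(n_snps))
        reads.append(
            Fragment(
                f"r{i}",
                "chr1",
                {s: int(rng.integers(2))},
                {s: float(rng.uniform(*eps_range))},
            )
        )
    return reads


def estimate_from(beta, eps=0.0, gene_id="g"):
    g0 = beta * (1 - eps) + (1 - beta) * eps
    return DHEEstimate(
        gene_id=gene_id,
        beta=beta,
        log_likelihood=0.0,
        nonuniform_pvalue=0.0,
        eligible=True,
        gamma0=g0,
        gamma1=1 - g0,
    )


@pytest.fixture(scope="session")
def default_scene():
    return simulate_scene(SimulationConfig(n_genes=5, seed=7))


@pytest.fixture(scope="session")
def scene_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("scene")
    scene = simulate_scene(
        SimulationConfig(n_genes=5, seed=7, barcode_rate=0.2),
        out_dir=str(out),
        write_sam=True,
    )
    return scene
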