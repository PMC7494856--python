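# dasephase

Diploid haplotype phasing from sequencing reads that combines two lines of
evidence in one maximum-likelihood framework:

* **read contiguity** — fragments (single reads, read pairs, spliced RNA-seq
  reads, barcode groups) that cover two or more heterozygous SNPs link those
  SNPs directly;
* **differential allele-specific expression (DASE)** — in RNA-seq, a gene
  transcribed unevenly from its two haplotypes over-represents, at *every*
  heterozygous SNP it contains, the allele on the higher-expressed copy.
  This links SNPs that no read pair connects, and makes reads covering a
  single SNP informative for phasing — reads every purely contiguity-based
  phaser throws away.

It is aimed at anyone phasing an individual's heterozygous variants from
RNA-seq (alone or jointly with DNA/exome or barcoded libraries): the inputs
are a coordinate-sorted SAM/BAM, a genotype VCF, and a gene annotation, and
the output is phased haplotype blocks (HapCUT-style text and/or a PS-tagged
phased VCF).

## Model

Write the two haplotypes over the heterozygous SNPs as complementary binary
sequences H = (H₀, H₁) (0 = reference allele, 1 = alternative). A read r
observes alleles at the SNPs it covers, with probability ε_{r,s} of opposite
allele information at locus s. If β_i^r is the probability that r was
sampled from haplotype H_i, the likelihood of a candidate phase is scored by
the relative likelihood

    RL(H) = P(H) · ∏_r Σ_{i∈{0,1}} β_i^r ∏_{s∈A(r,H_i)} (1−ε_{r,s}) ∏_{s∈D(r,H_i)} ε_{r,s}

where A/D are the loci where r agrees/disagrees with H_i and the prior
P(H) = ρ^P(H) (1−ρ)^S(H) counts parallel vs switched adjacent SNP pairs
(ρ = 0.5 gives the uniform prior). For genomic reads β₀^r = β₁^r = 0.5 and
single-SNP reads cancel out; for reads of a differentially expressed gene
the bias breaks the symmetry.

The per-gene expression bias β (probability a read comes from the
higher-expressed haplotype, β ∈ [0.5, 1]) is unknown and is estimated by
maximum likelihood: each multi-SNP read is restricted to one uniformly
chosen SNP so per-SNP observations are independent, and the likelihood
f(β) = P[R′ | β, ε] is computed exactly by a two-state HMM over phase
orientations (emissions fold the error into γ_i = β_i(1−ε) + (1−β_i)ε,
transitions stay/switch with ρ / 1−ρ), maximized by safeguarded
Newton-Raphson. Genes must pass a two-sided binomial test against uniform
expression (β = 0.5), and each SNP must clear a concordance screen

    P[concordant] = 1 / (1 + (γ₁/γ₀)^{|C_s⁰ − C_s¹|}) ≥ 0.99

before its majority allele is trusted to sit on the higher-expressed
haplotype. Blocks — connected components of the joint read graph
(contiguity edges plus within-gene cliques over screened SNPs) — are then
phased by exhaustive enumeration (small blocks) or a branch-and-prune beam
search over RL.

## Worked example

The five-SNP toy gene with per-SNP reference/mutant read counts
(12/92, 15/85, 79/7, 97/4, 11/84) — roughly 100 reads per SNP drawn at
expression bias β = 0.9:

```python
import numpy as np
from dasephase import (DaseConfig, Fragment, Gene, HetSNP, SNPPanel,
                       analyze_genes, assign_read_biases, phase_all)

ref_counts, mut_counts = [12, 15, 79, 97, 11], [92, 85, 7, 4, 84]
reads, k = [], 0
for s, (c0, c1) in enumerate(zip(ref_counts, mut_counts)):
    for allele, count in ((0, c0), (1, c1)):
        for _ in range(count):
            reads.append(Fragment(f"r{k}", "chr1", {s: allele}, {s: 0.01},
                                  gene_id="TOY"))
            k += 1

panel = SNPPanel(HetSNP("chr1", 100 + 100 * i, "A", "C", i) for i in range(5))
gene = Gene("TOY", "chr1", [(0, 1000)], [0, 1, 2, 3, 4])
analyses = analyze_genes([gene], reads, DaseConfig(p_uniform=0.0))
est = analyses["TOY"].estimate
print(f"beta_hat = {est.beta:.3f}  p_uniform_expression = {est.nonuniform_pvalue:.2e}")

biases = assign_read_biases(reads, analyses, p_uniform=0.0)
(block,) = phase_all(panel, reads, [gene], analyses, biases)
print("h0 =", "".join(map(str, block.h0)), " h1 =", "".join(map(str, block.h1)))
```

prints

```
beta_hat = 0.907  p_uniform_expression = 6.69e-79
h0 = 11001  h1 = 00110
```

i.e. the estimated bias recovers the generating β = 0.9, uniform expression
is decisively rejected, and the inferred haplotype pair groups every
majority allele on the higher-expressed haplotype (h0) — a full-gene block
built entirely from single-SNP reads.

The same pipeline runs from the shell; on a simulated 6-gene scene:

```bash
dasephase simulate --out-dir scene --n-genes 6 --seed 11 --sam
dasephase phase --vcf scene/scene.vcf --bam scene/scene.sam \
    --gff scene/scene.gtf --out scene/blocks.txt --truth scene/scene.truth.txt
# phased 34 SNPs in 6 blocks
# SNPs phased: 34; switch errors: 0/28 pairs (0.00%); span: 11.6 kb
```

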