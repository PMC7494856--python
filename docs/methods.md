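# Methods

## The phasing model

`dasephase` reconstructs the two haplotypes of a diploid individual over its
biallelic heterozygous SNPs. A phase is a pair of complementary binary
sequences H = (H₀, H₁); every read r is a sparse vector over the SNP panel
with r[s] ∈ {0, 1, −} (− means the read does not cover s, or carries a base
matching neither genotyped allele) and a per-locus opposite-allele
probability ε_{r,s}. Reads are assumed independently sampled, uniquely and
correctly mapped, with independent errors; multi-mapping must be resolved
upstream.

Candidate phases are compared by relative likelihood,

    log RL(H) = log P(H) + Σ_r log Σ_{i∈{0,1}} β_i^r
                ∏_{s∈A(r,H_i)} (1−ε_{r,s}) ∏_{s∈D(r,H_i)} ε_{r,s},

with A/D the loci where r agrees/disagrees with haplotype i and
(β₀^r, β₁^r) the read's haplotype-origin probabilities. The phase prior
P(H) = ρ^P (1−ρ)^S counts adjacent SNP pairs phased in parallel (P) vs
switched (S); ρ is the parallel-bias parameter, default 0.5 (uniform prior —
no non-uniform value is used anywhere by default). Note the prior is
complement-invariant and normalizes over unordered pairs {h₀, ~h₀}; the HMM
below adds the uniform ½ initial-state factor so likelihoods integrate to
one over orientations.

For genomic (DNA/exome) reads β₀^r = β₁^r = 0.5, the mixture is symmetric,
and single-SNP reads contribute a constant factor — only contiguity
information matters. The contribution of allelic imbalance enters through
non-trivial β^r for RNA-seq reads of differentially expressed genes.

## Estimating differential haplotypic expression (DHE)

For each annotated gene g the expression bias β = P[read from the
higher-expressed haplotype] ∈ [0.5, 1] is estimated from the gene's reads:

1. **Restriction.** Each read covering more than one SNP of g is restricted
   to one uniformly chosen covered SNP, giving R′_g in which per-SNP read
   sets are independent. Restriction happens once per run with the global
   seed; no averaging over restrictions is performed, and R′ is used *only*
   for β estimation — the phase search always uses the full fragments.
2. **Likelihood.** f(β) = P[R′_g | β, ε] is computed exactly by a two-state
   HMM: hidden state at SNP s is which allele sits on the higher-expressed
   haplotype; emission of a read observing that allele is
   γ = β(1−ε_r) + (1−β)ε_r (else 1−γ); transitions stay with ρ and switch
   with 1−ρ; initial distribution uniform. The forward recursion is carried
   in log space and is linear in SNPs and reads. It agrees with brute-force
   enumeration over all 2^|S_g| haplotypes to ~1e−15 relative error (tested
   exhaustively up to 10 SNPs).
3. **Maximization.** f has a single interior maximum on [0.5, 1].
   Newton-Raphson runs on d(log f)/dβ with central finite differences
   (h = 1e−5; the forward recursion has no convenient analytic derivative),
   initialized at the moment estimate M/(m+M); if it leaves the bracket or
   fails to converge in 50 iterations, bounded Brent minimization on
   [0.5, 1] takes over. Boundary maxima at 0.5 and 1 are admitted
   explicitly. The returned optimum matches a 1e−4 grid search within 1e−8
   in log-likelihood.

With 500 restricted reads per gene and 1% base error, the estimator's mean
absolute error is ≈0.015 and |β̂ − β| ≤ 0.05 in ≈98% of replicates (for
β ∈ {0.6, …, 0.9}); accuracy improves monotonically with coverage.

## Screening: which SNPs can imbalance phase?

Expression evidence is only trusted where it is strong enough to orient
alleles:

* **Expressed-gene screen.** A gene enters estimation with at least
  `min_gene_reads` (default 10) restricted reads. The annotation gives no
  expression cutoff, so a read-count floor stands in for one.
* **Non-uniformity test.** Pooling m = Σ_s min(C_s⁰, C_s¹) and
  M = Σ_s max(C_s⁰, C_s¹), the two-sided fair-coin tail
  P[X ≤ m] + P[X ≥ M], X ~ B(m+M, ½), must be ≤ `alpha_nonuniform`
  (default 0.01). **Known property:** because the pooled statistic takes the
  per-SNP majority before summing, it is an upper-bound screen, not a
  calibrated test — under truly uniform expression a many-SNP gene is
  rejected more often than α (≈8% measured at α = 1% for 5 SNPs × 20
  reads). At the single-binomial level the exact tail is conservative
  (measured type-I ≈0.7% at α = 1%). Downstream, the per-SNP concordance
  screen limits the damage of a false-positive gene.
* **Concordance screen.** At each SNP the posterior that the observed
  majority allele lies on the higher-expressed haplotype is
  1/(1 + (γ₁/γ₀)^{|C⁰−C¹|}) with γ_i = β_i(1−ε̄) + (1−β_i)ε̄; it must reach
  `min_concordance` (default 0.99). Ties (C⁰ = C¹) are never phaseable by
  imbalance alone. The gene's representative error rate ε̄ is the mean ε
  over its restricted reads, preserving the closed forms that per-read
  errors would break. The coverage-level form of this probability — the
  binomial majority tail Σ_{i≥⌈(N+1)/2⌉} C(N,i) γ₀^i γ₁^{N−i} — is bounded
  below by 1 − exp(−N(γ₀−½)²/(2γ₀)) (multiplicative Chernoff with mean
  Nγ₀; verified numerically over N ≤ 10⁴), so confidence grows
  exponentially with coverage.

A 0.99 concordance threshold admits up to ~1% discordant SNPs by
construction: on deep-coverage simulations the pipeline usually reaches 0
switch errors, but single switches inside borderline genes are possible and
expected at that rate.

Reads whose covered SNPs all lie in one eligible gene and are all phaseable
receive the mixture bias b₀ = p·0.5 + (1−p)·β̂, where `p_uniform`
(default 0.5) is the prior that the gene is in truth uniformly expressed;
all other reads stay at (0.5, 0.5). A fragment spanning two genes keeps its
contiguity evidence but gets no bias (distinct genes have independent
biases), as does a fragment ambiguous between overlapping genes.

## Block construction and search

Blocks are connected components of the joint read graph: vertices are SNPs,
edges join SNPs co-covered by a fragment, plus a connectivity path over each
eligible gene's phaseable SNPs. Expression evidence never links two
distinct genes. Components with fewer than two SNPs are suppressed (a
one-SNP phase is vacuous).

Within a block, SNPs are processed in genomic order. Blocks of at most
`exhaustive_cutoff` = 12 SNPs are solved by vectorized enumeration of all
2^n assignments; larger blocks by a branch-and-prune beam search that
extends every candidate prefix with 0 and 1, scores incrementally (each
candidate keeps, per touched fragment, the running agreement log-products
with h₀ and with its complement, so the mixture is always evaluated on
complete information so far), prunes candidates below best ×
`prune_ratio` (= 0.01) and caps the beam at `beam_width` (= 128). On
randomized blocks of ≤ 12 SNPs the beam attains the enumeration optimum in
100% of tested instances; the defaults were chosen to keep that equivalence
testable rather than tuned for speed.

Orientation: with any expression-biased fragment in the block, the search
itself orients h₀ as the higher-expressed haplotype (the mixture is
asymmetric). Without bias and with ρ = 0.5 the two orientations tie and the
block is canonicalized to h₀ starting with allele 0.

Determinism: given the seed and inputs, output is byte-identical across
runs; blocks are independent, so any parallel schedule must (and trivially
does, since execution is sequential) reproduce the sequential output.

## Evaluation

The switch-error rate is the percentage, pooled over blocks, of consecutive
assessable SNP pairs (both SNPs present in the truth) whose predicted
relative orientation (parallel vs switched) disagrees with the truth — the
minimal-switch reading of "positions where the two chromosomes must be
switched". It is invariant to complementing any block. Truth SNPs absent
from the prediction are skipped, not penalized; completeness is reported
separately as SNPs phased and total block span (Σ last−first position, in
kb). With no assessable pair the rate is reported as NaN with zero
denominators.

## The synthetic-data generator

`simulate_scene` draws scenes with exactly the structure the model assumes:
non-overlapping genes laid along one chromosome (2–4 exons of 200–400 bp,
introns 0.5–2 kb, intergenic gaps 5–10 kb), 4–8 heterozygous SNPs per gene
placed uniformly in exons, a uniform random truth haplotype, per-gene β
cycled through {0.5, 0.6, 0.7, 0.8, 0.9} (so balanced and strongly biased
genes are always represented; which truth haplotype is over-expressed is
random), mean per-SNP coverage 100, and reads covering contiguous runs of a
gene's SNPs with size distribution {1: 0.6, 2: 0.3, 3: 0.1} — mostly
single-SNP fragments, as in real RNA-seq over het SNPs. Each read samples
the over-expressed haplotype with probability β and flips each reported
allele with probability ε (default 0.01) — the opposite-allele error model,
quantized through the Phred scale so SAM emission round-trips exactly.
Optional extras: barcode grouping within genes, cross-gene linking reads
(untagged, to exercise the no-cross-gene-bias rule), SAM/BAM output with
spliced CIGARs (1M per SNP base, N-gaps between).

What it deliberately does not emulate: isoform mixtures (multi-transcript
DASE), GC/positional coverage bias, non-uniform error profiles, overlapping
genes, indels or multiallelic sites, and mapping artefacts. Passing tests
therefore demonstrate correctness of the inference given the model's
assumptions, not robustness to real-data violations of them.

## Numerical choices and degenerate inputs

* All likelihoods in log space; two-branch mixtures via `logaddexp`.
* ε from base quality as 10^(−Q/10), clamped to [1e−6, 0.49] so ε stays in
  (0, 0.5); error-free simulation uses Q = 60.
* Binomial tails are exact below `normal_approx_cutoff` = 1000 total reads
  and continuity-corrected normal beyond (agreement ≤ 1e−3 absolute at
  N = 1000).
* Mate conflicts at a shared SNP drop the locus (configurable to drop the
  fragment); barcode-group conflicts resolve by majority, ties drop the
  locus; the best (lowest-ε) observation is kept for duplicated loci.
* Zero reads: balance test returns p = 1, concordance-by-coverage returns
  0.5, empty blocks are unphased.
* Ties in the majority solution assign allele 0 and mark the SNP
  non-phaseable by imbalance alone (its concordance probability is exactly
  0.5).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `rho` | 0.5 | parallel-bias phase prior (0.5 = uniform) |
| `p_uniform` | 0.5 | prior that a gene is uniformly expressed |
| `alpha_nonuniform` | 0.01 | balance-test level for gene eligibility |
| `min_concordance` | 0.99 | per-SNP concordance threshold |
| `min_gene_reads` | 10 | expressed-gene read floor |
| `normal_approx_cutoff` | 1000 | exact vs normal binomial tails |
| `beam_width` / `prune_ratio` | 128 / 0.01 | beam search controls |
| `exhaustive_cutoff` | 12 | enumeration limit (SNPs per block) |
| `min_mapq` / `min_baseq` | 20 / 10 | alignment extraction filters |
| `seed` | 42 | global randomness (restriction, simulation) |

Extraction also skips duplicates, secondary and supplementary alignments;
these filters are conventional defaults, not values taken from any dataset.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` size their computations to run
comfortably on one CPU: 200 random instances (≤ 10 SNPs, ≤ 30 reads) for
HMM-vs-enumeration, 500 blocks (≤ 8 SNPs) for majority-solution optimality,
300 mixed-evidence blocks (≤ 12 SNPs) for beam-vs-enumeration, 100
replicates × 4 bias levels × 500 reads for estimator recovery, 10⁴
replicates for test calibration, and 20-gene scenes at coverage 100 for the
end-to-end runs. β is never re-estimated after phasing (no EM); the
estimate from the single restricted read set is final.

## Known limitations

* Diploid only; no polyploid search, no population/reference-panel priors.
* One β per gene: multi-isoform allele-specific expression is out of scope.
* The pooled non-uniformity screen is liberal for many-SNP genes (see
  above); the concordance screen, not the gene test, is the accuracy
  gatekeeper.
* ε is taken from base qualities (or the simulator), never re-estimated
  from data.
* CRAM input, realignment and genotype calling are out of scope; the VCF is
  trusted as the genotype truth.
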