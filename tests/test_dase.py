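"""Expression-bias estimation: restriction, HMM likelihood, MLE, screens."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dasephase import dase
from dasephase.model import AlleleCounts, Fragment

from .conftest import (
    TOY_MUT_COUNTS,
    TOY_PAIR,
    TOY_REF_COUNTS,
    estimate_from,
    make_read,
    random_restricted_reads,
    reads_from_counts,
)
from .oracles import enumeration_likelihood, straightline_log_rl


class TestRestrictReads:
    def test_size_one_reads_pass_through(self):
        r = make_read("a", 3, 1)
        rng = np.random.default_rng(0)
        assert dase.restrict_reads([r], rng) == [r]

    def test_fixed_seed_is_deterministic(self):
        frags = [
            Fragment("a", "chr1", {0: 0, 1: 1, 2: 0},
                     {0: 0.01, 1: 0.01, 2: 0.01})
            for _ in range(20)
        ]
        out1 = dase.restrict_reads(frags, np.random.default_rng(9))
        out2 = dase.restrict_reads(frags, np.random.default_rng(9))
        assert [f.alleles for f in out1] == [f.alleles for f in out2]
        assert all(f.size == 1 for f in out1)

    def test_restriction_is_uniform_over_covered_snps(self):
        frag = Fragment("a", "chr1", {0: 0, 1: 1, 2: 0},
                        {0: 0.01, 1: 0.01, 2: 0.01})
        rng = np.random.default_rng(1)
        chosen = [
            next(iter(dase.restrict_reads([frag], rng)[0].alleles))
            for _ in range(10000)
        ]
        for s in (0, 1, 2):
            assert chosen.count(s) / 10000 == pytest.approx(1 / 3, abs=0.02)


class TestAlleleCounts:
    def test_simple_tally(self):
        reads = [make_read("a", 0, 0), make_read("b", 0, 0), make_read("c", 0, 1)]
        counts = dase.compute_allele_counts(reads)
        assert (counts.c0(0), counts.c1(0)) == (2, 1)

    def test_empty_reads_give_zero_counts(self):
        counts = dase.compute_allele_counts([])
        assert counts.counts == {} and counts.n_reads == 0

    def test_multi_snp_read_is_contract_violation(self):
        frag = Fragment("a", "chr1", {0: 0, 1: 1}, {0: 0.01, 1: 0.01})
        with pytest.raises(ValueError):
            dase.compute_allele_counts([frag])

    def test_simulator_tally_matches_emission_log(self, default_scene):
        size1 = [f for f in default_scene.fragments if f.size == 1]
        counts = dase.compute_allele_counts(size1)
        expected = {}
        for f in size1:
            ((s, a),) = f.alleles.items()
            expected.setdefault(s, [0, 0])[a] += 1
        assert counts.counts == {s: tuple(v) for s, v in expected.items()}


class TestForwardLikelihood:
    def test_single_read_is_uninformative(self):
        r = make_read("a", 0, 0, eps=1e-6)
        for beta in (0.5, 0.7, 0.95):
            assert math.exp(dase.forward_log_likelihood([r], beta)) == (
                pytest.approx(0.5, abs=1e-5)
            )

    def test_two_agreeing_reads_closed_form(self):
        reads = [make_read("a", 0, 0, eps=1e-9), make_read("b", 0, 0, eps=1e-9)]
        beta = 0.9
        expected = 0.5 * beta**2 + 0.5 * (1 - beta) ** 2  # = 0.41
        assert math.exp(dase.forward_log_likelihood(reads, beta)) == (
            pytest.approx(expected, rel=1e-6)
        )
        assert expected == pytest.approx(0.41)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n_snps = int(rng.integers(1, 11))
            reads = random_restricted_reads(rng, n_snps, int(rng.integers(1, 25)))
            beta = float(rng.uniform(0.5, 1.0))
            rho = float(rng.uniform(0.5, 0.95))
            got = math.exp(dase.forward_log_likelihood(reads, beta, rho))
            want = enumeration_likelihood(reads, beta, rho)
            assert got == pytest.approx(want, rel=1e-10)

    def test_rejects_beta_outside_domain(self):
        r = make_read("a", 0, 0)
        with pytest.raises(ValueError):
            dase.forward_log_likelihood([r], 0.4)
        with pytest.raises(ValueError):
            dase.forward_log_likelihood([r], 1.1)


class TestMaximizeBeta:
    def test_balanced_counts_give_half(self):
        reads = reads_from_counts([(25, 25), (25, 25)], eps=1e-6)
        est = dase.maximize_beta(reads)
        assert est.beta == pytest.approx(0.5, abs=1e-6)

    def test_90_10_counts_match_dense_grid_search(self):
        reads = reads_from_counts([(90, 10)], eps=1e-6)
        est = dase.maximize_beta(reads)
        grid = np.linspace(0.5, 1.0, 5001)
        lls = [dase.forward_log_likelihood(reads, b) for b in grid]
        assert est.log_likelihood >= max(lls) - 1e-8
        assert est.beta == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_mle_beats_grid_on_random_instances(self):
        rng = np.random.default_rng(21)
        grid = np.linspace(0.5, 1.0, 501)
        for _ in range(10):
            reads = random_restricted_reads(
                rng, int(rng.integers(1, 6)), int(rng.integers(5, 60)),
                eps_range=(1e-3, 0.2),
            )
            est = dase.maximize_beta(reads, rho=0.5)
            best_grid = max(dase.forward_log_likelihood(reads, b) for b in grid)
            assert est.log_likelihood >= best_grid - 1e-8

    @pytest.mark.parametrize("true_beta", [0.7, 0.9])
    def test_recovery_error_shrinks_with_coverage(self, true_beta):
        errors = {}
        for n_reads in (20, 100, 500):
            rng = np.random.default_rng(1000 + n_reads)
            errs = []
            for _ in range(40):
                c1 = rng.binomial(n_reads, true_beta)
                reads = reads_from_counts([(n_reads - c1, c1)], eps=0.01)
                est = dase.maximize_beta(reads)
                errs.append(abs(est.beta - true_beta))
            errors[n_reads] = float(np.mean(errs))
        assert errors[20] > errors[100] > errors[500]

    def test_gamma_rates_are_complementary(self):
        reads = reads_from_counts([(80, 20)], eps=0.01)
        est = dase.maximize_beta(reads)
        assert est.gamma0 + est.gamma1 == pytest.approx(1.0)
        assert est.gamma0 == pytest.approx(
            est.beta * 0.99 + (1 - est.beta) * 0.01
        )


class TestConcordance:
    def test_equal_counts_are_uninformative(self):
        est = estimate_from(0.9)
        assert dase.concordance_probability(10, 10, est) == 0.5

    def test_closed_form_ratio_one_ninth_gap_two(self):
        est = estimate_from(0.9, eps=0.0)  # gamma0/gamma1 = 9
        assert dase.concordance_probability(6, 4, est) == pytest.approx(81 / 82)
        assert dase.concordance_probability(6, 4, est) == pytest.approx(
            0.98780, abs=1e-5
        )

    def test_degenerate_gamma_returns_half(self):
        est = estimate_from(0.5)
        assert dase.concordance_probability(7, 3, est) == 0.5

    def test_matches_two_hypothesis_posterior(self):
        # posterior of concordant vs discordant orientation from the
        # per-orientation likelihoods gamma0^c_maj * gamma1^c_min
        rng = np.random.default_rng(5)
        for _ in range(50):
            beta = float(rng.uniform(0.55, 0.99))
            eps = float(rng.uniform(0.0, 0.1))
            c0, c1 = int(rng.integers(0, 40)), int(rng.integers(0, 40))
            est = estimate_from(beta, eps)
            g0, g1 = est.gamma0, est.gamma1
            hi, lo = max(c0, c1), min(c0, c1)
            l_conc = g0**hi * g1**lo
            l_disc = g0**lo * g1**hi
            want = l_conc / (l_conc + l_disc)
            assert dase.concordance_probability(c0, c1, est) == (
                pytest.approx(want, rel=1e-12)
            )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        gap1=st.integers(0, 50),
        dgap=st.integers(0, 50),
        b1=st.floats(0.51, 0.99),
        db=st.floats(0.0, 0.2),
    )
    def test_monotone_in_gap_and_bias(self, gap1, dgap, b1, db):
        est1 = estimate_from(b1)
        p1 = dase.concordance_probability(gap1, 0, est1)
        assert dase.concordance_probability(gap1 + dgap, 0, est1) >= p1
        est2 = estimate_from(min(b1 + db, 0.999))
        assert dase.concordance_probability(gap1, 0, est2) >= p1 - 1e-12


class TestConcordanceByCoverage:
    def test_single_read_probability_is_gamma0(self):
        est = estimate_from(0.8, eps=0.02)
        prob, _ = dase.concordance_probability_by_coverage(1, est)
        assert prob == pytest.approx(est.gamma0)

    def test_unbiased_gene_gives_symmetric_binomial_tail(self):
        from scipy.stats import binom

        est = estimate_from(0.5)
        for n in (3, 10, 25):
            prob, _ = dase.concordance_probability_by_coverage(n, est)
            k = math.ceil((n + 1) / 2)
            want = sum(binom.pmf(i, n, 0.5) for i in range(k, n + 1))
            assert prob == pytest.approx(want, rel=1e-9)

    def test_zero_coverage_is_uninformative(self):
        prob, bound = dase.concordance_probability_by_coverage(0, estimate_from(0.9))
        assert prob == 0.5

    def test_exact_tail_dominates_chernoff_and_grows_with_coverage(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            beta = float(rng.uniform(0.55, 0.99))
            eps = float(rng.uniform(0.0, 0.05))
            est = estimate_from(beta, eps)
            prev = 0.0
            for n in (1, 5, 20, 100, 1000, 10000):
                prob, bound = dase.concordance_probability_by_coverage(n, est)
                assert prob >= bound - 1e-12
                if n > 1:
                    assert prob >= prev - 1e-9  # nondecreasing in N
                prev = prob


class TestNonuniformTest:
    def test_extreme_imbalance_single_term_tails(self):
        for n in (3, 10, 30):
            counts = AlleleCounts({0: (0, n)})
            assert dase.nonuniform_expression_test(counts) == (
                pytest.approx(2.0 ** (1 - n))
            )

    def test_perfect_balance_caps_at_one(self):
        counts = AlleleCounts({0: (7, 7)})
        assert dase.nonuniform_expression_test(counts) == 1.0

    def test_zero_reads_give_pvalue_one(self):
        assert dase.nonuniform_expression_test(AlleleCounts()) == 1.0

    def test_gene_scope_pools_minority_and_majority(self):
        counts = AlleleCounts({0: (3, 10), 1: (9, 2)})
        # m = 3 + 2, M = 10 + 9
        assert dase.nonuniform_expression_test(counts) == pytest.approx(
            dase.binomial_balance_pvalue(5, 19)
        )

    def test_snp_scope_uses_single_locus(self):
        counts = AlleleCounts({0: (3, 10), 1: (9, 2)})
        assert dase.nonuniform_expression_test(counts, scope="snp", snp=1) == (
            pytest.approx(dase.binomial_balance_pvalue(2, 9))
        )

    def test_normal_approximation_close_to_exact_at_n_1000(self):
        n = 1000
        for m in (400, 450, 470, 485, 500):
            exact = dase.binomial_balance_pvalue(m, n - m, normal_cutoff=10**9)
            approx = dase.binomial_balance_pvalue(m, n - m, normal_cutoff=10)
            assert approx == pytest.approx(exact, abs=1e-3)


class TestConcordantSolution:
    def test_majority_rule(self):
        counts = AlleleCounts({0: (10, 90), 1: (90, 10)})
        h0, ties = dase.concordant_solution(counts)
        assert h0 == {0: 1, 1: 0} and ties == set()

    def test_ties_take_reference_and_are_flagged(self):
        counts = AlleleCounts({0: (5, 5)})
        h0, ties = dase.concordant_solution(counts)
        assert h0 == {0: 0} and ties == {0}

    def test_toy_example_groups_majority_alleles(self):
        counts = AlleleCounts(
            {s: (r, m) for s, (r, m) in
             enumerate(zip(TOY_REF_COUNTS, TOY_MUT_COUNTS))}
        )
        h0, ties = dase.concordant_solution(counts)
        pair = (tuple(h0[s] for s in range(5)),
                tuple(1 - h0[s] for s in range(5)))
        assert set(pair) == set(TOY_PAIR)
        assert not ties

    def test_majority_solution_maximizes_relative_likelihood(self):
        # exhaustive check of the optimality guarantee: size-1 reads,
        # constant error, uniform phase prior
        import itertools

        from dasephase.model import ReadBiasAssignment

        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            counts = {s: (int(rng.integers(0, 12)), int(rng.integers(0, 12)))
                      for s in range(n)}
            eps = float(rng.uniform(0.01, 0.3))
            beta = float(rng.uniform(0.55, 0.95))
            reads = reads_from_counts([counts[s] for s in range(n)], eps=eps)
            biases = ReadBiasAssignment()
            for r in reads:
                biases.set(r.id, beta)
            h0, _ = dase.concordant_solution(AlleleCounts(counts))
            h_plus = tuple(h0[s] for s in range(n))
            rl_plus = straightline_log_rl(h_plus, range(n), reads, biases, 0.5)
            for bits in itertools.product([0, 1], repeat=n):
                rl = straightline_log_rl(bits, range(n), reads, biases, 0.5)
                assert rl <= rl_plus + 1e-9


class TestReadBiasAssignment:
    def _analysis(self, beta, eligible=True, phaseable=(0, 1)):
        from dasephase.dase import GeneAnalysis
        from dasephase.model import Gene, SNPAssessment

        est = estimate_from(beta, gene_id="g1")
        est.eligible = eligible
        return {
            "g1": GeneAnalysis(
                gene=Gene("g1", "chr1", [(0, 100)], [0, 1]),
                estimate=est,
                counts=AlleleCounts(),
                assessments={
                    s: SNPAssessment(0.999, phaseable=s in phaseable)
                    for s in (0, 1)
                },
            )
        }

    def test_pure_differential_prior_passes_beta_through(self):
        read = make_read("a", 0, 0, gene="g1")
        biases = dase.assign_read_biases([read], self._analysis(0.8), p_uniform=0.0)
        assert biases.get(read) == pytest.approx((0.8, 0.2))

    def test_pure_uniform_prior_neutralizes_all_reads(self):
        read = make_read("a", 0, 0, gene="g1")
        biases = dase.assign_read_biases([read], self._analysis(0.8), p_uniform=1.0)
        assert biases.get(read) == (0.5, 0.5)

    def test_mixture_prior_interpolates(self):
        read = make_read("a", 0, 0, gene="g1")
        biases = dase.assign_read_biases([read], self._analysis(0.9), p_uniform=0.5)
        assert biases.get(read) == pytest.approx((0.7, 0.3))

    def test_fragment_on_nonphaseable_snp_stays_unbiased(self):
        read = make_read("a", 1, 0, gene="g1")
        biases = dase.assign_read_biases(
            [read], self._analysis(0.8, phaseable=(0,)), p_uniform=0.0
        )
        assert biases.get(read) == (0.5, 0.5)

    def test_fragment_without_gene_stays_unbiased(self):
        read = make_read("a", 0, 0)
        biases = dase.assign_read_biases([read], self._analysis(0.8), p_uniform=0.0)
        assert biases.get(read) == (0.5, 0.5)

    def test_ineligible_gene_stays_unbiased(self):
        read = make_read("a", 0, 0, gene="g1")
        biases = dase.assign_read_biases(
            [read], self._analysis(0.8, eligible=False), p_uniform=0.0
        )
        assert biases.get(read) == (0.5, 0.5)
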