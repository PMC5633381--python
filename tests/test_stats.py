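"""Contingency tests, multiple-testing correction and rate comparisons."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from lohflux.stats import (
    ContingencyTable2x2,
    binomial_independence_test,
    fisher_exact_2x2,
    holm_bonferroni,
    independence_expected_rate,
    mann_whitney,
    pfge_chr2_fraction,
    round_to_sig,
    two_proportion_chisq,
    welch_t_test,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)

    def log_pmf(k):
        return (
            gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
            + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    log_probs = log_pmf(ks.astype(float))
    probs = np.exp(log_probs)
    observed = np.exp(log_pmf(float(a)))
    return float(probs[probs <= observed * (1 + 1e-9)].sum())


class TestFisherExact:
    def test_het_hom_comparison_between_mutants(self):
        """17/27 vs 22/22 heterozygous complex events differ (p ≈ 0.0011)."""
        result = fisher_exact_2x2(ContingencyTable2x2(17, 10, 22, 0))
        assert round(result.p_value, 4) == 0.0011

    def test_balanced_table_is_null(self):
        assert fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5)).p_value == 1.0

    def test_diagonal_table_small(self):
        result = fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 2))
        assert result.p_value == pytest.approx(1 / 3, rel=1e-12)

    def test_empty_margin_signalled(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4))

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(77)
        checked = 0
        while checked < 200:
            a, b, c, d = rng.integers(0, 12, size=4)
            table = np.array([[a, b], [c, d]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            p = fisher_exact_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert p.p_value == pytest.approx(
                fisher_oracle(int(a), int(b), int(c), int(d)), rel=1e-9, abs=1e-12
            )
            checked += 1


class TestTwoProportionChisq:
    def test_equal_proportions_null(self):
        result = two_proportion_chisq(30, 100, 30, 100)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_pooled_formula_value(self):
        # chi2 = (p1-p2)^2 / (p(1-p)(1/n1+1/n2)) with pooled p = 0.225
        result = two_proportion_chisq(30, 100, 15, 100)
        assert result.statistic == pytest.approx(
            0.15**2 / (0.225 * 0.775 * 0.02), rel=1e-9
        )
        assert result.statistic == pytest.approx(6.45, abs=0.01)

    def test_extreme_split_highly_significant(self):
        result = two_proportion_chisq(10, 10, 0, 10)
        assert result.statistic == pytest.approx(20.0, rel=1e-9)
        assert result.p_value < 1e-4

    def test_small_expected_cell_warns(self):
        with pytest.warns(UserWarning, match="fisher"):
            two_proportion_chisq(1, 2, 0, 2)

    def test_converges_to_fisher_with_scale(self):
        """As all cells grow proportionally the chi-square p approaches the
        exact p (checked at x1, x10, x100 of a fixed table)."""
        base = (6, 4, 2, 8)
        gaps = []
        for scale in (1, 10, 100):
            a, b, c, d = (x * scale for x in base)
            chi_p = two_proportion_chisq(a, a + b, c, c + d).p_value
            fisher_p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
            gaps.append(abs(chi_p - fisher_p))
        assert gaps[0] > gaps[1] > gaps[2]


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03]) == [pytest.approx(0.03)]

    def test_two_p_definition(self):
        assert holm_bonferroni([0.01, 0.04]) == [
            pytest.approx(0.02),
            pytest.approx(0.04),
        ]

    def test_all_ones(self):
        assert holm_bonferroni([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(5)
        ps = rng.uniform(size=8)
        adjusted = holm_bonferroni(list(ps))
        order = np.argsort(ps)
        assert all(
            adjusted[order[i]] <= adjusted[order[i + 1]] + 1e-12
            for i in range(len(ps) - 1)
        )
        assert all(adj >= raw - 1e-12 for adj, raw in zip(adjusted, ps))


class TestIndependenceNull:
    def test_product_of_segmental_and_cl_rates(self):
        expected = independence_expected_rate(12e-5, 5531e-7)
        assert expected == pytest.approx(6.6e-8, rel=0.01)
        assert round_to_sig(expected, 1) == pytest.approx(7e-8)

    def test_zero_and_commutativity(self):
        assert independence_expected_rate(0.5, 0.0) == 0.0
        assert independence_expected_rate(3e-4, 2e-5) == independence_expected_rate(
            2e-5, 3e-4
        )

    def test_binomial_upper_tail_small_case(self):
        result = binomial_independence_test(5, 1000, 0.001)
        # exact sum: P(X >= 5), lambda ≈ 1
        from scipy.stats import binom

        assert result.p_value == pytest.approx(
            float(binom.sf(4, 1000, 0.001)), rel=1e-12
        )
        assert result.p_value == pytest.approx(3.66e-3, rel=0.02)

    def test_zero_observed_is_null(self):
        assert binomial_independence_test(0, 100, 0.01).p_value == 1.0

    def test_poisson_switch_agrees_with_exact(self):
        """Above the exact-summation regime the Poisson tail matches."""
        from scipy.stats import binom

        n, p0 = 10_000_000, 5e-8  # at the switch boundary
        for k in (1, 2, 5):
            exact = float(binom.sf(k - 1, n, p0))
            approx = binomial_independence_test(k, n + 1, p0).p_value
            assert approx == pytest.approx(exact, rel=1e-3)

    def test_observed_complex_rate_rejects_independence(self):
        # observed ~6e-6 vs expected 7e-8 over 1e7 divisions
        n = 10_000_000
        k = int(round(6e-6 * n))
        assert binomial_independence_test(k, n, 7e-8).p_value < 0.01


class TestSampleComparisons:
    def test_welch_identical_samples(self):
        result = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_welch_shifted_sample_significant(self):
        assert welch_t_test([1, 2, 3], [11, 12, 13]).p_value < 0.01

    def test_welch_degenerate_samples_signalled(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_t_test([2.0, 2.0], [3.0, 3.0])

    def test_welch_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(123)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.0, 1.0, 6)
        observed = abs(welch_t_test(a, b).statistic)
        pooled = np.concatenate([a, b])
        hits = 0
        n_perm = 20_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            stat = abs(welch_t_test(pooled[:6], pooled[6:]).statistic)
            hits += stat >= observed - 1e-12
        assert welch_t_test(a, b).p_value == pytest.approx(hits / n_perm, abs=0.02)

    def test_mann_whitney_disjoint_small_samples(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)

    def test_mann_whitney_identical_samples(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_mann_whitney_all_tied(self):
        assert mann_whitney([5, 5, 5], [5, 5]).p_value == 1.0

    def test_mann_whitney_invariant_under_monotone_transform(self):
        a = [0.1, 0.5, 0.9, 1.7]
        b = [0.3, 1.1, 2.4, 3.0]
        p1 = mann_whitney(a, b).p_value
        p2 = mann_whitney(np.exp(a), np.exp(b)).p_value
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestPfgeFraction:
    def test_equal_volumes(self):
        assert pfge_chr2_fraction(1.0, 1.0, 1.0) == pytest.approx(1 / 3)

    def test_monosomy_signature(self):
        assert pfge_chr2_fraction(0.5, 1.0, 1.0) == pytest.approx(0.2)

    def test_scale_invariance(self):
        assert pfge_chr2_fraction(0.5, 1.0, 1.0) == pytest.approx(
            pfge_chr2_fraction(5.0, 10.0, 10.0)
        )

    def test_all_zero_signalled(self):
        with pytest.raises(ValueError, match="undefined"):
            pfge_chr2_fraction(0.0, 0.0, 0.0)
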