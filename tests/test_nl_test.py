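import numpy as np
import pytest
from scipy import stats

from nlhrv.nl_test import (
    NonlinearityTest,
    _rank_and_classify,
    bonferroni_adjust,
    clopper_pearson,
    compare_paired_means,
    compare_proportions_paired,
    surrogate_test,
)
from nlhrv.synthetic import GeneratorConfig, generate


class TestRankRule:
    def test_extreme_high_rank(self):
        rank, nl = _rank_and_classify(0.9, np.linspace(0.1, 0.8, 99))
        assert rank == 100 and nl

    def test_extreme_low_rank(self):
        rank, nl = _rank_and_classify(0.05, np.linspace(0.1, 0.8, 99))
        assert rank == 1 and nl

    def test_median_not_nonlinear(self):
        surr = np.linspace(0.1, 0.8, 99)
        rank, nl = _rank_and_classify(float(np.median(surr)), surr)
        assert not nl and 45 <= rank <= 55

    def test_boundary_ranks(self):
        surr = np.arange(99, dtype=float)
        # 4 surrogates below -> rank 5 -> rejected (low tail)
        assert _rank_and_classify(3.5, surr) == (5, True)
        # 5 below -> rank 6 -> kept
        assert _rank_and_classify(4.5, surr) == (6, False)
        # 95 below -> rank 96 -> rejected (high tail)
        assert _rank_and_classify(94.5, surr) == (96, True)
        assert _rank_and_classify(93.5, surr) == (95, False)

    def test_ties_resolve_toward_non_rejection(self):
        surr = np.concatenate([np.full(8, 0.5), np.linspace(0.6, 0.9, 91)])
        # original tied with 8 surrogates at the low end: conservative rank 9
        rank, nl = _rank_and_classify(0.5, surr)
        assert not nl and rank == 9


class TestSurrogateTestEndToEnd:
    def test_fit_runs_and_summarizes(self, ar_series):
        res = NonlinearityTest(ar_series, statistic="DET", n_surrogates=19).fit(seed=3)
        assert 1 <= res.rank <= 20
        assert res.surrogate_values.size == 19
        assert 0 <= res.original_value <= 1
        text = res.summary()
        assert "DET" in text and "rank" in text

    def test_statistic_choice_lam(self, ar_series):
        res = surrogate_test(ar_series, statistic="LAM", n_surrogates=19, seed=3)
        assert res.statistic_name == "LAM"

    def test_seed_reproducibility(self, ar_series):
        r1 = surrogate_test(ar_series, n_surrogates=19, seed=5)
        r2 = surrogate_test(ar_series, n_surrogates=19, seed=5)
        np.testing.assert_array_equal(r1.surrogate_values, r2.surrogate_values)
        assert r1.rank == r2.rank

    def test_embedding_reused_across_surrogates(self, ar_series):
        res = surrogate_test(ar_series, n_surrogates=19, seed=5)
        assert res.embedding.m >= 1 and res.embedding.tau >= 1

    def test_rho_one_never_rejects(self, ar_series):
        # all surrogates equal the original: full tie, conservative ranks
        res = NonlinearityTest(ar_series, n_surrogates=19, rho=1.0).fit(seed=1)
        assert not res.classified_nonlinear

    def test_nonlinear_map_detected(self):
        s = generate(GeneratorConfig(kind="map_modulated_alt", seed=1))
        res = surrogate_test(s, statistic="DET", n_surrogates=99, seed=401)
        assert res.classified_nonlinear


class TestClopperPearson:
    def oracle(self, k, n, conf=0.95):
        """Bisection on the binomial tail sums."""
        alpha = 1 - conf

        def tail_ge(p):  # P(X >= k)
            return sum(stats.binom.pmf(range(k, n + 1), n, p))

        def tail_le(p):  # P(X <= k)
            return sum(stats.binom.pmf(range(0, k + 1), n, p))

        def bisect(f, target, lo, hi):
            for _ in range(60):
                mid = (lo + hi) / 2
                if f(mid) < target:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        lower = 0.0 if k == 0 else bisect(tail_ge, alpha / 2, 0.0, 1.0)
        upper = 1.0 if k == n else bisect(lambda p: 1 - tail_le(p), 1 - alpha / 2, 0.0, 1.0)
        return 100 * lower, 100 * upper

    def test_zero_successes(self):
        ci = clopper_pearson(0, 68)
        assert ci.lower == 0.0 and ci.point == 0.0

    def test_printed_proportions(self):
        assert clopper_pearson(20, 68).point == pytest.approx(29.4, abs=0.05)
        assert clopper_pearson(21, 68).point == pytest.approx(30.9, abs=0.05)

    @pytest.mark.parametrize("k", [1, 5, 21, 40, 67, 68])
    def test_matches_tail_sum_oracle(self, k):
        ci = clopper_pearson(k, 68)
        lo, hi = self.oracle(k, 68)
        assert ci.lower == pytest.approx(lo, abs=1e-4)
        assert ci.upper == pytest.approx(hi, abs=1e-4)

    def test_ordering_invariant(self):
        ci = clopper_pearson(20, 68)
        assert 0 <= ci.lower <= ci.point <= ci.upper <= 100

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestProportionComparisons:
    def test_identical_vectors_mcnemar(self):
        b = np.array([True] * 20 + [False] * 48)
        _, p = compare_proportions_paired(b, b, method="mcnemar")
        assert p == 1.0

    def test_single_discordant_pair_each_way(self):
        b = np.array([True] * 20 + [False] * 48)
        a = b.copy()
        a[0], a[30] = False, True  # one discordant pair each way
        _, p = compare_proportions_paired(b, a, method="mcnemar")
        assert p > 0.05

    def test_chi2_on_similar_proportions(self):
        b = np.array([True] * 20 + [False] * 48)
        a = np.array([True] * 21 + [False] * 47)
        chi2, p = compare_proportions_paired(b, a, method="chi2")
        # closed-form Pearson chi-square on the 2x2 margins
        table = np.array([[20, 48], [21, 47]], dtype=float)
        expected = stats.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(expected.statistic)
        assert p > 0.05


class TestPairedMeans:
    def test_identical(self):
        t, p = compare_paired_means([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_pure_shift(self):
        t, p = compare_paired_means([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
        assert p == 0.0 and np.isinf(t)

    def test_matches_closed_form(self, rng):
        xb = rng.normal(30, 5, 68)
        xa = xb - rng.normal(2, 4, 68)
        t, p = compare_paired_means(xb, xa)
        d = xb - xa
        t_exact = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert t == pytest.approx(t_exact, abs=1e-10)
        p_exact = 2 * stats.t.sf(abs(t_exact), d.size - 1)
        assert p == pytest.approx(p_exact, abs=1e-12)


def test_bonferroni_capped():
    np.testing.assert_allclose(
        bonferroni_adjust([0.01, 0.4, 0.9]), [0.03, 1.0, 1.0]
    )
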