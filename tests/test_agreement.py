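"""Statistics layer: exact tests vs enumeration oracles, AC1, Altman bands."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from garange.agreement import (DEFAULT_READERS, ReaderTable, binomial_test,
                               dagostino_pearson, gwet_ac1, interpret_altman,
                               simulate_readers, wilcoxon_signed_rank)


class TestDagostinoPearson:
    def test_k2_nonnegative(self, rng):
        for _ in range(5):
            k2, _ = dagostino_pearson(rng.standard_normal(50))
            assert k2 >= 0

    def test_calibration_on_normal_samples(self):
        """Standard-normal data should rarely be flagged (p > 0.05 in >= 90%)."""
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(200)
            _, p = dagostino_pearson(x)
            hits += p > 0.05
        assert hits >= 90

    def test_power_on_lognormal_samples(self):
        """Heavily skewed data should be flagged (p < 0.05 in >= 95%)."""
        hits = 0
        for seed in range(100):
            x = np.exp(np.random.default_rng(seed).standard_normal(200))
            _, p = dagostino_pearson(x)
            hits += p < 0.05
        assert hits >= 95

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            dagostino_pearson(np.ones(30))

    def test_small_sample_warns(self, rng):
        with pytest.warns(UserWarning, match="n < 20"):
            dagostino_pearson(rng.standard_normal(12))


def wilcoxon_enumeration_oracle(d, alternative):
    """Brute-force signed-rank p-value over all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = Fraction(int(round(2 * ranks[d > 0].sum())), 2)
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        ws.append(Fraction(int(round(2 * w)), 2))
    total = len(ws)
    ge = Fraction(sum(w >= w_obs for w in ws), total)
    le = Fraction(sum(w <= w_obs for w in ws), total)
    if alternative == "greater":
        return float(ge)
    if alternative == "less":
        return float(le)
    return float(min(2 * min(ge, le), Fraction(1)))


class TestWilcoxon:
    def test_three_positive_differences(self):
        """{+1,+2,+3}: W+ = 6, exact two-sided p = 2/8."""
        w, p = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert w == 6.0
        assert p == 0.25

    def test_antisymmetry_of_one_sided_p(self, rng):
        d = rng.standard_normal(10)
        _, p_g = wilcoxon_signed_rank(d, "greater")
        _, p_l = wilcoxon_signed_rank(-d, "less")
        assert p_g == p_l

    @pytest.mark.parametrize("n", [5, 8, 12])
    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_p_matches_enumeration(self, n, alternative):
        """DP-based exact p equals the brute-force oracle bit-for-bit."""
        rng = np.random.default_rng(100 + n)
        for _ in range(3):
            d = np.round(rng.standard_normal(n), 1)  # induces occasional ties
            if np.all(d == 0):
                continue
            _, p = wilcoxon_signed_rank(d, alternative)
            assert p == wilcoxon_enumeration_oracle(d, alternative)

    def test_matches_scipy_without_ties(self, rng):
        d = rng.standard_normal(15)
        w, p = wilcoxon_signed_rank(d)
        res = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert p == pytest.approx(res.pvalue, rel=1e-12)

    def test_zeros_dropped_and_all_zero_rejected(self):
        w, _ = wilcoxon_signed_rank(np.array([0.0, 1.0, -2.0]))
        assert w == 1.0
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(5))

    def test_large_sample_normal_approximation(self, rng):
        d = rng.standard_normal(60) + 0.5
        _, p = wilcoxon_signed_rank(d)
        res = sps.wilcoxon(d, alternative="two-sided", method="approx",
                           correction=True)
        assert p == pytest.approx(res.pvalue, rel=0.05)


def binomial_oracle(successes, n, p0, alternative):
    p = Fraction(p0)
    pmf = [comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
    if alternative == "greater":
        return float(sum(pmf[successes:]))
    if alternative == "less":
        return float(sum(pmf[: successes + 1]))
    obs = pmf[successes]
    return float(min(Fraction(1), sum(m for m in pmf if m <= obs)))


class TestBinomial:
    def test_38_of_40_extreme_tail(self):
        """38/40 vs 0.5, one-sided: p = (C(40,38)+C(40,39)+C(40,40))/2^40."""
        expected = (comb(40, 38) + comb(40, 39) + comb(40, 40)) / 2**40
        assert binomial_test(38, 40, 0.5, "greater") == pytest.approx(
            expected, rel=1e-15)
        assert expected == pytest.approx(821 / 2**40)

    def test_20_of_40_near_half(self):
        assert binomial_test(20, 40, 0.5, "greater") == pytest.approx(
            binomial_oracle(20, 40, 0.5, "greater"), rel=1e-15)
        assert binomial_test(20, 40, 0.5, "greater") == pytest.approx(0.5627, abs=2e-4)

    @pytest.mark.parametrize("n", [4, 7, 12])
    def test_all_successes_closed_form(self, n):
        assert binomial_test(n, n, 0.5, "greater") == 0.5**n

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_oracle_small_n(self, alternative):
        for n in range(1, 13):
            for s in range(n + 1):
                ours = binomial_test(s, n, 0.5, alternative)
                assert ours == binomial_oracle(s, n, 0.5, alternative)

    def test_matches_scipy(self):
        for s, n, p0 in [(9, 12, 0.5), (3, 10, 0.3), (40, 40, 0.5)]:
            for alt in ("two-sided", "greater", "less"):
                ours = binomial_test(s, n, p0, alt)
                ref = sps.binomtest(s, n, p0, alternative=alt).pvalue
                assert ours == pytest.approx(ref, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_test(5, 4)
        with pytest.raises(ValueError):
            binomial_test(1, 4, p0=1.0)


class TestGwetAc1:
    def test_perfect_agreement(self):
        table = ReaderTable(np.ones((6, 4), dtype=int))
        res = gwet_ac1(table)
        assert res.ac1 == 1.0
        assert res.interpretation == "Very Good"

    def test_hand_example_two_raters_four_items(self):
        """3 agreements on category 1 + 1 split: pa=0.75, pe=0.21875, AC1=0.68."""
        scores = np.array([[1, 1], [1, 1], [1, 1], [1, 2]])
        res = gwet_ac1(ReaderTable(scores))
        assert res.ac1 == pytest.approx(0.68, abs=1e-10)
        assert res.ci_low <= res.ac1 <= res.ci_high

    def test_label_swap_invariance(self, rng):
        scores = rng.integers(1, 3, size=(12, 5))
        swapped = 3 - scores
        assert gwet_ac1(ReaderTable(scores)).ac1 == pytest.approx(
            gwet_ac1(ReaderTable(swapped)).ac1, rel=1e-12)

    def test_agreement_increase_raises_ac1(self, rng):
        scores = rng.integers(1, 3, size=(10, 3))
        scores[0] = [1, 2, 1]  # ensure one disagreeing item
        before = gwet_ac1(ReaderTable(scores)).ac1
        fixed = scores.copy()
        fixed[0] = [1, 1, 1]
        after = gwet_ac1(ReaderTable(fixed)).ac1
        assert after > before

    def test_pairwise_equals_two_rater_formula(self, rng):
        """AC1 on a rater pair equals the 2-rater computation on that pair."""
        scores = rng.integers(1, 3, size=(15, 4))
        table = ReaderTable(scores)
        for i, j in itertools.combinations(range(4), 2):
            sub = gwet_ac1(table, raters=[i, j])
            direct = gwet_ac1(ReaderTable(scores[:, [i, j]]))
            assert sub.ac1 == pytest.approx(direct.ac1, rel=1e-12)

    def test_more_stable_than_kappa_under_high_prevalence(self):
        """On skewed tables AC1 stays above mean pairwise Cohen's kappa."""
        def cohen_kappa(a, b):
            po = np.mean(a == b)
            p1a, p1b = np.mean(a == 1), np.mean(b == 1)
            pe = p1a * p1b + (1 - p1a) * (1 - p1b)
            if pe == 1.0:
                return np.nan
            return (po - pe) / (1 - pe)

        wins = total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            scores = np.where(rng.random((12, 3)) < 0.88, 1, 2)
            if np.all(scores == scores[0, 0]):
                continue
            ac1 = gwet_ac1(ReaderTable(scores)).ac1
            kappas = [cohen_kappa(scores[:, i], scores[:, j])
                      for i, j in itertools.combinations(range(3), 2)]
            kappas = [k for k in kappas if not np.isnan(k)]
            if not kappas:
                continue
            total += 1
            wins += ac1 >= np.mean(kappas) - 1e-12
        assert total > 80
        assert wins == total


class TestAltman:
    @pytest.mark.parametrize("value,label", [
        (0.71, "Good"),        # overall image-quality agreement regime
        (0.93, "Very Good"),   # lesion-detectability regime
        (0.94, "Very Good"),
        (0.20, "Poor"),
        (0.40, "Fair"),
        (0.60, "Moderate"),
        (0.80, "Good"),
        (0.81, "Very Good"),
        (-0.5, "Poor"),
    ])
    def test_banding(self, value, label):
        assert interpret_altman(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_altman(1.5)


class TestSimulateReaders:
    def test_deterministic_per_seed(self):
        eff = np.array([10.0, 20.0, 5.0, 30.0])
        noi = np.zeros(4)
        a = simulate_readers(eff, noi, seed=3)
        b = simulate_readers(eff, noi, seed=3)
        assert np.array_equal(a.scores, b.scores)

    def test_strong_effect_gives_all_category_one(self):
        from garange.agreement import ReaderProfile
        profiles = (ReaderProfile(a=0.0, b_effect=100.0),) * 3
        table = simulate_readers(np.full(8, 50.0), np.zeros(8),
                                 profiles=profiles, seed=0)
        assert np.all(table.scores == 1)

    def test_default_panel_is_high_prevalence(self):
        """Positive effect sizes should yield >= 80% category-1 prevalence."""
        rng = np.random.default_rng(8)
        eff = rng.uniform(10, 40, size=40)
        noi = rng.normal(0, 2, size=40)
        table = simulate_readers(eff, noi, profiles=DEFAULT_READERS, seed=1)
        assert np.mean(table.scores == 1) >= 0.8

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            ReaderTable(np.array([[1, 3], [1, 2]]))
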