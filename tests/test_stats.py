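import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from barcodeaudit.errors import ValidationError
from barcodeaudit.stats import (
    anova_from_sums,
    balanced_resample,
    chi_square_from_contingency,
    group_means,
    moods_median_test,
    one_way_anova,
    spearman,
    welch_t,
)

from _oracles import anova_brute, chi_square_brute, spearman_brute, welch_brute


class TestMoodsMedian:
    def test_identical_groups_give_zero_chi_square(self):
        r = moods_median_test({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert r.chi_square == pytest.approx(0.0, abs=1e-12)

    def test_ties_count_at_or_below(self):
        r = moods_median_test({"a": [1.0, 2.0, 2.0], "b": [2.0, 3.0, 4.0]})
        assert r.pooled_median == 2.0
        assert r.contingency["a"] == (0, 3)  # both ties in the <= cell
        assert r.contingency["b"] == (2, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_groups_match_bruteforce_expected_counts(self, seed):
        rng = np.random.default_rng(seed)
        groups = {
            k: rng.normal(loc, 1, size=rng.integers(3, 7)).tolist()
            for k, loc in (("a", 0.0), ("b", 0.8), ("c", 1.6))
        }
        r = moods_median_test(groups)
        table = np.array(list(r.contingency.values()), float)
        chi2, df = chi_square_brute(table)
        assert r.chi_square == pytest.approx(chi2, abs=1e-12)
        assert r.df == df == len(groups) - 1

    def test_agrees_with_scipy_median_test(self):
        rng = np.random.default_rng(8)
        a, b, c = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25), rng.normal(1, 2, 41)
        r = moods_median_test({"a": a, "b": b, "c": c})
        ref = sps.median_test(a, b, c, ties="below", correction=False)
        assert r.chi_square == pytest.approx(ref.statistic, abs=1e-9)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_one_sided_degenerate_table_advises_exact_test(self):
        with pytest.raises(ValidationError, match="exact"):
            moods_median_test({"a": [1.0, 1.0], "b": [1.0, 1.0]})

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_group_order_and_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        # odd pooled size keeps the pooled median on a data point
        a = rng.normal(0, 1, 7)
        b = rng.normal(1, 1, 6)
        r1 = moods_median_test({"a": a, "b": b})
        r2 = moods_median_test({"b": b, "a": a})
        r3 = moods_median_test({"a": np.exp(a), "b": np.exp(b)})
        assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-12)
        assert r1.chi_square == pytest.approx(r3.chi_square, abs=1e-12)


class TestAnova:
    def test_no_between_variation_gives_zero_f(self):
        t = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert t.ss_between == pytest.approx(0.0, abs=1e-12)
        assert t.F == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_reported_degenerate(self):
        t = one_way_anova({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert t.degenerate and t.F == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_decomposition_matches_bruteforce_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        groups = {
            k: rng.normal(i, 1 + i, size=rng.integers(5, 15))
            for i, k in enumerate("abcd")
        }
        t = one_way_anova(groups)
        ssb, ssw, F = anova_brute(groups)
        assert t.ss_between == pytest.approx(ssb, abs=1e-9)
        assert t.ss_within == pytest.approx(ssw, abs=1e-9)
        assert t.F == pytest.approx(F, abs=1e-9)
        ref = sps.f_oneway(*groups.values())
        assert t.F == pytest.approx(ref.statistic, rel=1e-12)
        assert t.p == pytest.approx(ref.pvalue, rel=1e-9)
        # conservation: SS_total = SS_between + SS_within
        pooled = np.concatenate(list(groups.values()))
        assert t.ss_total == pytest.approx(((pooled - pooled.mean()) ** 2).sum(), abs=1e-9)


class TestWelch:
    def test_equal_samples_give_zero_t(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_sign_reflects_direction(self):
        t_up, _, _ = welch_t([2.0, 2.001, 1.999], [1.0, 1.001, 0.999])
        assert t_up > 100  # tiny variance, unit shift
        t_dn, _, _ = welch_t([1.0, 1.001, 0.999], [2.0, 2.001, 1.999])
        assert t_dn < -100

    def test_zero_variance_in_both_groups_raises(self):
        with pytest.raises(ValidationError):
            welch_t([1.0, 1.0], [2.0, 2.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(4, 20))
        b = rng.normal(0.5, 2, rng.integers(4, 20))
        t, df, _ = welch_t(a, b)
        t0, df0 = welch_brute(a, b)
        assert t == pytest.approx(t0, abs=1e-12)
        assert df == pytest.approx(df0, abs=1e-12)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_constant_vector_reported_missing(self):
        rho, p = spearman([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho) and math.isnan(p)

    @pytest.mark.parametrize("seed", range(5))
    def test_tied_data_matches_midrank_formula(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=20).astype(float)  # heavy ties
        y = x + rng.normal(0, 1, 20)
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(spearman_brute(x, y), abs=1e-12)
        assert -1.0 <= rho <= 1.0

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert spearman(x, y)[0] == pytest.approx(
            spearman(np.exp(x), y**3)[0], abs=1e-12
        )


class TestResampleAndMeans:
    def test_full_size_draw_is_a_permutation(self):
        out = balanced_resample({"a": [1.0, 2.0, 3.0]}, n=3, seed=0)
        assert sorted(out["a"].tolist()) == [1.0, 2.0, 3.0]

    def test_deterministic_under_seed(self):
        groups = {"a": list(range(20)), "b": list(range(100, 130))}
        r1 = balanced_resample(groups, 10, seed=42)
        r2 = balanced_resample(groups, 10, seed=42)
        assert all(np.array_equal(r1[k], r2[k]) for k in groups)

    def test_too_small_group_is_named(self):
        with pytest.raises(ValidationError, match="b"):
            balanced_resample({"a": [1.0] * 5, "b": [1.0] * 2}, n=4, seed=0)

    def test_resampled_mean_consistent_with_full_mean(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(2.0, 2.0, size=211)
        means = [
            balanced_resample({"g": values}, 73, seed=s)["g"].mean()
            for s in range(200)
        ]
        se = values.std(ddof=1) / math.sqrt(73)
        assert abs(np.mean(means) - values.mean()) < 3 * se / math.sqrt(200) * 10

    def test_group_means_exact_and_empty(self):
        out = dict(
            (k, (n, s, m))
            for k, n, s, m in group_means({"a": [1.0, 2.0], "b": []})
        )
        assert out["a"] == (2, 3.0, 1.5)
        assert out["b"][0] == 0 and math.isnan(out["b"][2])


def test_anova_from_sums_reconstructs_f():
    t = anova_from_sums(362.48, 3, 5613.26, 1192)
    assert round(t.F, 2) == 25.66
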