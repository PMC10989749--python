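import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from markerflow.diversity_alpha import (
    alpha_group_test,
    alpha_numeric_regression,
    chao1,
    shannon,
    simpson,
)


class TestIndexes:
    def test_shannon_closed_forms(self):
        assert shannon([0.5, 0.5]) == pytest.approx(math.log(2), abs=1e-12)
        assert shannon([1.0]) == 0.0
        assert shannon([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)

    def test_simpson_closed_forms(self):
        assert simpson([1.0]) == 0.0
        assert simpson([0.5, 0.5]) == pytest.approx(0.5)
        for k in (3, 7, 10):
            assert simpson([1 / k] * k) == pytest.approx(1 - 1 / k, abs=1e-12)

    def test_chao1_hand_example(self):
        # F1=2 singletons, F2=1 doubleton: 5 + 2*1/(2*2) = 5.5
        assert chao1([5, 3, 1, 1, 2]) == 5.5

    def test_chao1_no_singletons(self):
        assert chao1([5, 3, 2, 2]) == 4.0

    def test_chao1_single_singleton(self):
        assert chao1([1]) == 1.0

    def test_chao1_rejects_relative_abundance(self):
        with pytest.raises(TypeError, match="integer counts"):
            chao1([0.5, 0.5])

    def test_chao1_at_least_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.poisson(1.5, size=30)
            if counts.sum() == 0:
                continue
            assert chao1(counts) >= (counts > 0).sum()

    @pytest.mark.parametrize("k", [3, 5, 9])
    def test_uniform_maximizes_shannon_and_simpson(self, k):
        rng = np.random.default_rng(k)
        uniform = np.full(k, 1 / k)
        for _ in range(25):
            p = rng.dirichlet(np.ones(k))
            assert shannon(p) <= shannon(uniform) + 1e-12
            assert simpson(p) <= simpson(uniform) + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=20))
    def test_index_bounds_on_arbitrary_profiles(self, weights):
        p = np.array(weights) / np.sum(weights)
        k = len(p)
        assert -1e-9 <= shannon(p) <= math.log(k) + 1e-9
        assert -1e-9 <= simpson(p) <= 1 - 1 / k + 1e-9

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 50), min_size=1, max_size=30))
    def test_chao1_bounds_on_arbitrary_counts(self, counts):
        if sum(counts) == 0:
            assert chao1(counts) is None
        else:
            assert chao1(counts) >= sum(c > 0 for c in counts)

    def test_permutation_invariance(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        q = p[::-1]
        assert shannon(p) == pytest.approx(shannon(q))
        assert simpson(p) == pytest.approx(simpson(q))


def _series(vals, prefix="s"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


class TestGroupTest:
    def test_exact_two_group_separated(self):
        vals = _series([1, 2, 3, 4, 5, 6])
        grp = _series(["a"] * 3 + ["b"] * 3)
        u, p, method = alpha_group_test(vals, grp)
        assert method == "mann-whitney-exact"
        assert p == pytest.approx(0.1)  # 2 of the 20 rank splits are as extreme

    def test_exact_matches_scipy_enumeration(self):
        # independent oracle: scipy's exact Mann-Whitney on tie-free data
        rng = np.random.default_rng(3)
        for _ in range(10):
            n1, n2 = rng.integers(2, 7, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            vals = _series(np.concatenate([x, y]))
            grp = _series(["a"] * n1 + ["b"] * n2)
            _, p, _ = alpha_group_test(vals, grp)
            expected = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(expected, abs=1e-12)

    def test_kruskal_three_groups_hand_ranks(self):
        vals = _series([1, 2, 3, 4, 5, 6, 7, 8, 9])
        grp = _series(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        h, p, method = alpha_group_test(vals, grp)
        assert method == "kruskal-wallis"
        assert h == pytest.approx(7.2)

    def test_pure_ties_give_p_one(self):
        vals = _series([2.0] * 6)
        grp = _series(["a"] * 3 + ["b"] * 3)
        _, p, method = alpha_group_test(vals, grp)
        assert p == 1.0

    def test_missing_dropped_pairwise(self):
        vals = _series([1, 2, 3, 4, np.nan, 6])
        grp = _series(["a", "a", "a", "b", "b", "b"])
        _, p, _ = alpha_group_test(vals, grp)
        assert 0 < p <= 1

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            alpha_group_test(_series([1, 2, 3]), _series(["a", "a", "a"]))

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 400
        for _ in range(reps):
            vals = _series(rng.normal(size=24))
            grp = _series(["a"] * 12 + ["b"] * 12)
            _, p, _ = alpha_group_test(vals, grp)
            rejections += p <= 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestNumericRegression:
    def test_exact_line(self):
        x = _series([1.0, 2.0, 3.0, 4.0])
        y = pd.Series(2 * x.to_numpy() + 1, index=x.index)
        slope, intercept, r2, p = alpha_numeric_regression(y, x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_response(self):
        slope, _, r2, p = alpha_numeric_regression(
            _series([5.0, 5.0, 5.0]), _series([1.0, 2.0, 3.0])
        )
        assert (slope, r2, p) == (0.0, 0.0, 1.0)

    def test_hand_ols(self):
        # x=[1,2,3], y=[1,3,2]: slope 0.5, r2 0.25
        slope, _, r2, _ = alpha_numeric_regression(
            _series([1.0, 3.0, 2.0]), _series([1.0, 2.0, 3.0])
        )
        assert slope == pytest.approx(0.5)
        assert r2 == pytest.approx(0.25)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            alpha_numeric_regression(_series([1.0, 2.0, 3.0]), _series([1.0, 1.0, 1.0]))
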