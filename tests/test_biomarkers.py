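import numpy as np
import pandas as pd
import pytest
from scipy import stats

from markerflow.biomarkers import (
    feature_tests,
    numeric_biomarkers,
    ranksum_screen,
    rf_rank,
)
from markerflow.io_formats import AbundanceTable


def _counts_table(mat, prefix="f"):
    n, p = mat.shape
    return AbundanceTable(
        pd.DataFrame(mat, index=[f"s{i}" for i in range(n)],
                     columns=[f"{prefix}{j}" for j in range(p)]),
        unit="counts",
    )


def _grp(n_per):
    ids = [f"s{i}" for i in range(2 * n_per)]
    return pd.Series(["a"] * n_per + ["b"] * n_per, index=ids)


class TestScreen:
    def test_planted_shift_kept_with_exact_p(self):
        # groups [1..5] vs [11..15]: fully separated, exact p = 2/C(10,5)
        mat = np.ones((10, 3))
        mat[:, 0] = [1, 2, 3, 4, 5, 11, 12, 13, 14, 15]
        mat[:, 1] = np.tile([3.0, 4.0], 5)
        mat[:, 2] = np.repeat([7.0], 10)
        res = feature_tests(_counts_table(mat), _grp(5))
        row = res[res.feature == "f0"].iloc[0]
        assert row.p == pytest.approx(2 / 252)
        kept = ranksum_screen(_counts_table(mat), _grp(5))
        assert [k[0] for k in kept] == ["f0"]

    def test_identical_feature_excluded(self):
        mat = np.column_stack([
            np.repeat([5.0], 10),
            [1, 2, 3, 4, 5, 11, 12, 13, 14, 15],
        ])
        res = feature_tests(_counts_table(mat), _grp(5))
        assert res[res.feature == "f0"].iloc[0].p == 1.0
        assert "f0" not in [k[0] for k in ranksum_screen(_counts_table(mat), _grp(5))]

    def test_bh_ladder_hand_example(self):
        # BH on p=[0.01, 0.02, 0.03], m=3 -> q=[0.03, 0.03, 0.03]
        qs = stats.false_discovery_control(np.array([0.01, 0.02, 0.03]), method="bh")
        np.testing.assert_allclose(qs, [0.03, 0.03, 0.03])

    def test_prevalence_filter_excludes_rare_features(self):
        mat = np.zeros((20, 2))
        mat[:, 0] = np.arange(20, dtype=float) + 1
        mat[0, 1] = 3.0  # 5% prevalence
        res = feature_tests(_counts_table(mat), _grp(10))
        assert list(res.feature) == ["f0"]

    def test_null_false_discovery_control(self):
        # 60 null simulations, 50 features: mean kept fraction stays small
        rng = np.random.default_rng(0)
        kept_frac = []
        for _ in range(60):
            mat = rng.lognormal(0, 1, size=(20, 50))
            kept = ranksum_screen(_counts_table(mat), _grp(10))
            kept_frac.append(len(kept) / 50)
        assert np.mean(kept_frac) <= 0.05 + 2 * np.std(kept_frac) / np.sqrt(60) + 0.01


class TestRfRank:
    def _planted(self, seed, n=60, noise=20):
        rng = np.random.default_rng(seed)
        mat = rng.lognormal(0, 1, size=(n, noise + 1))
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        mat[:, 0] = rng.lognormal(0, 0.3, n) + y * 5  # perfectly separating feature
        return _counts_table(mat), _grp(n // 2)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_planted_feature_ranks_first(self, seed):
        t, g = self._planted(seed)
        report = rf_rank(t, g, trees=200, seed=seed)
        assert report.entries[0]["feature"] == "f0"
        assert report.model_error <= 0.05

    def test_same_seed_reproducible(self):
        t, g = self._planted(3)
        r1 = rf_rank(t, g, trees=100, seed=11)
        r2 = rf_rank(t, g, trees=100, seed=11)
        assert [e["importance"] for e in r1.entries] == [e["importance"] for e in r2.entries]

    def test_permuted_labels_near_baseline_error(self):
        t, g = self._planted(4)
        rng = np.random.default_rng(0)
        gp = pd.Series(rng.permutation(g.to_numpy()), index=g.index)
        report = rf_rank(t, gp, trees=200, seed=5)
        assert abs(report.model_error - 0.5) <= 0.15

    def test_duplicated_feature_shares_importance(self):
        t, g = self._planted(6, noise=5)
        dup = t.data.copy()
        dup["f0_copy"] = dup["f0"]
        t2 = AbundanceTable(dup, unit="counts")
        ranks = []
        for seed in range(5):
            rep = rf_rank(t2, g, trees=200, seed=seed)
            order = [e["feature"] for e in rep.entries]
            ranks.append(order.index("f0") + order.index("f0_copy"))
        # the two copies jointly occupy the top ranks (0 and 1 -> sum 1)
        assert np.median(ranks) <= 3

    def test_single_class_errors(self):
        t, _ = self._planted(7)
        g = pd.Series(["a"] * 60, index=t.sample_ids)
        with pytest.raises(ValueError):
            rf_rank(t, g, trees=50, seed=0)


class TestNumericBiomarkers:
    def test_exact_monotone_feature(self):
        x = np.arange(10, dtype=float)
        mat = np.column_stack([x, np.ones(10)])
        t = _counts_table(mat)
        var = pd.Series(x, index=t.sample_ids)
        hits = numeric_biomarkers(t, var)
        assert hits[0][0] == "f0"
        assert hits[0][1] == pytest.approx(1.0)

    def test_hand_spearman(self):
        # x=[1,2,3] vs y=[3,1,2]: rho = 1 - 6*6/(3*8) = -0.5
        rho = stats.spearmanr([1, 2, 3], [3, 1, 2]).statistic
        assert rho == pytest.approx(-0.5)
        mat = np.column_stack([[3.0, 1.0, 2.0], [5.0, 6.0, 4.0]])
        t = _counts_table(mat)
        var = pd.Series([1.0, 2.0, 3.0], index=t.sample_ids)
        hits = numeric_biomarkers(t, var, q_threshold=1.0)
        by_feat = {h[0]: h[1] for h in hits}
        assert by_feat["f0"] == pytest.approx(-0.5)

    def test_null_type_one_rate(self):
        rng = np.random.default_rng(1)
        kept = 0
        reps = 300
        for _ in range(reps):
            mat = rng.lognormal(0, 1, size=(15, 1))
            t = _counts_table(mat)
            var = pd.Series(rng.normal(size=15), index=t.sample_ids)
            kept += len(numeric_biomarkers(t, var)) > 0
        assert kept / reps <= 0.07

    def test_constant_variable_errors(self):
        t = _counts_table(np.ones((5, 2)))
        with pytest.raises(ValueError):
            numeric_biomarkers(t, pd.Series(np.ones(5), index=t.sample_ids))
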