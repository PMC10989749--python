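import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from conftest import make_pack, profile
from markerflow.diversity_beta import (
    anosim,
    distance_matrix,
    distance_numeric_regression,
    hierarchical_metastorms,
    metastorms_distance,
    pca,
    pcoa,
    permanova,
)
from markerflow.function_prediction import FunctionalProfile
from markerflow.io_formats import AbundanceTable, DistanceMatrix
from markerflow.synthetic_data import simulate_reference_pack


class TestMetastorms:
    def test_identical_profiles_distance_zero(self, toy_pack):
        p = profile("a", {"A": 0.5, "C": 0.5})
        assert metastorms_distance(p, profile("b", {"A": 0.5, "C": 0.5}), toy_pack) == 0.0

    def test_two_leaf_hand_trace(self, two_leaf_pack):
        # disjoint siblings across unit branches: S = e^-1
        d = metastorms_distance(
            profile("a", {"A": 1.0}), profile("b", {"B": 1.0}), two_leaf_pack
        )
        assert d == pytest.approx(1 - math.exp(-1), abs=1e-9)

    def test_zero_branch_lengths_make_siblings_equivalent(self):
        pack = make_pack(
            "(A:0.0,B:0.0)root:0.0;",
            taxonomy={
                "A": "k__K;p__P;c__C;o__O;f__F;g__G;s__A",
                "B": "k__K;p__P;c__C;o__O;f__F;g__G;s__B",
            },
        )
        d = metastorms_distance(profile("a", {"A": 1.0}), profile("b", {"B": 1.0}), pack)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_empty_sample_conventions(self, toy_pack):
        e = profile("e", {})
        p = profile("p", {"A": 1.0})
        assert metastorms_distance(e, e, toy_pack) == 0.0
        assert metastorms_distance(e, p, toy_pack) == 1.0

    def test_unweighted_invariant_to_abundance_rescale(self, toy_pack):
        a = profile("a", {"A": 0.9, "C": 0.1})
        b = profile("b", {"A": 0.1, "C": 0.9})
        c = profile("c", {"B": 0.5, "D": 0.5})
        d1 = metastorms_distance(a, c, toy_pack, weighted=False)
        d2 = metastorms_distance(b, c, toy_pack, weighted=False)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_monotone_with_clade_distance_on_ladder(self):
        # caterpillar tree: moving mass to more distant clades grows distance
        pack = make_pack(
            "(((L1:0.5,L2:0.5)n1:0.5,L3:0.5)n2:0.5,L4:0.5)root:0.0;",
            taxonomy={
                f"L{i}": f"k__K;p__P;c__C;o__O;f__F;g__G;s__L{i}" for i in range(1, 5)
            },
        )
        ref = profile("ref", {"L1": 1.0})
        ds = [
            metastorms_distance(ref, profile("x", {leaf: 1.0}), pack)
            for leaf in ("L2", "L3", "L4")
        ]
        assert ds[0] < ds[1] < ds[2]

    def test_symmetry_range_and_self_distance_random(self):
        pack = simulate_reference_pack(32, seed=7)
        leaves = pack.leaf_ids
        rng = np.random.default_rng(1)
        for i in range(30):
            pa = dict(zip(leaves, rng.dirichlet(np.full(32, 0.3))))
            pb = dict(zip(leaves, rng.dirichlet(np.full(32, 0.3))))
            a, b = profile("a", pa), profile("b", pb)
            dab = metastorms_distance(a, b, pack)
            dba = metastorms_distance(b, a, pack)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert 0.0 <= dab <= 1.0
            assert metastorms_distance(a, a, pack) == pytest.approx(0.0, abs=1e-9)


class TestHierarchicalMetastorms:
    def _pack(self):
        return make_pack(
            "(A:0.1,B:0.1)root:0.0;",
            taxonomy={
                "A": "k__K;p__P;c__C;o__O;f__F;g__G;s__A",
                "B": "k__K;p__P;c__C;o__O;f__F;g__G;s__B",
            },
            ko={"A": {"K1": 1, "K2": 1, "K3": 1}, "B": {"K1": 1, "K2": 1, "K3": 1}},
            hierarchy={
                "K1": ("M1", "Ca", "Pa"),
                "K2": ("M1", "Ca", "Pa"),  # shares the level-3 parent with K1
                "K3": ("M2", "Cb", "Pb"),  # shares only the root with K1
            },
        )

    def test_identical_profiles(self):
        pack = self._pack()
        a = FunctionalProfile("a", {"K1": 0.4, "K3": 0.6}, 0.0)
        b = FunctionalProfile("b", {"K1": 0.4, "K3": 0.6}, 0.0)
        assert hierarchical_metastorms(a, b, pack) == pytest.approx(0.0, abs=1e-12)

    def test_siblings_under_level3(self):
        # one 0.5-attenuating edge per side before the common node
        pack = self._pack()
        a = FunctionalProfile("a", {"K1": 1.0}, 0.0)
        b = FunctionalProfile("b", {"K2": 1.0}, 0.0)
        assert hierarchical_metastorms(a, b, pack) == pytest.approx(0.5, abs=1e-12)

    def test_sharing_only_root(self):
        # four attenuating edges per side: match min(0.0625, 0.0625)
        pack = self._pack()
        a = FunctionalProfile("a", {"K1": 1.0}, 0.0)
        b = FunctionalProfile("b", {"K3": 1.0}, 0.0)
        assert hierarchical_metastorms(a, b, pack) == pytest.approx(0.9375, abs=1e-12)


class TestDistanceMatrix:
    def test_identical_samples_zero_matrix(self, toy_pack):
        ps = [profile(f"s{i}", {"A": 0.5, "B": 0.5}) for i in range(3)]
        d = distance_matrix(ps, toy_pack)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)

    def test_thread_count_invariance(self):
        pack = simulate_reference_pack(16, seed=3)
        rng = np.random.default_rng(2)
        ps = [
            profile(f"s{i}", dict(zip(pack.leaf_ids, rng.dirichlet(np.full(16, 0.4)))))
            for i in range(8)
        ]
        d1 = distance_matrix(ps, pack, threads=1)
        d8 = distance_matrix(ps, pack, threads=8)
        assert d1.sample_ids == d8.sample_ids
        np.testing.assert_array_equal(d1.values, d8.values)


class TestOrdination:
    def test_pcoa_collinear_exact(self):
        d = DistanceMatrix(["a", "b", "c"], np.array(
            [[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]]))
        res = pcoa(d, axes=2)
        x = res.coordinates[:, 0]
        assert abs(x[0] - x[1]) == pytest.approx(1.0, abs=1e-8)
        assert abs(x[0] - x[2]) == pytest.approx(2.0, abs=1e-8)

    def test_pcoa_zero_distances(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(d, axes=2)
        np.testing.assert_allclose(res.coordinates, 0.0)

    def test_pcoa_matches_skbio_eigenvalues(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 4))
        from scipy.spatial import distance_matrix as euclid

        d = euclid(x, x)
        ours = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d), axes=3)
        theirs = skbio_pcoa(SkbioDM(d), number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(ours.coordinates), np.abs(theirs.samples.to_numpy()[:, :3]), atol=1e-8
        )

    def test_pca_pcoa_duality(self):
        rng = np.random.default_rng(5)
        x = rng.random((7, 5))
        x = x / x.sum(axis=1, keepdims=True)
        t = AbundanceTable(
            pd.DataFrame(x, index=[f"s{i}" for i in range(7)],
                         columns=[f"f{j}" for j in range(5)])
        )
        from scipy.spatial import distance_matrix as euclid

        d = DistanceMatrix(t.sample_ids, euclid(x, x))
        cp = pca(t, axes=2).coordinates
        cq = pcoa(d, axes=2).coordinates
        np.testing.assert_allclose(np.abs(cp), np.abs(cq), atol=1e-8)

    def test_pca_constant_feature_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.random((5, 3))
        base = pd.DataFrame(x, index=list("abcde"), columns=["f1", "f2", "f3"])
        aug = base.copy()
        aug["f4"] = 7.0
        c1 = pca(AbundanceTable(base, unit="counts"), axes=2).coordinates
        c2 = pca(AbundanceTable(aug, unit="counts"), axes=2).coordinates
        np.testing.assert_allclose(c1, c2, atol=1e-10)

    def test_explained_fractions_non_increasing(self):
        rng = np.random.default_rng(2)
        from scipy.spatial import distance_matrix as euclid

        x = rng.random((8, 6))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], euclid(x, x)), axes=5)
        assert all(np.diff(res.explained) <= 1e-12)
        assert res.explained.sum() <= 1 + 1e-9


def _four_sample_dm():
    # within-pair distance 1, between-pair 2
    d = np.full((4, 4), 2.0)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 1.0
    d[2, 3] = d[3, 2] = 1.0
    return DistanceMatrix(["s1", "s2", "s3", "s4"], d)


def _grp(labels, ids=None):
    ids = ids or [f"s{i + 1}" for i in range(len(labels))]
    return pd.Series(labels, index=ids)


class TestPermanova:
    def test_hand_example_f_equals_seven(self):
        f, p = permanova(_four_sample_dm(), _grp(["g1", "g1", "g2", "g2"]),
                         permutations=99, seed=0)
        assert f == pytest.approx(7.0)

    def test_matches_skbio_pseudo_f(self):
        rng = np.random.default_rng(4)
        from scipy.spatial import distance_matrix as euclid

        x = rng.random((10, 5))
        d = euclid(x, x)
        ids = [f"s{i}" for i in range(10)]
        labels = ["a"] * 5 + ["b"] * 5
        f, _ = permanova(DistanceMatrix(ids, d), _grp(labels, ids), permutations=9, seed=0)
        ref = skbio_permanova(SkbioDM(d, ids=ids), grouping=labels, permutations=9)
        assert f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # n=6, 3+3: exact p over all C(6,3)=20 label arrangements
        rng = np.random.default_rng(8)
        from scipy.spatial import distance_matrix as euclid

        x = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2, 1, (3, 2))])
        d = euclid(x, x)
        ids = [f"s{i + 1}" for i in range(6)]
        dm = DistanceMatrix(ids, d)
        grp = _grp(["a", "a", "a", "b", "b", "b"])

        from markerflow.diversity_beta import _pseudo_f

        f_obs = None
        fs = []
        for combo in itertools.combinations(range(6), 3):
            codes = np.array([0 if i in combo else 1 for i in range(6)])
            fval = _pseudo_f(d**2, codes, 2)
            fs.append(fval)
            if combo == (0, 1, 2):
                f_obs = fval
        exact_p = np.mean([fv >= f_obs - 1e-12 for fv in fs])
        _, p = permanova(dm, grp, permutations=999, seed=1)
        mc_se = math.sqrt(exact_p * (1 - exact_p) / 999)
        assert abs(p - exact_p) <= 2 * mc_se + 2 / 999

    def test_no_structure_on_identical_samples(self):
        d = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        f, p = permanova(d, pd.Series(["x", "x", "y", "y"], index=list("abcd")),
                         permutations=99, seed=0)
        assert p > 0.05


class TestAnosim:
    def test_perfect_separation_r_one(self):
        r, _ = anosim(_four_sample_dm(), _grp(["g1", "g1", "g2", "g2"]),
                      permutations=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_all_equal_distances_r_zero(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        r, _ = anosim(DistanceMatrix(list("abcd"), d),
                      pd.Series(["x", "x", "y", "y"], index=list("abcd")),
                      permutations=99, seed=0)
        assert r == pytest.approx(0.0)

    def test_matches_brute_force_ranks_and_skbio(self):
        rng = np.random.default_rng(6)
        from scipy.spatial import distance_matrix as euclid

        x = rng.random((6, 3))
        d = euclid(x, x)
        ids = [f"s{i}" for i in range(6)]
        labels = ["a", "a", "a", "b", "b", "b"]
        r, _ = anosim(DistanceMatrix(ids, d), _grp(labels, ids), permutations=9, seed=0)
        # independent oracle: explicit mean ranks over the 15 pairs
        pairs = list(itertools.combinations(range(6), 2))
        dists = [d[i, j] for i, j in pairs]
        ranks = stats.rankdata(dists)
        within = [k for k, (i, j) in enumerate(pairs) if labels[i] == labels[j]]
        between = [k for k, (i, j) in enumerate(pairs) if labels[i] != labels[j]]
        expected = (ranks[between].mean() - ranks[within].mean()) / (len(pairs) / 2)
        assert r == pytest.approx(expected, abs=1e-12)
        ref = skbio_anosim(SkbioDM(d, ids=ids), grouping=labels, permutations=9)
        assert r == pytest.approx(ref["test statistic"], rel=1e-9)


class TestDistanceRegression:
    def test_proportional_distances_r2_one(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        ids = list("abcd")
        slope, r2, p = distance_numeric_regression(
            DistanceMatrix(ids, d), pd.Series(x, index=ids), permutations=99, seed=0
        )
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_two_samples_error(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            distance_numeric_regression(d, pd.Series([1.0, 2.0], index=["a", "b"]))

    def test_constant_variable_error(self):
        d = DistanceMatrix(list("abc"), 1 - np.eye(3))
        with pytest.raises(ValueError, match="constant"):
            distance_numeric_regression(d, pd.Series([1.0, 1.0, 1.0], index=list("abc")))
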