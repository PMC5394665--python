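"""PERMANOVA, post hoc, Mantel and disparity correlations.

Exact permutation p-values are checked against independent brute-force
enumerations written here with plain loops; statistics are cross-checked
against scikit-bio on complete data.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

import floramorph as fm
from floramorph.dissimilarity import ArgumentError
from floramorph.group_tests import posthoc_triangle_table

from conftest import dissim_from_square


def euclid_dm(points, scale=1.0):
    d = squareform(pdist(np.atleast_2d(np.asarray(points, float)).reshape(len(points), -1)))
    d = d / max(d.max(), 1e-9) * scale
    return dissim_from_square(d)


def brute_force_permanova(values, labels):
    """Independent pseudo-F and exact p by full enumeration of label orders."""
    labels = list(labels)
    n = len(labels)

    def f_stat(lab):
        groups = sorted(set(lab))
        ss_total = sum(values[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for g in groups:
            members = [i for i, l in enumerate(lab) if l == g]
            if len(members) < 2:
                continue
            s = sum(
                values[i][j] ** 2
                for i, j in itertools.combinations(members, 2)
            )
            ss_within += s / len(members)
        ss_b = ss_total - ss_within
        if ss_within <= 0:
            return float("inf")
        return (ss_b / (len(groups) - 1)) / (ss_within / (n - len(groups)))

    f_obs = f_stat(labels)
    perms = set(itertools.permutations(labels))
    count = sum(1 for p in perms if f_stat(p) >= f_obs - 1e-12)
    return f_obs, count / len(perms)


class TestPermanova:
    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=6).tolist()
        pts[3:] = [p + 1.5 for p in pts[3:]]
        d = euclid_dm(pts)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = fm.permanova(d, labels, exhaustive=True)
        f_ref, p_ref = brute_force_permanova(d.values, labels)
        assert res.statistic == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_exact_p_unbalanced_groups(self):
        rng = np.random.default_rng(7)
        d = euclid_dm(rng.normal(size=(6, 2)))
        labels = ["a", "a", "b", "b", "b", "b"]
        res = fm.permanova(d, labels, exhaustive=True)
        _, p_ref = brute_force_permanova(d.values, labels)
        assert res.p_value == pytest.approx(p_ref)

    def test_two_group_euclidean_equals_classical_anova_f(self):
        """On a 1-D trait with Euclidean d, pseudo-F reduces to ANOVA F."""
        x1 = [1.0, 2.0, 3.5]
        x2 = [5.0, 6.5, 7.0]
        pts = x1 + x2
        d = dissim_from_square(
            np.abs(np.subtract.outer(pts, pts)) / 10.0
        )
        res = fm.permanova(d, ["a"] * 3 + ["b"] * 3, n_perm=10, seed=0)
        f_classical = f_oneway(x1, x2).statistic
        assert res.statistic == pytest.approx(f_classical)

    def test_statistic_matches_skbio(self, small_synthetic):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        _, resolved, _ = small_synthetic
        d = fm.dissimilarity_matrix(resolved)
        grouping = resolved.groups("family")
        ours = fm.permanova(d, grouping, n_perm=99, seed=0)
        theirs = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(d.values, ids=d.taxa),
            grouping.loc[list(d.taxa)].tolist(),
            permutations=99,
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_observed_f_invariant_to_within_group_relabelling(self):
        rng = np.random.default_rng(3)
        d = euclid_dm(rng.normal(size=(8, 2)))
        labels = ["a"] * 4 + ["b"] * 4
        base = fm.permanova(d, labels, n_perm=10, seed=0).statistic
        # swap taxa within groups: F unchanged
        order = [1, 0, 3, 2, 5, 4, 7, 6]
        v = d.values[np.ix_(order, order)]
        res = fm.permanova(dissim_from_square(v), labels, n_perm=10, seed=0)
        assert res.statistic == pytest.approx(base)

    def test_single_group_rejected(self):
        d = euclid_dm([1.0, 2.0, 3.0])
        with pytest.raises(ArgumentError):
            fm.permanova(d, ["a", "a", "a"])

    def test_type_i_error_calibrated(self):
        """Null rejection rate at alpha = 0.05 stays within 5% +/- 2%."""
        rng = np.random.default_rng(2024)
        n_sims, rejections = 500, 0
        for _ in range(n_sims):
            pts = rng.normal(size=(12, 2))
            d = euclid_dm(pts)
            labels = ["a"] * 6 + ["b"] * 6
            res = fm.permanova(d, labels, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        rate = rejections / n_sims
        assert 0.03 <= rate <= 0.07, rate


class TestPosthoc:
    def test_bonferroni_arithmetic(self):
        assert min(1.0, 0.01 * 45) == pytest.approx(0.45)
        assert min(1.0, 0.5 * 3) == 1.0

    def test_pairwise_table(self):
        rng = np.random.default_rng(4)
        pts = np.concatenate(
            [rng.normal(0, 1, (5, 2)), rng.normal(4, 1, (5, 2)), rng.normal(8, 1, (5, 2))]
        )
        d = euclid_dm(pts)
        labels = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5, index=d.taxa)
        out = fm.permanova_posthoc(d, labels, n_perm=199, seed=0)
        assert len(out) == 3
        assert (out["adjusted_p"] >= out["p"] - 1e-12).all()
        assert (out["adjusted_p"] <= 1.0).all()
        tri = posthoc_triangle_table(out)
        assert tri.loc["a", "b"] != "" and tri.loc["b", "a"] != ""

    def test_needs_three_groups(self):
        d = euclid_dm([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ArgumentError):
            fm.permanova_posthoc(d, ["a", "a", "b", "b"])


class TestMantel:
    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(5)
        d = euclid_dm(rng.normal(size=(6, 2)))
        res = fm.mantel(d, d, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_of_24_permutations(self):
        rng = np.random.default_rng(6)
        d1 = euclid_dm(rng.normal(size=(4, 2)))
        d2 = euclid_dm(rng.normal(size=(4, 2)))
        res = fm.mantel(d1, d2, exhaustive=True)
        # independent brute force over all 4! = 24 relabellings
        iu = np.triu_indices(4, 1)
        x = d1.values[iu]
        rs = []
        for perm in itertools.permutations(range(4)):
            B = d2.values[np.ix_(perm, perm)]
            rs.append(np.corrcoef(x, B[iu])[0, 1])
        r_obs = rs[0]  # identity first
        p_ref = np.mean([r >= r_obs - 1e-12 for r in rs])
        assert res.statistic == pytest.approx(r_obs)
        assert res.p_value == pytest.approx(p_ref)
        assert res.n_permutations == 24

    def test_masked_pairs_removed_and_counted(self):
        v1 = np.array(
            [[0, 0.2, 0.4, 0.5], [0.2, 0, 0.3, 0.6], [0.4, 0.3, 0, 0.1], [0.5, 0.6, 0.1, 0]]
        )
        v2 = v1.copy()
        v2[0, 1] = v2[1, 0] = np.nan
        d1, d2 = dissim_from_square(v1), dissim_from_square(v2)
        res = fm.mantel(d1, d2, n_perm=49, seed=0)
        assert res.extra["n_pairs"] == 5
        assert res.statistic == pytest.approx(1.0)

    def test_invariant_to_joint_reordering(self):
        rng = np.random.default_rng(8)
        d1 = euclid_dm(rng.normal(size=(7, 2)))
        d2 = euclid_dm(rng.normal(size=(7, 3)))
        base = fm.mantel(d1, d2, n_perm=9, seed=0).statistic
        order = rng.permutation(7)
        p1 = dissim_from_square(d1.values[np.ix_(order, order)])
        p2 = dissim_from_square(d2.values[np.ix_(order, order)])
        assert fm.mantel(p1, p2, n_perm=9, seed=0).statistic == pytest.approx(base)

    def test_r_matches_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(9)
        d1 = euclid_dm(rng.normal(size=(8, 2)))
        d2 = euclid_dm(rng.normal(size=(8, 2)))
        ours = fm.mantel(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values),
            skbio_distance.DistanceMatrix(d2.values),
            permutations=0,
        )
        assert ours.statistic == pytest.approx(r_ref, rel=1e-10)

    def test_type_i_error_calibrated(self):
        """Independent random matrices: one-sided rejection rate ~5%."""
        rng = np.random.default_rng(77)
        n_sims, rejections = 500, 0
        for _ in range(n_sims):
            d1 = euclid_dm(rng.normal(size=(9, 2)))
            d2 = euclid_dm(rng.normal(size=(9, 2)))
            res = fm.mantel(d1, d2, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        rate = rejections / n_sims
        assert 0.03 <= rate <= 0.07, rate

    def test_too_few_taxa_rejected(self):
        d = euclid_dm([1.0, 2.0])
        with pytest.raises(ArgumentError):
            fm.mantel(d, d)


class TestCorrelateDisparity:
    def test_monotone_transform_gives_rho_one(self):
        x = pd.Series([0.1, 0.3, 0.2, 0.5], index=list("abcd"))
        y = np.exp(3 * x)
        res = fm.correlate_disparity(x, y, method="spearman")
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        y = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        assert fm.correlate_disparity(x, y).statistic == pytest.approx(-1.0)

    def test_nan_groups_dropped_pairwise(self):
        x = pd.Series([0.1, np.nan, 0.2, 0.5, 0.3], index=list("abcde"))
        y = pd.Series([1.0, 2.0, 3.0, 9.0, 4.0], index=list("abcde"))
        res = fm.correlate_disparity(x, y)
        assert res.extra["n_groups"] == 4

    def test_zero_variance_undefined(self):
        x = pd.Series([0.2, 0.2, 0.2], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert math.isnan(fm.correlate_disparity(x, y).statistic)
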