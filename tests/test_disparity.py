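"""Group disparity statistics: means, rarefied ranges, partial disparity."""

import itertools
import math

import numpy as np
import pytest

import floramorph as fm
from floramorph.dissimilarity import ArgumentError
from floramorph.disparity import (
    bootstrap_se_mean_pairwise,
    group_disparity_table,
    range_disparity,
)

from conftest import dissim_from_square


def symmetric(vals):
    v = np.asarray(vals, float)
    return dissim_from_square((v + v.T) / 2 * 0 + np.triu(v, 1) + np.triu(v, 1).T)


class TestMeanPairwise:
    def test_pair_of_two_is_their_d(self):
        d = dissim_from_square([[0, 0.4], [0.4, 0]])
        assert fm.mean_pairwise_disparity(d, ["t0", "t1"]) == pytest.approx(0.4)

    def test_identical_taxa_zero(self):
        d = dissim_from_square(np.zeros((3, 3)))
        assert fm.mean_pairwise_disparity(d, d.taxa) == 0.0

    def test_hand_mean_four_taxa(self):
        v = np.zeros((4, 4))
        pair_d = {(0, 1): 0.1, (0, 2): 0.2, (0, 3): 0.3, (1, 2): 0.1, (1, 3): 0.2, (2, 3): 0.3}
        for (i, j), val in pair_d.items():
            v[i, j] = v[j, i] = val
        d = dissim_from_square(v)
        assert fm.mean_pairwise_disparity(d, d.taxa) == pytest.approx(0.2)

    def test_single_taxon_group_undefined(self):
        d = dissim_from_square(np.zeros((3, 3)))
        assert math.isnan(fm.mean_pairwise_disparity(d, ["t0"]))

    def test_invariant_to_taxon_ordering(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.1, 0.9, size=(5, 5))
        v = np.triu(v, 1)
        d = dissim_from_square(v + v.T)
        base = fm.mean_pairwise_disparity(d, d.taxa)
        for order in itertools.islice(itertools.permutations(d.taxa), 10):
            assert fm.mean_pairwise_disparity(d, list(order)) == pytest.approx(base)


class TestRarefiedRange:
    def test_group_of_two_falls_back_to_plain_r(self):
        d = dissim_from_square([[0, 0.33], [0.33, 0]])
        r, rare, se = fm.rarefied_range_disparity(d, d.taxa, n=10, reps=50, seed=1)
        assert r == rare == pytest.approx(0.33)

    def test_constant_distances_rarefy_to_constant(self):
        v = 0.25 * (1 - np.eye(6))
        d = dissim_from_square(v)
        r, rare, se = fm.rarefied_range_disparity(d, d.taxa, n=3, reps=200, seed=2)
        assert r == pytest.approx(0.25)
        assert rare == pytest.approx(0.25)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_subsample_enumeration(self):
        """Rarefied R at n=3 on 5 taxa equals the mean max over all C(5,3) triples."""
        rng = np.random.default_rng(3)
        v = np.triu(rng.uniform(0.1, 0.9, (5, 5)), 1)
        d = dissim_from_square(v + v.T)
        exact = np.mean(
            [
                max(
                    d.values[i, j]
                    for i, j in itertools.combinations(triple, 2)
                )
                for triple in itertools.combinations(range(5), 3)
            ]
        )
        _, rare, _ = fm.rarefied_range_disparity(d, d.taxa, n=3, reps=8000, seed=4)
        assert rare == pytest.approx(exact, abs=0.01)

    def test_monotone_non_decreasing_in_n(self):
        """Exhaustive expectation of the subsample max grows with n."""
        rng = np.random.default_rng(9)
        v = np.triu(rng.uniform(0.05, 0.95, (6, 6)), 1)
        d = dissim_from_square(v + v.T)
        means = []
        for n in (2, 3, 4, 5, 6):
            vals = [
                max(d.values[i, j] for i, j in itertools.combinations(sub, 2))
                for sub in itertools.combinations(range(6), n)
            ]
            means.append(np.mean(vals))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
        assert means[-1] == pytest.approx(range_disparity(d, d.taxa))

    def test_n_below_two_rejected(self):
        d = dissim_from_square(np.zeros((3, 3)))
        with pytest.raises(ArgumentError):
            fm.rarefied_range_disparity(d, d.taxa, n=1)

    def test_bootstrap_se_of_constant_mean_is_zero(self):
        v = 0.4 * (1 - np.eye(5))
        d = dissim_from_square(v)
        assert bootstrap_se_mean_pairwise(d, d.taxa, reps=100, seed=0) == pytest.approx(0.0)


class TestPartialDisparity:
    def _toy_pcoa(self, coords, taxa=None):
        coords = np.asarray(coords, float)
        coords = coords - coords.mean(axis=0)
        taxa = taxa or [f"t{i}" for i in range(len(coords))]
        lam = (coords**2).sum(axis=0)
        return fm.PCoAResult(
            taxa=taxa,
            coordinates=coords,
            eigenvalues=lam,
            variance_proportion=lam / lam.sum(),
            negative_eigenvalue_mass=0.0,
        )

    def test_single_group_is_total(self):
        p = self._toy_pcoa([[0, 0], [2, 0], [0, 2], [2, 2]])
        out = fm.partial_disparity(p, {"all": p.taxa})
        assert out.loc["all", "pdiv"] == pytest.approx(fm.total_disparity(p))
        assert out.loc["all", "pdiv_pct"] == pytest.approx(100.0)

    def test_mirror_symmetric_groups_equal(self):
        p = self._toy_pcoa([[1, 2], [3, 1], [-1, -2], [-3, -1]])
        out = fm.partial_disparity(p, {"a": ["t0", "t1"], "b": ["t2", "t3"]})
        assert out.loc["a", "pdiv"] == pytest.approx(out.loc["b", "pdiv"])

    def test_hand_computed_integer_configuration(self):
        # 6 points, already centred; PDiv = sum coord^2 / 6 per group
        coords = [[2, 0], [-2, 0], [0, 1], [0, -1], [3, 2], [-3, -2]]
        p = self._toy_pcoa(coords)
        out = fm.partial_disparity(p, {"g1": ["t0", "t1"], "g2": ["t2", "t3"], "g3": ["t4", "t5"]})
        assert out.loc["g1", "pdiv"] == pytest.approx((4 + 4) / 6)
        assert out.loc["g2", "pdiv"] == pytest.approx((1 + 1) / 6)
        assert out.loc["g3", "pdiv"] == pytest.approx((9 + 4 + 9 + 4) / 6)

    def test_non_partition_rejected(self):
        p = self._toy_pcoa([[0, 0], [1, 0], [0, 1]])
        with pytest.raises(ArgumentError):
            fm.partial_disparity(p, {"a": ["t0"], "b": ["t1"]})  # t2 unassigned

    def test_additivity_on_synthetic(self, small_synthetic):
        """Sum of family PDiv equals the total disparity (Foote additivity)."""
        _, resolved, _ = small_synthetic
        d = fm.dissimilarity_matrix(resolved)
        p = fm.pcoa(d)
        fams = resolved.groups("family")
        groups = {g: [t for t in p.taxa if fams[t] == g] for g in fams.unique()}
        out = fm.partial_disparity(p, groups)
        assert out["pdiv"].sum() == pytest.approx(fm.total_disparity(p), abs=1e-10)
        assert out["pdiv_pct"].sum() == pytest.approx(100.0, abs=1e-8)


class TestGroupTable:
    def test_table_columns_and_consistency(self, small_synthetic):
        _, resolved, _ = small_synthetic
        d = fm.dissimilarity_matrix(resolved)
        p = fm.pcoa(d)
        table = group_disparity_table(d, resolved.groups("family"), p=p, reps=50, seed=0)
        assert set(table.columns) >= {
            "n_taxa", "mean_pairwise", "range", "rarefied_range", "pdiv", "pdiv_pct"
        }
        fams = resolved.groups("family")
        for g in table.index:
            members = [t for t in d.taxa if fams[t] == g]
            assert table.loc[g, "mean_pairwise"] == pytest.approx(
                fm.mean_pairwise_disparity(d, members)
            )
            assert table.loc[g, "mean_pairwise"] <= table.loc[g, "range"] + 1e-12
            assert table.loc[g, "rarefied_range"] <= table.loc[g, "range"] + 1e-12
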