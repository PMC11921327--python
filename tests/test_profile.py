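"""Diversity, distances, ordination and permutation statistics."""

import itertools
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from magcom import profile
from magcom.profile import DistanceMatrix
from magcom.types import AbundanceTable

DATA = Path(__file__).parent / "data"


def toy_two_group_matrix():
    """6 samples, two groups of 3: within-group distance 0, between 1."""
    ids = [f"s{i}" for i in range(6)]
    d = np.ones((6, 6))
    d[:3, :3] = 0
    d[3:, 3:] = 0
    np.fill_diagonal(d, 0)
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=ids, name="group")
    return DistanceMatrix(ids, d), groups


@pytest.fixture(scope="module")
def vegan_reference():
    """14-sample Bray-Curtis matrix with results frozen from vegan 2.7
    (adonis2 by="terms" and betadisper type="median")."""
    frame = pd.read_csv(DATA / "bray14_reference.tsv", sep="\t",
                        index_col="sample_id")
    ids = list(frame.index)
    d = DistanceMatrix(ids, frame.to_numpy())
    design = pd.DataFrame(
        {"host": ["a"] * 7 + ["b"] * 7,
         "site": ["x", "y", "z", "x", "y", "z", "x"] * 2},
        index=ids)
    return d, design


class TestAggregateAndAlpha:
    def _table(self):
        values = pd.DataFrame(
            {"g1a": [10.0, 20.0], "g1b": [5.0, 0.0], "g2a": [45.0, 40.0]},
            index=["s1", "s2"])
        unmapped = pd.Series([40.0, 40.0], index=values.index)
        return AbundanceTable(values, unmapped)

    def test_genus_sums_and_conservation(self):
        out = profile.aggregate_phylotypes(
            self._table(), {"g1a": "Gilliamella", "g1b": "Gilliamella",
                            "g2a": "Snodgrassella"})
        assert out.values.loc["s1", "Gilliamella"] == 15.0
        before = self._table().values.sum(axis=1)
        pd.testing.assert_series_equal(out.values.sum(axis=1), before)

    def test_one_mag_per_genus_is_relabeling(self):
        table = self._table()
        out = profile.aggregate_phylotypes(
            table, {"g1a": "A", "g1b": "B", "g2a": "C"})
        assert sorted(out.features) == ["A", "B", "C"]
        np.testing.assert_allclose(
            out.values[["A", "B", "C"]].values, table.values.values)

    def test_unmapped_feature_raises(self):
        with pytest.raises(KeyError):
            profile.aggregate_phylotypes(self._table(), {"g1a": "A"})

    def test_richness(self):
        assert profile.richness([50, 0, 25]) == 2
        assert profile.richness([0, 0]) == 0
        assert profile.richness([0.5, 2], detection=1) == 1

    def test_shannon(self):
        assert profile.shannon([7.0]) == 0.0
        assert profile.shannon([25, 25, 25, 25]) == pytest.approx(math.log(4))
        assert profile.shannon([30, 10, 0]) == pytest.approx(
            profile.shannon([30, 10]))
        with pytest.raises(ValueError):
            profile.shannon([0.0, 0.0])


class TestDistances:
    def test_bray_curtis_examples(self):
        assert profile.bray_curtis([3, 1], [3, 1]) == 0.0
        assert profile.bray_curtis([1, 0], [0, 1]) == 1.0
        assert profile.bray_curtis([1, 0], [0.5, 0.5]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            profile.bray_curtis([0, 0], [0, 0])

    def test_jaccard_examples(self):
        assert profile.jaccard_distance({"x"}, {"x"}) == 0.0
        assert profile.jaccard_distance({"x"}, {"y"}) == 1.0
        assert profile.jaccard_distance({"x", "y"}, {"y", "z"}) == \
            pytest.approx(2 / 3)
        assert profile.jaccard_distance(set(), set()) == 0.0
        assert profile.jaccard_distance([True, False], [True, True]) == 0.5

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=1, max_size=8))
    def test_bray_curtis_bounded(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        if sum(a) + sum(b) == 0:
            return
        assert 0 <= profile.bray_curtis(a, b) <= 1

    def test_matrix_invariants(self, dataset):
        d = profile.bray_curtis_matrix(dataset.abundance)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)
        assert d.values.max() <= 1 + 1e-12


class TestPcoa:
    def test_two_points(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 3.0], [3.0, 0]]))
        coords, eigvals = profile.pcoa(d)
        np.testing.assert_allclose(sorted(coords["PCo1"]), [-1.5, 1.5])

    def test_reconstructs_euclidean_configuration(self):
        rng = np.random.default_rng(7)
        points = rng.normal(size=(9, 2))
        d = DistanceMatrix([f"s{i}" for i in range(9)],
                           squareform(pdist(points)))
        coords, eigvals = profile.pcoa(d)
        rec = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(rec, d.values, atol=1e-8)
        # only 2 meaningful axes for planar points
        assert (eigvals > 1e-8).sum() == 2

    def test_eigenvalue_sum_is_centered_trace(self):
        rng = np.random.default_rng(8)
        x = rng.random((6, 3))
        d = DistanceMatrix([f"s{i}" for i in range(6)],
                           squareform(pdist(x, metric="braycurtis")))
        _, eigvals = profile.pcoa(d)
        g = profile._gower_center(d.values ** 2)
        assert eigvals.sum() == pytest.approx(np.trace(g))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1.0], [0.5, 0]]))


def brute_force_one_way(d: np.ndarray, labels: list) -> tuple[float, float]:
    """Independent PERMANOVA oracle from summed squared distances
    (SS_total = sum_{i<j} d2/n; SS_within = per-group analogue)."""
    n = len(labels)
    d2 = d ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for level in set(labels):
        idx = [i for i, l in enumerate(labels) if l == level]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(set(labels))
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return ss_between / ss_total, f


class TestPermanova:
    def test_toy_exhaustive_p(self):
        d, groups = toy_two_group_matrix()
        res = profile.permanova(d, groups, exhaustive=True)
        assert res.terms[0]["p"] == pytest.approx(0.1)

    def test_toy_sampled_p_within_monte_carlo_error(self):
        d, groups = toy_two_group_matrix()
        res = profile.permanova(d, groups, n_perm=9999, seed=3)
        assert res.terms[0]["p"] == pytest.approx(0.1, abs=0.012)

    def test_label_order_invariance(self, vegan_reference):
        d, design = vegan_reference
        a = profile.permanova(d, design["host"], n_perm=99, seed=5)
        shuffled = design["host"].sample(frac=1.0, random_state=0)
        b = profile.permanova(d, shuffled, n_perm=99, seed=5)
        assert a.terms[0]["F"] == pytest.approx(b.terms[0]["F"])
        assert a.terms[0]["p"] == b.terms[0]["p"]

    def test_r2_and_f_match_brute_force(self):
        rng = np.random.default_rng(12)
        for labels in [["a", "a", "b", "b"], ["a", "a", "a", "b"]]:
            x = rng.random((4, 3))
            d = squareform(pdist(x))
            dm = DistanceMatrix(list("wxyz"), d)
            res = profile.permanova(
                dm, pd.Series(labels, index=list("wxyz"), name="g"),
                n_perm=49, seed=1)
            r2, f = brute_force_one_way(d, labels)
            assert res.terms[0]["r2"] == pytest.approx(r2)
            assert res.terms[0]["F"] == pytest.approx(f)

    def test_r2_partition_sums_to_one(self, vegan_reference):
        d, design = vegan_reference
        res = profile.permanova(d, design, n_perm=9, seed=0)
        total_r2 = sum(t["r2"] for t in res.terms) + \
            res.residual_ss / res.total_ss
        assert total_r2 == pytest.approx(1.0)
        assert all(0 <= t["r2"] <= 1 for t in res.terms)

    def test_sequential_terms_match_vegan(self, vegan_reference):
        """Two-factor sequential SS equals adonis2 by="terms" (frozen)."""
        d, design = vegan_reference
        res = profile.permanova(d, design, n_perm=9, seed=0)
        host, site = res.terms
        assert host["ss"] == pytest.approx(0.149606954710, rel=1e-9)
        assert host["F"] == pytest.approx(1.205650396597, rel=1e-9)
        assert host["r2"] == pytest.approx(0.0944535864246, rel=1e-9)
        assert site["ss"] == pytest.approx(0.193431636295, rel=1e-9)
        assert site["F"] == pytest.approx(0.779412058302, rel=1e-9)
        assert site["r2"] == pytest.approx(0.1221220752168, rel=1e-9)
        assert res.residual_ss == pytest.approx(1.240881727670, rel=1e-9)
        assert res.total_ss == pytest.approx(1.583920318675, rel=1e-9)

    def test_matches_scikit_bio(self, vegan_reference):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        d, design = vegan_reference
        mine = profile.permanova(d, design["host"], n_perm=999, seed=4)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(np.ascontiguousarray(d.values), d.ids),
            design, column="host", permutations=999)
        assert mine.terms[0]["F"] == pytest.approx(
            theirs["test statistic"], rel=1e-9)
        assert mine.terms[0]["p"] == pytest.approx(
            theirs["p-value"], abs=0.05)

    def test_single_group_rejected(self):
        d, _ = toy_two_group_matrix()
        ones = pd.Series(["a"] * 6, index=d.ids, name="g")
        with pytest.raises(ValueError):
            profile.permanova(d, ones)

    def test_exhaustive_matches_sampled_small_n(self):
        rng = np.random.default_rng(21)
        x = rng.random((6, 3))
        d = DistanceMatrix([f"s{i}" for i in range(6)],
                           squareform(pdist(x, metric="braycurtis")))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=d.ids, name="g")
        exact = profile.permanova(d, groups, exhaustive=True).terms[0]["p"]
        sampled = profile.permanova(d, groups, n_perm=9999,
                                    seed=2).terms[0]["p"]
        assert sampled == pytest.approx(exact, abs=0.02)


class TestDispersion:
    def test_identical_samples_zero_dispersion(self):
        d, groups = toy_two_group_matrix()
        res = profile.dispersion_test(d, groups, n_perm=99, seed=0)
        np.testing.assert_allclose(res.distances.to_numpy(), 0.0, atol=1e-8)

    def test_scale_equivariance(self, vegan_reference):
        d, design = vegan_reference
        base = profile.dispersion_test(d, design["host"], n_perm=9, seed=0)
        doubled = profile.dispersion_test(
            DistanceMatrix(d.ids, 2 * d.values), design["host"],
            n_perm=9, seed=0)
        np.testing.assert_allclose(doubled.distances.to_numpy(),
                                   2 * base.distances.to_numpy(), atol=1e-7)

    def test_matches_vegan_betadisper_median(self, vegan_reference):
        d, design = vegan_reference
        res = profile.dispersion_test(d, design["host"], n_perm=999, seed=0)
        expected = [0.141556738704, 0.140314262626, 0.29405009587,
                    0.494088101315, 0.366048184722, 0.352692978453,
                    0.342019801345, 0.146392245971, 0.3704536321,
                    0.359472960852, 0.29016052107, 0.281932617304,
                    0.174418159311, 0.49614188067]
        # vegan's spatial-median optimizer converges to a slightly looser
        # tolerance, hence the 1e-5 agreement band
        np.testing.assert_allclose(res.distances.to_numpy(), expected,
                                   atol=1e-5)
        assert res.f_statistic == pytest.approx(0.00064917391019, rel=1e-4)
        assert res.p_value > 0.5  # dispersions essentially identical

    def test_singleton_group_warns_distance_zero(self):
        ids = ["a", "b", "c"]
        d = DistanceMatrix(ids, np.array([[0, 1, 1], [1, 0, 0.5],
                                          [1, 0.5, 0]]))
        groups = pd.Series(["g1", "g2", "g2"], index=ids, name="g")
        with pytest.warns(UserWarning, match="single sample"):
            res = profile.dispersion_test(d, groups, n_perm=9, seed=0)
        assert res.distances["a"] == 0.0


class TestPairwise:
    def test_three_groups_three_pairs_bonferroni(self, vegan_reference):
        d, design = vegan_reference
        groups = pd.Series((["a"] * 5 + ["b"] * 5 + ["c"] * 4), index=d.ids,
                           name="g")
        table = profile.pairwise_permanova(d, groups, n_perm=99, seed=0)
        assert len(table) == 3
        np.testing.assert_allclose(
            table["p_bonferroni"], np.minimum(1.0, table["p_raw"] * 3))

    def test_matches_single_permanova_on_subset(self, vegan_reference):
        d, design = vegan_reference
        groups = pd.Series((["a"] * 5 + ["b"] * 5 + ["c"] * 4), index=d.ids,
                           name="g")
        table = profile.pairwise_permanova(d, groups, n_perm=99, seed=7)
        ids = [s for s in d.ids if groups[s] in ("a", "c")]
        single = profile.permanova(d.subset(ids), groups.loc[ids].rename("g"),
                                   n_perm=99, seed=7)
        row = table.loc["a vs c"]
        assert row["F"] == pytest.approx(single.terms[0]["F"])
        assert row["p_raw"] == single.terms[0]["p"]
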