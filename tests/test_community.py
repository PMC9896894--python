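import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from paleodecay import (
    CommunityTable,
    relative_abundances,
    group_fractions,
    partition_total_abundance,
    bray_curtis,
    anosim,
    fraction_vs_age_regression,
)
from paleodecay.community import _anosim_r, jaccard


def make_table(counts, groups=None, totals=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"s{i}" for i in range(len(counts))]
    taxa = list(counts.columns)
    groups = groups or {t: "g" for t in taxa}
    return CommunityTable(
        counts=counts,
        taxon_groups=pd.Series(groups),
        total_copies=None if totals is None else pd.Series(
            totals, index=counts.index),
    )


class TestRelativeAbundances:
    def test_simple_fractions(self):
        t = make_table({"a": [8], "b": [2]})
        fr = relative_abundances(t)
        assert fr.iloc[0].tolist() == pytest.approx([0.8, 0.2])

    def test_single_taxon(self):
        fr = relative_abundances(make_table({"a": [7]}))
        assert fr.iloc[0, 0] == 1.0

    def test_random_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = make_table({c: rng.integers(0, 100, 10) for c in "abcde"})
        fr = relative_abundances(t)
        np.testing.assert_allclose(fr.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_sample_excluded_with_warning(self):
        t = make_table({"a": [5, 0], "b": [5, 0]})
        with pytest.warns(UserWarning, match="zero counts"):
            fr = relative_abundances(t)
        assert len(fr) == 1


class TestPartition:
    def test_multiplication(self):
        fr = pd.DataFrame({"diatom": [0.05], "other": [0.95]}, index=["s0"])
        totals = pd.Series([1e9], index=["s0"])
        est = partition_total_abundance(fr, totals)
        assert est.at["s0", "diatom"] == pytest.approx(5e7)

    def test_zero_fraction(self):
        fr = pd.DataFrame({"g": [0.0], "h": [1.0]}, index=["s0"])
        est = partition_total_abundance(fr, pd.Series([1e6], index=["s0"]))
        assert est.at["s0", "g"] == 0.0

    def test_conservation(self):
        rng = np.random.default_rng(1)
        raw = rng.random((8, 4))
        fr = pd.DataFrame(raw / raw.sum(1, keepdims=True),
                          index=[f"s{i}" for i in range(8)])
        totals = pd.Series(rng.uniform(1e6, 1e9, 8), index=fr.index)
        est = partition_total_abundance(fr, totals)
        np.testing.assert_allclose(est.sum(axis=1), totals, rtol=1e-9)

    def test_missing_total_skipped(self):
        fr = pd.DataFrame({"g": [1.0, 1.0]}, index=["s0", "s1"])
        with pytest.warns(UserWarning, match="skipped"):
            est = partition_total_abundance(fr, pd.Series([5.0], index=["s0"]))
        assert list(est.index) == ["s0"]


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = make_table({"a": [3, 6], "b": [1, 2]})  # same composition
        dm = bray_curtis(t)
        assert dm.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_taxa_one(self):
        dm = bray_curtis(make_table({"a": [5, 0], "b": [0, 7]}))
        assert dm.iloc[0, 1] == pytest.approx(1.0)

    def test_three_sample_hand_example(self):
        t = make_table({"a": [6, 2, 0], "b": [2, 2, 4], "c": [2, 6, 6]})
        fr = relative_abundances(t).values
        dm = bray_curtis(t).values

        def hand_bc(x, y):
            return np.abs(x - y).sum() / (x + y).sum()

        for i, j in itertools.combinations(range(3), 2):
            assert dm[i, j] == pytest.approx(hand_bc(fr[i], fr[j]), abs=1e-12)

    def test_depth_invariance_and_bounds(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 50, (6, 8))
        t1 = make_table({f"t{j}": counts[:, j] for j in range(8)})
        t2 = make_table({f"t{j}": counts[:, j] * 10 for j in range(8)})
        dm1, dm2 = bray_curtis(t1).values, bray_curtis(t2).values
        np.testing.assert_allclose(dm1, dm2, atol=1e-12)
        assert np.all((dm1 >= 0) & (dm1 <= 1))
        assert np.allclose(np.diag(dm1), 0)
        np.testing.assert_allclose(dm1, dm1.T)

    def test_jaccard_alternative_metric(self):
        dm = jaccard(make_table({"a": [5, 0], "b": [3, 7], "c": [0, 2]}))
        assert dm.iloc[0, 1] == pytest.approx(2.0 / 3.0)


class TestAnosim:
    def _separated(self):
        # two tight clusters -> all between > all within
        d = np.array([
            [0, .1, .1, .9, .9, .9],
            [.1, 0, .1, .9, .9, .9],
            [.1, .1, 0, .9, .9, .9],
            [.9, .9, .9, 0, .1, .1],
            [.9, .9, .9, .1, 0, .1],
            [.9, .9, .9, .1, .1, 0.]])
        return d, np.array(list("aaabbb"))

    def test_perfect_separation_r_one(self):
        d, g = self._separated()
        res = anosim(d, g, n_permutations=99, seed=0)
        assert res.r_statistic == pytest.approx(1.0)
        assert res.p_value <= 0.11

    def test_all_equal_dissimilarities_r_zero(self):
        d = np.ones((6, 6)) - np.eye(6)
        res = anosim(d, np.array(list("aaabbb")), n_permutations=99, seed=0)
        assert res.r_statistic == pytest.approx(0.0)

    def test_r_matches_skbio(self):
        import skbio

        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        d = np.abs(X[:, None, :] - X[None, :, :]).sum(-1)
        labels = np.array(list("aaaabbbb"))
        ours = anosim(d, labels, n_permutations=99, seed=1)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d), grouping=list(labels), permutations=99)
        assert ours.r_statistic == pytest.approx(ref["test statistic"],
                                                 abs=1e-12)

    def test_p_matches_exhaustive_enumeration(self):
        d, g = self._separated()
        r_obs = _anosim_r(d, g)
        # exact p over all distinct assignments of 3 'a' labels to 6 slots
        rs = []
        for idx in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(idx)] = "a"
            rs.append(_anosim_r(d, lab))
        p_exact = np.mean([r >= r_obs - 1e-12 for r in rs])
        res = anosim(d, g, n_permutations=9999, seed=7)
        assert res.p_value == pytest.approx(p_exact, abs=0.01)

    def test_p_resolution_and_determinism(self):
        d, g = self._separated()
        r1 = anosim(d, g, n_permutations=99, seed=3)
        r2 = anosim(d, g, n_permutations=99, seed=3)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1.0 / 100.0

    def test_singleton_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="'b'"):
            anosim(d, np.array(["a", "a", "b"]), seed=0)


class TestFractionVsAge:
    def test_perfect_positive_trend(self):
        ages = np.arange(1.0, 11.0)
        slope, r2, p = fraction_vs_age_regression(0.01 * ages, ages)
        assert slope == pytest.approx(0.01)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6

    def test_constant_fraction(self):
        slope, r2, p = fraction_vs_age_regression([0.2] * 5, range(5))
        assert slope == 0.0 and r2 == 0.0 and p == 1.0

    def test_zero_age_variance_rejected(self):
        with pytest.raises(ValueError, match="age"):
            fraction_vs_age_regression([0.1, 0.2, 0.3], [1, 1, 1])
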