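"""Dissimilarities, PERMANOVA, PCoA, Shannon, Welch t."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rhizodmm import (
    CountTable,
    bray_curtis,
    jaccard,
    pcoa,
    permanova,
    shannon,
    welch_t,
)
from rhizodmm.diversity import DistanceMatrix


def count_table(rows, ids=None):
    rows = np.atleast_2d(rows)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    cols = [f"t{j}" for j in range(rows.shape[1])]
    return CountTable(pd.DataFrame(rows, index=ids, columns=cols))


class TestDissimilarities:
    def test_bray_curtis_closed_form(self):
        ct = count_table([[6, 0, 2], [2, 2, 2]])
        assert bray_curtis(ct).values[0, 1] == pytest.approx(6 / 14)

    def test_jaccard_closed_form(self):
        # presence sets {0,1,2} vs {1,2,3}: 1 - 2/4
        ct = count_table([[5, 1, 9, 0], [0, 3, 2, 7]])
        assert jaccard(ct).values[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("metric", [bray_curtis, jaccard])
    def test_identical_samples_distance_zero(self, metric):
        ct = count_table([[3, 1, 4], [3, 1, 4]])
        assert metric(ct).values[0, 1] == pytest.approx(0.0)

    @pytest.mark.parametrize("metric", [bray_curtis, jaccard])
    def test_disjoint_supports_distance_one(self, metric):
        ct = count_table([[3, 1, 0, 0], [0, 0, 4, 2]])
        assert metric(ct).values[0, 1] == pytest.approx(1.0)

    @given(st.lists(st.lists(st.integers(0, 50), min_size=4, max_size=4),
                    min_size=3, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_binary_bray_curtis_jaccard_identity(self, rows):
        # J = 2B/(1+B) on presence/absence data
        arr = np.asarray(rows)
        if (arr.sum(axis=1) == 0).any():
            return
        ct = count_table((arr > 0).astype(int))
        B = bray_curtis(ct).values
        J = jaccard(ct).values
        np.testing.assert_allclose(J, 2 * B / (1 + B), atol=1e-12)

    @pytest.mark.parametrize("metric", [bray_curtis, jaccard])
    def test_metric_axioms(self, metric, rng):
        ct = count_table(rng.integers(0, 30, (5, 8)) + (np.arange(8) == 0))
        d = metric(ct).values
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1


class TestPermanova:
    def brute_force_p(self, d, labels):
        """Enumerate all label assignments; p = frac with F >= observed."""
        from rhizodmm.diversity import _enumerate_labels, _permanova_stats

        d2 = d ** 2
        k = len(set(labels))
        lab = np.asarray(labels)
        f_obs, _ = _permanova_stats(d2, lab, k)
        fs = []
        n1 = int((lab == 0).sum())
        for combo in itertools.combinations(range(len(lab)), n1):
            perm = np.ones(len(lab), dtype=int)
            perm[list(combo)] = 0
            fs.append(_permanova_stats(d2, perm, k)[0])
        fs = np.array(fs)
        return float((fs >= f_obs - 1e-12).sum() / fs.size)

    @pytest.fixture
    def six_sample_distance(self, rng):
        ct = count_table(rng.integers(1, 50, (6, 10)))
        return bray_curtis(ct)

    def test_exact_enumeration_matches_brute_force(self, six_sample_distance):
        labels = pd.Series(["a", "a", "a", "b", "b", "b"],
                           index=six_sample_distance.sample_ids)
        res = permanova(six_sample_distance, labels)
        assert res.exact and res.n_permutations == 20
        lab01 = np.array([0, 0, 0, 1, 1, 1])
        assert res.p_value == pytest.approx(
            self.brute_force_p(six_sample_distance.values, lab01))

    def test_matches_skbio_pseudo_f(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        ct = count_table(rng.integers(0, 40, (9, 12)) + 1)
        d = bray_curtis(ct)
        labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        mine = permanova(d, pd.Series(labels, index=d.sample_ids), exact_limit=0)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d.values, d.sample_ids), labels, permutations=99)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_separated_clusters_give_high_r2_and_minimal_p(self):
        a = np.array([[100, 0, 0], [99, 1, 0], [98, 2, 0]])
        b = np.array([[0, 0, 100], [0, 1, 99], [0, 2, 98]])
        d = bray_curtis(count_table(np.vstack([a, b])))
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=d.sample_ids)
        res = permanova(d, labels)
        assert res.r2 > 0.9
        assert res.p_value == pytest.approx(2 / 20)  # observed split and its mirror

    def test_sampled_p_converges_to_enumeration(self, six_sample_distance):
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=six_sample_distance.sample_ids)
        exact = permanova(six_sample_distance, labels)
        sampled = permanova(six_sample_distance, labels, n_perm=9999, seed=4,
                            exact_limit=0)
        assert abs(sampled.p_value - exact.p_value) < 2 / math.sqrt(9999)

    def test_degenerate_groupings_rejected(self, six_sample_distance):
        ids = six_sample_distance.sample_ids
        with pytest.raises(ValueError, match="2 groups"):
            permanova(six_sample_distance, pd.Series(["a"] * 6, index=ids))
        with pytest.raises(ValueError, match="own group"):
            permanova(six_sample_distance, pd.Series(list("abcdef"), index=ids))


class TestPcoa:
    def test_recovers_planted_euclidean_configuration(self, rng):
        pts = rng.normal(size=(7, 2))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix([f"s{i}" for i in range(7)],
                           squareform(pdist(pts)), "custom")
        coords, eigvals = pcoa(d)
        assert (eigvals.iloc[:2] > 0).all()
        # compare via distance matrices (rotation/reflection invariant)
        dd = squareform(pdist(coords.to_numpy()[:, :2]))
        np.testing.assert_allclose(dd, d.values, atol=1e-8)

    def test_equilateral_triangle_two_equal_eigenvalues(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]],
                                                     dtype=float))
        coords, eigvals = pcoa(d)
        assert eigvals.iloc[0] == pytest.approx(eigvals.iloc[1], rel=1e-9)

    def test_matches_skbio_eigenvalues(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        ct = count_table(rng.integers(0, 30, (6, 9)) + 1)
        d = bray_curtis(ct)
        _, eigvals = pcoa(d)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = skbio_ord.pcoa(skbio_dist.DistanceMatrix(d.values, d.sample_ids))
        np.testing.assert_allclose(np.sort(eigvals)[::-1][:5],
                                   np.sort(ref.eigvals)[::-1][:5], atol=1e-8)

    def test_duplicate_sample_at_zero_distance(self):
        ct = count_table([[5, 5, 0], [5, 5, 0], [0, 0, 10]])
        coords, _ = pcoa(bray_curtis(ct))
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)


class TestShannonAndWelch:
    def test_uniform_composition_maximal(self):
        ct = count_table([np.full(10, 7)])
        assert shannon(ct).iloc[0] == pytest.approx(math.log(10), abs=1e-12)

    def test_single_taxon_zero(self):
        ct = count_table([[42, 0, 0]])
        assert shannon(ct).iloc[0] == pytest.approx(0.0)

    def test_half_quarter_quarter(self):
        ct = count_table([[2, 1, 1]])
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert shannon(ct).iloc[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_invariant_to_zero_count_taxa(self):
        h1 = shannon(count_table([[3, 5, 2]])).iloc[0]
        h2 = shannon(count_table([[3, 5, 2, 0, 0]])).iloc[0]
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_welch_matches_hand_formula_and_r(self):
        x, y = np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 6, 8])
        t, df, p = welch_t(x, y)
        vx, vy = x.var(ddof=1) / 4, y.var(ddof=1) / 4
        t_hand = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx ** 2 / 3 + vy ** 2 / 3)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert df == pytest.approx(df_hand, abs=1e-10)
        # frozen values from R t.test(c(1,2,3,4), c(2,4,6,8))
        assert t == pytest.approx(-1.732050807569, abs=1e-10)
        assert df == pytest.approx(4.411764705882, abs=1e-10)
        assert p == pytest.approx(0.151580504845, abs=1e-10)

    def test_same_values_t_zero_p_one(self):
        t, df, p = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_equal_n_equal_variance_matches_pooled_t(self):
        x, y = np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 4, 5])
        from scipy.stats import ttest_ind

        t_w, _, _ = welch_t(x, y)
        t_p = ttest_ind(x, y, equal_var=True).statistic
        assert t_w == pytest.approx(t_p, abs=1e-12)

    def test_zero_variance_both_sides_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_t([2.0, 2.0], [3.0, 3.0])
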