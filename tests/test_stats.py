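"""Classifier, rank-based tests, permutation scheme, ANOVA and PCA."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from xsilence import stats as xst


class TestMedianSplit:
    def test_below_median_is_high(self):
        labels = xst.median_split_labels([-0.4, -0.3, -0.1, 0.0])
        assert list(labels) == ["High", "High", "Low", "Low"]

    def test_degenerate_all_equal_is_all_low(self):
        assert (xst.median_split_labels([0.1] * 6) == "Low").all()

    def test_balanced_without_ties(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=101)
        labels = xst.median_split_labels(z)
        n_high = (labels == "High").sum()
        assert abs(n_high - (101 - n_high)) <= 1


class TestAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
            ([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], 0.0),
            ([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0], 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert xst.auc(scores, np.array(labels, dtype=bool)) == pytest.approx(expected)

    def test_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 5, size=60).astype(float)  # heavy ties
        labels = rng.integers(0, 2, size=60).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert xst.auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_complement_identity(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=50)  # continuous, no ties
        labels = rng.integers(0, 2, size=50).astype(bool)
        labels[:2] = [True, False]
        assert xst.auc(scores, labels) + xst.auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            xst.auc([1.0, 2.0], [True, True])


def rank_sum_enumeration(x, y, alternative):
    """Exhaustive-enumeration oracle for the tie-free rank-sum test."""
    pooled = list(x) + list(y)
    ranks = sps.rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    ws = [sum(combo) for combo in itertools.combinations(ranks, nx)]
    total = len(ws)
    if alternative == "less":
        return sum(w <= w_obs for w in ws) / total
    if alternative == "greater":
        return sum(w >= w_obs for w in ws) / total
    p_less = sum(w <= w_obs for w in ws) / total
    p_greater = sum(w >= w_obs for w in ws) / total
    return min(1.0, 2 * min(p_less, p_greater))


class TestWilcoxonRankSum:
    def test_exact_small_sample(self):
        assert xst.wilcoxon_rank_sum([1, 2], [3, 4], "less") == pytest.approx(1 / 6)

    def test_identical_samples_uninformative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert xst.wilcoxon_rank_sum(x, x, "two_sided") > 0.9

    def test_matches_enumeration_oracle(self):
        """Exact agreement with brute-force enumeration for all tie-free shapes <= 4."""
        rng = np.random.default_rng(6)
        for nx in range(1, 5):
            for ny in range(1, 5):
                for _ in range(3):
                    pooled = rng.choice(100, size=nx + ny, replace=False).astype(float)
                    x, y = pooled[:nx], pooled[nx:]
                    for alt in ("less", "greater", "two_sided"):
                        assert xst.wilcoxon_rank_sum(x, y, alt) == pytest.approx(
                            rank_sum_enumeration(x, y, alt)
                        ), (x, y, alt)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            xst.wilcoxon_rank_sum([], [1.0])

    def test_large_sample_uses_normal_branch(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 50)
        y = rng.normal(1, 1, 50)
        p = xst.wilcoxon_rank_sum(x, y, "less")
        assert p < 0.01


class TestMatchedPermutation:
    def test_degenerate_subsample_has_zero_sd(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(0.2, 0.1, size=45)
        ref = rng.normal(0.0, 0.1, size=45)
        report = xst.matched_permutation_test(scores, scores, ref, n_perm=180, seed=0)
        assert report.n_perm == 180
        assert report.subsample_size == 45
        assert report.sd == 0.0

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError):
            xst.matched_permutation_test([1.0, 2.0], [1.0], [0.0], subsample_size=5)

    def test_monte_carlo_stability(self):
        rng = np.random.default_rng(9)
        large = rng.normal(0.3, 0.2, size=120)
        small = rng.normal(0.3, 0.2, size=30)
        ref = rng.normal(0.0, 0.2, size=100)
        r1 = xst.matched_permutation_test(large, small, ref, n_perm=400, seed=1)
        r2 = xst.matched_permutation_test(large, small, ref, n_perm=400, seed=2)
        pooled_sd = max(r1.sd, r2.sd, 1e-9)
        assert abs(r1.mean - r2.mean) < 4 * pooled_sd / math.sqrt(400)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(10)
        large = rng.normal(size=60)
        small = rng.normal(size=20)
        ref = rng.normal(size=50)
        a = xst.matched_permutation_test(large, small, ref, n_perm=50, seed=3)
        b = xst.matched_permutation_test(large, small, ref, n_perm=50, seed=3)
        assert np.array_equal(a.neglog10_p, b.neglog10_p)


def hypergeom_tail(universe, na, nb, k):
    total = math.comb(universe, nb)
    return sum(
        math.comb(na, i) * math.comb(universe - na, nb - i)
        for i in range(k, min(na, nb) + 1)
    ) / total


class TestHypergeometricOverlap:
    def test_closed_form_example(self):
        assert xst.hypergeometric_overlap(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_zero_overlap_certain(self):
        assert xst.hypergeometric_overlap(100, 30, 20, 0) == pytest.approx(1.0)

    def test_nested_set_certain(self):
        assert xst.hypergeometric_overlap(50, 50, 10, 10) == pytest.approx(1.0)

    def test_matches_tail_sum_on_random_parameters(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            universe = int(rng.integers(5, 200))
            na = int(rng.integers(1, universe + 1))
            nb = int(rng.integers(1, universe + 1))
            k = int(rng.integers(0, min(na, nb) + 1))
            if na + nb - universe > k:  # overlap forced larger than k is fine for sf
                k = max(k, na + nb - universe)
            assert xst.hypergeometric_overlap(universe, na, nb, k) == pytest.approx(
                hypergeom_tail(universe, na, nb, k), rel=1e-9
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            xst.hypergeometric_overlap(10, 5, 4, 5)


class TestAnova:
    def test_null_draw_not_significant(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(0, 1, 40) for _ in range(3)]
        f, p = xst.one_way_anova(groups)
        assert p > 0.01

    def test_separated_means_significant(self):
        f, p = xst.one_way_anova([[1, 2, 3], [101, 102, 103]])
        assert f > 1e3 and p < 1e-6

    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        f, p_f = xst.one_way_anova([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            xst.one_way_anova([[1, 1, 1], [2, 2, 2]])


class TestReplicatePca:
    def test_identical_replicates_coincide(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=30)
        matrix = pd.DataFrame([base, base, base + 1.0])
        scores = xst.replicate_pca(matrix)
        d = np.linalg.norm(scores.iloc[0] - scores.iloc[1])
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(15)
        matrix = pd.DataFrame(rng.normal(size=(6, 40)))
        scores = xst.replicate_pca(matrix).to_numpy()
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * max(1.0, np.abs(gram).max())

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(16)
        matrix = pd.DataFrame(rng.normal(size=(5, 20)))
        a = xst.replicate_pca(matrix)
        b = xst.replicate_pca(matrix)
        pd.testing.assert_frame_equal(a, b)

    def test_component_truncation(self):
        rng = np.random.default_rng(17)
        matrix = pd.DataFrame(rng.normal(size=(3, 10)))
        scores = xst.replicate_pca(matrix, n_components=10)
        assert scores.shape[1] <= 2  # rank of a 3-row centred matrix

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            xst.replicate_pca(pd.DataFrame([[1.0, 2.0]]))


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(18)
    n = 120
    x = rng.uniform(size=n)
    labels = np.where(x > 0.5, "High", "Low")
    features = pd.DataFrame({"signal": x, "noise": rng.uniform(size=n)})
    return features, labels


class TestClassifier:
    def test_separable_feature_gives_unit_auc(self, separable):
        features, labels = separable
        report = xst.train_rf(features, labels, seed=0)
        assert report.auc == pytest.approx(1.0, abs=0.02)
        assert report.importance.idxmax() == "signal"

    def test_importance_sums_to_one(self, separable):
        features, labels = separable
        report = xst.train_rf(features, labels, seed=0)
        assert report.importance.sum() == pytest.approx(1.0)
        assert (report.importance >= 0).all()

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(19)
        n = 500
        features = pd.DataFrame(rng.uniform(size=(n, 5)), columns=list("abcde"))
        labels = np.array(["High", "Low"] * (n // 2))
        rng.shuffle(labels)
        report = xst.train_rf(features, labels, seed=1)
        assert 0.4 <= report.auc <= 0.6

    def test_reproducible_under_seed(self, separable):
        features, labels = separable
        a = xst.train_rf(features, labels, seed=5)
        b = xst.train_rf(features, labels, seed=5)
        assert a.auc == b.auc
        pd.testing.assert_series_equal(a.importance, b.importance)
        pd.testing.assert_series_equal(a.fold_assignment, b.fold_assignment)

    def test_single_class_rejected(self):
        features = pd.DataFrame({"x": np.arange(20, dtype=float)})
        with pytest.raises(ValueError):
            xst.train_rf(features, ["Low"] * 20)

    def test_summary_mentions_parameters(self, separable):
        features, labels = separable
        text = xst.train_rf(features, labels, seed=0).summary()
        assert "trees: 50" in text and "folds: 5" in text

    def test_permutation_importance_option(self, separable):
        features, labels = separable
        report = xst.train_rf(features, labels, seed=0, importance="permutation")
        assert report.importance.idxmax() == "signal"
        assert report.importance.sum() == pytest.approx(1.0)
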