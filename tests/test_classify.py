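"""Rank-sum screening, preprocessing, SVM evaluation and LDA projection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qpicd.classify import (
    MinMaxGamma,
    build_parameter_table,
    lda_project,
    rank_sum_test,
    ranksum_screen,
    significance_stars,
    train_eval_svm,
    two_class_death_classifier,
)
from qpicd.synthetic import FEATURE_NAMES


def enumerate_rank_sum_p(x, y):
    """Independent oracle: exact conditional two-sided p by enumerating
    every assignment of the pooled midranks to group one."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mean = len(pooled) * 0 + n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    def test_small_disjoint_samples_exact_p(self):
        # {1,2,3} vs {4,5,6}: 2 of the 20 assignments are as extreme
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_enumeration_for_small_samples(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(2, 9))
            n2 = int(rng.integers(2, 9))
            x = rng.integers(0, 6, n1).astype(float)  # ties included
            y = rng.integers(0, 6, n2).astype(float)
            assert rank_sum_test(x, y) == pytest.approx(
                enumerate_rank_sum_p(x, y), abs=1e-12
            )

    def test_matches_scipy_for_large_samples(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 35)
        ours = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=0.05)

    def test_null_distribution_rarely_significant(self, rng):
        rejections = 0
        for _ in range(100):
            pooled = rng.normal(0, 1, 40)
            p = rank_sum_test(pooled[:20], pooled[20:])
            rejections += p <= 0.05
        assert rejections <= 10  # p > 0.05 in >= 90 % of null trials

    def test_disjoint_support_highly_significant(self, rng):
        x = rng.uniform(0, 1, 20)
        y = rng.uniform(5, 6, 20)
        assert rank_sum_test(x, y) < 0.001

    def test_all_tied_gives_p_one(self):
        assert rank_sum_test([2.0] * 10, [2.0] * 12) == 1.0

    def test_stars(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == ""


def _param_table(rng, n_per_class=20, separation=3.0):
    rows = []
    for label, shift in [("normal", 0.0), ("apoptotic", separation), ("necrotic", -separation)]:
        for _ in range(n_per_class):
            row = {"track_id": len(rows), "class_label": label}
            for f in FEATURE_NAMES:
                row[f"{f}_A"] = rng.normal(shift, 1.0)
                row[f"{f}_G"] = rng.normal(2.0, 0.3)
                row[f"{f}_AxG"] = row[f"{f}_A"] * row[f"{f}_G"]
            rows.append(row)
    return pd.DataFrame(rows)


class TestScreenAndTable:
    def test_product_column_is_exact(self, rng):
        fits = pd.DataFrame(
            [
                {"track_id": i, "feature": f, "amplitude": rng.normal(),
                 "gain": rng.normal()}
                for i in range(4)
                for f in FEATURE_NAMES
            ]
        )
        labels = pd.DataFrame({"cell_id": range(4), "class_label": ["normal"] * 4})
        table = build_parameter_table(fits, labels)
        for f in FEATURE_NAMES:
            np.testing.assert_array_equal(
                table[f"{f}_AxG"], table[f"{f}_A"] * table[f"{f}_G"]
            )

    def test_screen_orders_separated_columns_first(self, rng):
        table = _param_table(rng)
        out = ranksum_screen(table)
        assert set(out.columns) == {"column", "p_value", "stars"}
        assert (out["p_value"] <= 1).all()
        # amplitudes are separated by construction, gains are not
        top = out.iloc[0]["column"]
        assert top.endswith("_A") or top.endswith("_AxG")

    def test_screen_needs_two_cells_per_class(self, rng):
        table = _param_table(rng, n_per_class=1)
        with pytest.raises(ValueError):
            ranksum_screen(table)


class TestMinMaxGamma:
    def test_gamma_one_is_plain_minmax(self, rng):
        X = rng.normal(0, 2, (30, 3))
        prep = MinMaxGamma(gamma=1.0).fit(X)
        Z = prep.transform(X)
        assert Z.min() == pytest.approx(0.0)
        assert Z.max() == pytest.approx(1.0)

    def test_monotone_for_any_positive_gamma(self, rng):
        X = rng.normal(0, 2, (30, 1))
        for gamma in (0.33, 0.5, 2.0, 3.0):
            Z = MinMaxGamma(gamma=gamma).fit(X).transform(X)
            order = np.argsort(X[:, 0])
            assert np.all(np.diff(Z[order, 0]) >= 0)

    def test_out_of_range_test_values_clipped(self):
        X = np.array([[0.0], [1.0]])
        prep = MinMaxGamma(gamma=2.0).fit(X)
        Z = prep.transform(np.array([[-5.0], [9.0]]))
        assert Z[0, 0] == 0.0 and Z[1, 0] == 1.0

    def test_zero_range_column_constant(self):
        X = np.array([[1.0, 2.0], [1.0, 3.0]])
        Z = MinMaxGamma().fit(X).transform(X)
        assert np.all(Z[:, 0] == 0.5)


class TestTrainEvalSVM:
    def test_separable_clusters_near_perfect(self, rng):
        table = _param_table(rng, n_per_class=20, separation=6.0)
        X = table[["cell_area_A", "circularity_A"]].to_numpy()
        rep = train_eval_svm(X, table["class_label"].to_numpy(), n_splits=30, seed=1)
        assert rep.overall_accuracy >= 0.98

    def test_permuted_labels_at_chance(self, rng):
        table = _param_table(rng, n_per_class=20, separation=6.0)
        X = table[["cell_area_A", "circularity_A"]].to_numpy()
        y = rng.permutation(table["class_label"].to_numpy())
        rep = train_eval_svm(X, y, n_splits=60, seed=1)
        assert abs(rep.overall_accuracy - 1 / 3) <= 0.1

    def test_deterministic_under_seed(self, rng):
        table = _param_table(rng, n_per_class=10)
        X = table[["cell_area_A", "phase_sd_A"]].to_numpy()
        y = table["class_label"].to_numpy()
        a = train_eval_svm(X, y, n_splits=20, seed=9)
        b = train_eval_svm(X, y, n_splits=20, seed=9)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_confusion_rows_sum_to_test_counts(self, rng):
        table = _param_table(rng, n_per_class=20)
        X = table[["cell_area_A"]].to_numpy()
        rep = train_eval_svm(X, table["class_label"].to_numpy(), n_splits=25, seed=2)
        assert np.all(rep.confusion >= 0)
        # 2:1:2 split of 20 -> 8 test cells per class on average
        np.testing.assert_allclose(rep.confusion.sum(axis=1), 8.0)

    def test_small_class_rejected(self, rng):
        table = _param_table(rng, n_per_class=4)
        with pytest.raises(ValueError, match=">= 5"):
            train_eval_svm(
                table[["cell_area_A"]].to_numpy(),
                table["class_label"].to_numpy(),
                n_splits=5,
                seed=0,
            )

    def test_no_information_leak_canary(self, rng):
        """A label-copy column reaches perfect accuracy; a pure-noise column
        stays at chance — preprocessing and tuning must not see test data."""
        n = 60
        y = np.array(["a", "b"] * (n // 2))
        label_col = (y == "a").astype(float)[:, None]
        rep = train_eval_svm(label_col, y, n_splits=25, seed=3)
        assert rep.overall_accuracy == pytest.approx(1.0)
        noise = rng.normal(0, 1, (n, 1))
        rep_noise = train_eval_svm(noise, y, n_splits=60, seed=3)
        assert rep_noise.overall_accuracy <= 0.5 + 0.1

    def test_two_class_death_classifier_separable(self, rng):
        table = _param_table(rng, n_per_class=20, separation=5.0)
        rep = two_class_death_classifier(table, n_splits=30, seed=4)
        assert rep.classes == ["apoptotic", "necrotic"]
        assert rep.overall_accuracy >= 0.9


class TestLDA:
    def test_three_blobs_projected_apart(self, rng):
        X = np.vstack(
            [rng.normal(mu, 0.2, (40, 4)) for mu in ([0] * 4, [4] * 4, [-4, 4, -4, 4])]
        )
        y = np.repeat(["a", "b", "c"], 40)
        coords, loadings = lda_project(X, y)
        assert coords.shape == (120, 2)
        cents = {c: coords[y == c].mean(axis=0) for c in "abc"}
        within = np.mean([coords[y == c].std(axis=0).mean() for c in "abc"])
        for c1, c2 in itertools.combinations("abc", 2):
            assert np.linalg.norm(cents[c1] - cents[c2]) > 5 * within

    def test_identical_distributions_do_not_separate(self, rng):
        X = rng.normal(0, 1, (90, 3))
        y = np.repeat(["a", "b", "c"], 30)
        coords, _ = lda_project(X, y)
        cents = {c: coords[y == c].mean(axis=0) for c in "abc"}
        within = np.mean([coords[y == c].std(axis=0).mean() for c in "abc"])
        for c1, c2 in itertools.combinations("abc", 2):
            assert np.linalg.norm(cents[c1] - cents[c2]) < within

    def test_projection_invariant_to_column_rescaling(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(2, 1, (30, 3))])
        y = np.repeat(["a", "b"], 30)
        c1, _ = lda_project(X, y)
        scale = np.array([3.0, 0.5, 10.0])
        c2, _ = lda_project(X * scale + np.array([1.0, -2.0, 0.0]), y)
        # 1-D projections must agree up to scale and sign
        r = np.corrcoef(c1[:, 0], c2[:, 0])[0, 1]
        assert abs(r) > 0.999

    def test_matches_sklearn_subspace(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.vstack([rng.normal(mu, 1.0, (40, 3)) for mu in ([0] * 3, [3] * 3, [0, 3, 0])])
        y = np.repeat(["a", "b", "c"], 40)
        ours, _ = lda_project(X, y)
        ref = LinearDiscriminantAnalysis(n_components=2).fit_transform(X, y)
        for j in range(2):
            r = abs(np.corrcoef(ours[:, j], ref[:, j])[0, 1])
            assert r > 0.99
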