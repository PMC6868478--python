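import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from cogload.classify import (
    DEFAULT_SHRINKAGE_GRID,
    chance_level,
    crossval_classify,
    majority_class_rate,
    optimize_shrinkage,
    parse_comparison,
    permutation_null,
    rlda_fit,
    rlda_predict,
    rlda_scores,
    transfer_learning,
)
from cogload.features import FeatureTable

from oracles import closed_form_lda_scores, diagonal_lda_predict


def _gaussian_data(rng, means, n_per_class, scale=1.0):
    X, y = [], []
    for label, mu in means.items():
        X.append(rng.standard_normal((n_per_class, len(mu))) * scale + np.asarray(mu))
        y.extend([label] * n_per_class)
    return np.vstack(X), np.array(y)


def _feature_table(X, y, bands=None):
    n_feat = X.shape[1]
    bands = bands or tuple(f"b{i}" for i in range(n_feat))
    return FeatureTable(
        values=X, channels=("c0",), bands=bands, labels=y, participant_id="T",
    )


class TestRldaFit:
    def test_separated_gaussians_classified_perfectly_at_gamma_zero(self):
        rng = np.random.default_rng(0)
        X, y = _gaussian_data(rng, {0: (0, 0), 2: (10, 10)}, 50)
        model = rlda_fit(X, y, shrinkage=0.0)
        assert np.mean(rlda_predict(model, X) == y) == 1.0
        # decision boundary crosses near the midpoint between the means
        scores = rlda_scores(model, np.array([[5.0, 5.0]]))
        assert abs(scores[0, 0] - scores[0, 1]) < 1.0

    def test_gamma_one_equals_diagonal_discriminant_oracle(self):
        rng = np.random.default_rng(1)
        cov_mix = rng.standard_normal((4, 4))
        X, y = _gaussian_data(rng, {0: (0, 0, 0, 0), 1: (1, 0, 1, 0), 2: (0, 2, 0, 1)}, 30)
        X = X @ (np.eye(4) + 0.3 * cov_mix)  # correlated features
        model = rlda_fit(X, y, shrinkage=1.0)
        Xte = rng.standard_normal((40, 4))
        np.testing.assert_array_equal(
            rlda_predict(model, Xte), diagonal_lda_predict(X, y, Xte)
        )

    def test_gamma_zero_matches_textbook_closed_form(self):
        rng = np.random.default_rng(2)
        X, y = _gaussian_data(rng, {0: (0, 1, 0), 1: (1, 0, 2), 2: (2, 2, 0)}, 25)
        model = rlda_fit(X, y, shrinkage=0.0)
        classes, expected = closed_form_lda_scores(X, y, X)
        np.testing.assert_array_equal(model.classes, classes)
        np.testing.assert_allclose(rlda_scores(model, X), expected, atol=1e-8)

    def test_gamma_zero_agrees_with_sklearn_lda_predictions(self):
        rng = np.random.default_rng(3)
        X, y = _gaussian_data(rng, {0: (0, 0, 1), 1: (1, 1, 0), 2: (2, 0, 2)}, 40)
        model = rlda_fit(X, y, shrinkage=0.0)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        np.testing.assert_array_equal(rlda_predict(model, X), sk.predict(X))

    def test_singular_covariance_at_gamma_zero_suggests_shrinkage(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 40))  # fewer trials than features
        y = np.repeat([0, 2], 5)
        with pytest.raises(ValueError, match="shrinkage > 0"):
            rlda_fit(X, y, shrinkage=0.0)
        rlda_fit(X, y, shrinkage=0.5)  # regularized fit succeeds

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            rlda_fit(np.ones((5, 2)), np.zeros(5))
        with pytest.raises(ValueError, match="two trials"):
            rlda_fit(np.ones((3, 2)), np.array([0, 0, 2]))


class TestOptimizeShrinkage:
    def test_tie_breaks_to_smallest_gamma(self):
        rng = np.random.default_rng(5)
        X, y = _gaussian_data(rng, {0: (0, 0), 2: (20, 20)}, 20)  # any gamma wins
        g = optimize_shrinkage(X, y, rng=np.random.default_rng(0))
        assert g == DEFAULT_SHRINKAGE_GRID[0]

    def test_high_dimensional_low_n_selects_positive_gamma(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 40))
        X[:10, 0] += 1.0
        y = np.repeat([0, 2], 10)
        g = optimize_shrinkage(X, y, rng=np.random.default_rng(0))
        assert g > 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            optimize_shrinkage(np.ones((4, 2)), np.repeat([0, 2], 2), grid=())


class TestCrossval:
    def _planted_table(self, rng, effect=1.0, n_per_class=40, n_feat=8):
        X = rng.standard_normal((3 * n_per_class, n_feat))
        y = np.repeat([0, 1, 2], n_per_class)
        X[:, 0] += effect * y  # strong theta-like increase
        X[:, 1] -= effect * y  # alpha-like decrease
        return _feature_table(X, y)

    def test_strong_planted_effects_recovered(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = self._planted_table(rng, effect=2.0)
            res = crossval_classify(table, "0v2", rng=np.random.default_rng(seed))
            accs.append(res.mean_accuracy)
        assert np.mean(accs) >= 0.95

    def test_fold_structure_and_chance(self):
        rng = np.random.default_rng(7)
        table = self._planted_table(rng)
        res = crossval_classify(table, "0v1v2", rng=np.random.default_rng(0))
        assert len(res.fold_accuracies) == 4
        assert res.chance == pytest.approx(1 / 3)
        res2 = crossval_classify(table, "0v2", rng=np.random.default_rng(0))
        assert res2.chance == pytest.approx(0.5)

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 4))
        table = _feature_table(X, np.repeat([0, 1], 10))
        with pytest.raises(ValueError, match="absent"):
            crossval_classify(table, "0v2")

    def test_indivisible_trial_count_trimmed_with_warning(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((42, 4))
        y = np.repeat([0, 2], 21)
        table = _feature_table(X, y)
        with pytest.warns(UserWarning, match="trimmed"):
            res = crossval_classify(table, "0v2", rng=np.random.default_rng(0))
        assert len(res.fold_accuracies) == 4

    def test_permuting_test_labels_changes_accuracy_not_predictions(self):
        # no label leakage: the fitted discriminant is a function of the
        # training partition only
        rng = np.random.default_rng(10)
        X, y = _gaussian_data(rng, {0: (0, 0), 2: (1, 1)}, 40)
        model = rlda_fit(X[:60], y[:60], shrinkage=0.1)
        pred_before = rlda_predict(model, X[60:])
        pred_after = rlda_predict(model, X[60:][::-1][::-1])  # same rows
        np.testing.assert_array_equal(pred_before, pred_after)

    def test_train_equals_test_upper_bounds_crossval(self):
        rng = np.random.default_rng(11)
        diffs = []
        for seed in range(5):
            table = self._planted_table(np.random.default_rng(seed), effect=0.5)
            cv = crossval_classify(table, "0v2", rng=np.random.default_rng(seed),
                                   shrinkage=0.1)
            model = rlda_fit(
                table.values[np.isin(table.labels, (0, 2))],
                table.labels[np.isin(table.labels, (0, 2))],
                shrinkage=0.1,
            )
            mask = np.isin(table.labels, (0, 2))
            train_acc = np.mean(
                rlda_predict(model, table.values[mask]) == table.labels[mask]
            )
            diffs.append(train_acc - cv.mean_accuracy)
        assert np.mean(diffs) >= 0.0

    def test_noise_feature_with_optimized_shrinkage_is_harmless(self):
        drops = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = self._planted_table(rng, effect=1.0, n_feat=4)
            base = crossval_classify(table, "0v2", rng=np.random.default_rng(seed))
            noisy_vals = np.column_stack(
                [table.values, rng.standard_normal(table.n_trials)]
            )
            noisy = _feature_table(noisy_vals, table.labels)
            with_noise = crossval_classify(noisy, "0v2", rng=np.random.default_rng(seed))
            drops.append(base.mean_accuracy - with_noise.mean_accuracy)
        assert np.mean(drops) < 0.05


class TestPermutationNull:
    def test_three_class_null_centers_on_chance(self):
        rng = np.random.default_rng(12)
        table = TestCrossval()._planted_table(rng, effect=1.0, n_per_class=20)
        null = permutation_null(table, "0v1v2", n_perm=30,
                                rng=np.random.default_rng(0))
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean() - 1 / 3) < 3 * max(se, 1e-3)

    def test_single_replicate_reproducible(self):
        rng = np.random.default_rng(13)
        table = TestCrossval()._planted_table(rng, effect=1.0, n_per_class=20)
        a = permutation_null(table, "0v2", n_perm=1, rng=np.random.default_rng(42))
        b = permutation_null(table, "0v2", n_perm=1, rng=np.random.default_rng(42))
        assert a == b


class TestTransfer:
    def _participant(self, rng, sign, pid, n_per_class=30):
        X = rng.standard_normal((2 * n_per_class, 6))
        y = np.repeat([0, 2], n_per_class)
        X[:, 0] += sign * 1.0 * (y / 2)
        X[:, 1] -= sign * 1.0 * (y / 2)
        return FeatureTable(values=X, channels=("c0",),
                            bands=tuple(f"b{i}" for i in range(6)),
                            labels=y, participant_id=pid)

    def test_identical_twins_transfer_like_within(self):
        p1 = self._participant(np.random.default_rng(1), +1, "A")
        p2 = self._participant(np.random.default_rng(1), +1, "B")  # same seed
        accs = transfer_learning([p1, p2], "0v2", suppression="off",
                                 rng=np.random.default_rng(0), shrinkage=0.1)
        # bit-identical participants are exchangeable, and training on the
        # twin equals evaluating a self-trained model on the same data
        assert accs["A"] == accs["B"]
        model = rlda_fit(p1.values, p1.labels, shrinkage=0.1)
        self_acc = float(np.mean(rlda_predict(model, p1.values) == p1.labels))
        assert accs["A"] == self_acc

    def test_homogeneous_population_transfers_above_chance(self):
        tables = [
            self._participant(np.random.default_rng(seed), +1, f"P{seed}")
            for seed in range(6)
        ]
        accs = transfer_learning(tables, "0v2", suppression="off",
                                 rng=np.random.default_rng(0))
        assert np.mean(list(accs.values())) > 0.7

    def test_sign_flipped_population_transfers_near_chance(self):
        tables = [
            self._participant(np.random.default_rng(seed), (-1) ** seed, f"P{seed}")
            for seed in range(6)
        ]
        accs = transfer_learning(tables, "0v2", suppression="off",
                                 rng=np.random.default_rng(0))
        within = [
            crossval_classify(t, "0v2", rng=np.random.default_rng(i)).mean_accuracy
            for i, t in enumerate(tables)
        ]
        transfer_mean = np.mean(list(accs.values()))
        assert np.mean(within) > 0.7
        assert abs(transfer_mean - 0.5) < 0.15
        assert np.mean(within) - transfer_mean > 0.1

    def test_inconsistent_feature_sets_rejected(self):
        p1 = self._participant(np.random.default_rng(0), 1, "A")
        p2 = p1.select(bands=("b0", "b1"))
        with pytest.raises(ValueError, match="inconsistent"):
            transfer_learning([p1, p2])


class TestChance:
    def test_balanced_designs(self):
        assert chance_level(np.repeat([0, 2], 10)) == 0.5
        assert chance_level(np.repeat([0, 1, 2], 10)) == pytest.approx(1 / 3)
        assert chance_level([1, 1, 1]) == 1.0

    def test_majority_rate_under_imbalance(self):
        assert majority_class_rate([0, 0, 0, 2]) == 0.75

    def test_comparison_parsing(self):
        assert parse_comparison("0v2") == (0, 2)
        assert parse_comparison("0v1v2") == (0, 1, 2)
        assert parse_comparison((0, 2)) == (0, 2)
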