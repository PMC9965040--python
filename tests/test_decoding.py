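import numpy as np
import pandas as pd
import pytest

from erpdecode.decoding import (ClassifierSpec, DecodingResult, auroc,
                                balance_training, decode_static,
                                decode_timecourse, default_classifier_specs,
                                derive_seed, evaluate_fold, minmax_scale_apply,
                                minmax_scale_fit, stratified_kfold)


def oddball_labels(n=147, n_rare=23, seed=0):
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, n_rare, replace=False)] = 1
    return y


class TestStratifiedKFold:
    def test_rare_counts_differ_by_at_most_one(self):
        plan = stratified_kfold(oddball_labels(), k=10, seed=1)
        y = oddball_labels()
        rare = [int(y[te].sum()) for _, te in plan.folds]
        assert set(rare) <= {2, 3}
        assert sum(rare) == 23

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(oddball_labels(), k=1, seed=0)

    def test_test_folds_partition_all_trials(self):
        plan = stratified_kfold(oddball_labels(), k=10, seed=3)
        seen = np.concatenate([te for _, te in plan.folds])
        assert sorted(seen) == list(range(147))

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer members"):
            stratified_kfold(oddball_labels(n=30, n_rare=5), k=10, seed=0)


class TestBalanceTraining:
    def test_paper_fold_geometry_yields_66(self, rng):
        X = rng.normal(size=(132, 5))
        y = np.array([0] * 112 + [1] * 20)
        Xb, yb = balance_training(X, y, seed=0)
        assert (yb == 0).sum() == 66 and (yb == 1).sum() == 66

    def test_equal_classes_unchanged_sizes(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        Xb, yb = balance_training(X, y, seed=0)
        assert (yb == 0).sum() == 20 and (yb == 1).sum() == 20

    def test_identical_minority_points_interpolate_to_themselves(self, rng):
        X = np.vstack([rng.normal(size=(30, 2)), np.tile([3.0, -1.0], (4, 1))])
        y = np.array([0] * 30 + [1] * 4)
        Xb, yb = balance_training(X, y, seed=1)
        assert np.allclose(Xb[yb == 1], [3.0, -1.0])

    def test_synthetic_points_lie_on_minority_segments(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.array([0] * 50 + [1] * 10)
        Xb, yb = balance_training(X, y, seed=2)
        minority = X[y == 1]

        def on_some_segment(p):
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    seg = minority[j] - minority[i]
                    t = np.dot(p - minority[i], seg) / np.dot(seg, seg)
                    if -1e-9 <= t <= 1 + 1e-9:
                        proj = minority[i] + t * seg
                        if np.linalg.norm(p - proj) < 1e-9:
                            return True
            return False

        # every balanced minority point is an original or an interpolation
        # between two originals
        assert all(on_some_segment(p) for p in Xb[yb == 1])

    def test_minority_of_one_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 19 + [1])
        with pytest.raises(ValueError):
            balance_training(X, y, seed=0)


class TestMinMaxScaling:
    def test_maps_train_range_to_unit_interval(self):
        scaler = minmax_scale_fit(np.array([[2.0], [4.0]]))
        assert minmax_scale_apply(scaler, np.array([[3.0]]))[0, 0] == 0.5

    def test_constant_feature_maps_to_zero(self):
        scaler = minmax_scale_fit(np.full((5, 2), 7.0))
        out = minmax_scale_apply(scaler, np.full((3, 2), 7.0))
        assert np.all(out == 0.0)

    def test_test_values_not_clipped(self):
        scaler = minmax_scale_fit(np.array([[2.0], [4.0]]))
        assert minmax_scale_apply(scaler, np.array([[5.0]]))[0, 0] == 1.5


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc(np.array([1, 2, 3, 10, 11]),
                     np.array([0, 0, 0, 1, 1])) == 1.0

    def test_all_ties_give_half(self):
        assert auroc(np.ones(10), oddball_labels(10, 3)) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(8, 30)
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, rng.integers(2, n - 2), replace=False)] = 1
            s = np.round(rng.normal(size=n), 1)  # induce ties
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = wins / (len(pos) * len(neg))
            assert auroc(s, y) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = oddball_labels(60, 12)
        s = rng.normal(size=60)
        assert auroc(s, y) == pytest.approx(auroc(np.exp(2 * s + 1), y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(np.arange(5.0), np.zeros(5, dtype=int))


class TestEvaluateFold:
    def test_lda_on_separated_classes_perfect_auroc(self, rng):
        X0 = rng.normal([-5, -5], 0.3, size=(60, 2))
        X1 = rng.normal([5, 5], 0.3, size=(12, 2))
        X = np.vstack([X0, X1])
        y = np.array([0] * 60 + [1] * 12)
        tr = np.arange(0, 72, 2)
        te = np.arange(1, 72, 2)
        rec = evaluate_fold(ClassifierSpec("lda"), X[tr], y[tr], X[te], y[te],
                            seed=0)
        assert rec.auroc == 1.0

    def test_shuffled_labels_decode_at_chance(self, rng):
        X = rng.normal(size=(147, 8))
        y = oddball_labels()
        res = decode_static(X, y, (ClassifierSpec("lda"),), seed=5)
        aucs = res.records["auroc"]
        se = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 3 * se + 0.02

    def test_majority_class_baseline_arithmetic(self):
        # the accuracy-vs-AUROC discrepancy mechanism: a constant
        # frequent-class prediction scores high accuracy but chance AUROC
        y = oddball_labels()
        pred = np.zeros_like(y)
        assert (pred == y).mean() == pytest.approx(124 / 147)
        assert auroc(np.zeros(len(y)), y) == 0.5
        tp = ((pred == 1) & (y == 1)).sum()
        assert tp == 0  # recall is zero

    def test_fit_failure_surfaces_classifier_and_fold(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.tile([0, 0, 0, 1], 10)
        bad = ClassifierSpec("logreg", {"C": -1.0})  # invalid parameter
        with pytest.raises(RuntimeError, match="logreg.*fold 3"):
            evaluate_fold(bad, X[:32], y[:32], X[32:], y[32:], fold=3)


class TestDecodeStatic:
    def test_uninformative_features_near_chance(self):
        X = np.ones((147, 4))
        y = oddball_labels()
        res = decode_static(X, y, (ClassifierSpec("lda"),), seed=0)
        assert res.participant_scores()["auroc"].iloc[0] == pytest.approx(
            0.5, abs=0.05)

    def test_seed_stability_of_mean_auroc(self, rng):
        y = oddball_labels()
        X = rng.normal(size=(147, 6)) + 1.2 * y[:, None]
        means = []
        for seed in (1, 2):
            res = decode_static(X, y, (ClassifierSpec("lda"),), seed=seed)
            means.append(res.records["auroc"].mean())
        assert abs(means[0] - means[1]) < 0.02

    def test_linear_model_beats_tree_on_linear_signal(self, rng):
        # weak linear signal in correlated noise favours high-bias models
        y = oddball_labels(seed=3)
        X = rng.normal(size=(147, 8))
        X[:, 0] += 1.0 * y
        X[:, 1] += 0.8 * y
        specs = default_classifier_specs(("lda", "tree"))
        res = decode_static(X, y, specs, seed=4)
        m = res.records.groupby("classifier")["auroc"].mean()
        assert m["lda"] >= m["tree"]


class TestDecodeTimecourse:
    def test_single_time_point_matches_static_slice(self, rng):
        y = oddball_labels(60, 12)
        values = rng.normal(size=(60, 3, 4))
        specs = (ClassifierSpec("lda"),)
        tc = decode_timecourse(values, y, np.array([0.0, 10.0, 20.0]),
                               specs, seed=9, k=5)
        t = 1
        static = decode_static(values[:, t, :], y, specs,
                               seed=derive_seed(9, t), k=5)
        a = tc.records[tc.records["time_ms"] == 10.0].reset_index(drop=True)
        b = static.records
        assert np.allclose(a["auroc"], b["auroc"])
        assert np.allclose(a["accuracy"], b["accuracy"])

    def test_test_fold_ratio_never_balanced(self):
        # balancing must touch only training folds
        y = oddball_labels()
        plan = stratified_kfold(y, k=10, seed=0)
        for _, te in plan.folds:
            frac = y[te].mean()
            assert 0.1 <= frac <= 0.25  # session ratio ~0.156, never 0.5


class TestLdaClosedFormOracle:
    def test_sklearn_lda_matches_pooled_covariance_discriminant(self, rng):
        # independent reference: w = Sigma_pooled^-1 (mu1 - mu0)
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X = rng.normal(size=(200, 4))
        y = np.repeat([0, 1], 100)
        X[y == 1] += [0.8, -0.4, 0.2, 0.0]
        model = LinearDiscriminantAnalysis().fit(X, y)
        mu0, mu1 = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
        S = ((X[y == 0] - mu0).T @ (X[y == 0] - mu0)
             + (X[y == 1] - mu1).T @ (X[y == 1] - mu1)) / (200 - 2)
        w = np.linalg.solve(S, mu1 - mu0)
        ref_scores = X @ w
        skl_scores = model.decision_function(X)
        assert auroc(skl_scores, y) == pytest.approx(auroc(ref_scores, y))
        assert np.corrcoef(ref_scores, skl_scores)[0, 1] > 0.999999
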