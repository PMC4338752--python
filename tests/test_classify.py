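import itertools

import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

from ecogseg.classify import (
    cross_validate,
    decision_values,
    discretize_quantile,
    ledoit_wolf_cov,
    mrmr_select,
    mutual_information,
    train_rlda,
)
from ecogseg.stats import roc_auc


def plugin_lda_scores(X_train, y_train, X_test):
    """Brute-force plug-in LDA oracle: pooled MLE covariance, no shrinkage."""
    mu_p = X_train[y_train].mean(axis=0)
    mu_n = X_train[~y_train].mean(axis=0)
    Xc = X_train.astype(float).copy()
    Xc[y_train] -= mu_p
    Xc[~y_train] -= mu_n
    S = Xc.T @ Xc / len(Xc)
    w = np.linalg.solve(S, mu_p - mu_n)
    b = -0.5 * w @ (mu_p + mu_n) + np.log(y_train.sum() / (~y_train).sum())
    return X_test @ w + b


def greedy_mrmr_oracle(Xd, y, k):
    """Exhaustive evaluation of the greedy MID criterion on a small set."""
    d = Xd.shape[1]
    rel = [mutual_info_score(Xd[:, j], y) for j in range(d)]
    sel = []
    for _ in range(k):
        best, best_score = None, -np.inf
        for j in range(d):
            if j in sel:
                continue
            red = np.mean([mutual_info_score(Xd[:, j], Xd[:, s]) for s in sel]) if sel else 0.0
            score = rel[j] - red
            if score > best_score + 1e-12:
                best, best_score = j, score
        sel.append(best)
    return sel


class TestMutualInformation:
    def test_matches_sklearn(self, rng):
        for _ in range(20):
            a = rng.integers(0, 3, size=200)
            b = rng.integers(0, 4, size=200)
            assert mutual_information(a, b) == pytest.approx(
                mutual_info_score(a, b), abs=1e-12
            )

    def test_constant_feature_zero_mi(self, rng):
        a = np.zeros(100, dtype=int)
        b = rng.integers(0, 2, size=100)
        assert mutual_information(a, b) == 0.0

    def test_discretization_handles_constant_column(self):
        X = np.column_stack([np.ones(30), np.arange(30.0)])
        Xd = discretize_quantile(X)
        assert len(np.unique(Xd[:, 0])) == 1
        assert len(np.unique(Xd[:, 1])) == 3


class TestMRMR:
    def test_label_copy_ranked_first(self, rng):
        y = rng.integers(0, 2, size=120)
        X = rng.standard_normal((120, 6))
        X[:, 3] = y + 0.001 * rng.standard_normal(120)
        sel = mrmr_select(X, y, k=3)
        assert sel[0] == 3

    def test_duplicate_feature_not_selected_second(self, rng):
        # 4-feature toy set: f0 informative, f1 = copy of f0, f2 weakly
        # informative and non-redundant, f3 noise
        y = rng.integers(0, 2, size=300)
        f0 = y + 0.01 * rng.standard_normal(300)
        f2 = 0.3 * y + rng.standard_normal(300)
        f3 = rng.standard_normal(300)
        X = np.column_stack([f0, f0.copy(), f2, f3])
        sel = mrmr_select(X, y, k=2)
        assert sel[0] == 0
        assert sel[1] != 1
        # cross-check the whole greedy path against the exhaustive oracle
        Xd = discretize_quantile(X)
        assert list(mrmr_select(X, y, k=4)) == greedy_mrmr_oracle(Xd, y, 4)

    def test_k_equals_d_returns_all(self, rng):
        X = rng.standard_normal((50, 5))
        y = rng.integers(0, 2, size=50)
        sel = mrmr_select(X, y, k=5)
        assert sorted(sel) == list(range(5))

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            mrmr_select(rng.standard_normal((20, 3)), rng.integers(0, 2, 20), k=4)


class TestLedoitWolf:
    def test_large_sample_consistency_nonspherical(self):
        # with a non-spherical truth the optimal intensity vanishes as n
        # grows and the shrunk estimate converges to the true covariance
        rng = np.random.default_rng(7)
        D = np.diag([1.0, 2.0, 4.0, 0.5, 3.0])
        X = rng.standard_normal((10000, 5)) @ np.sqrt(D)
        cov, lam = ledoit_wolf_cov(X)
        assert lam < 0.05
        assert np.max(np.abs(cov - D)) < 0.1

    def test_spherical_truth_estimate_near_identity(self):
        # when the truth equals the shrinkage target, lambda is free to be
        # large; what matters is that the estimate lands on the identity
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10000, 5))
        cov, lam = ledoit_wolf_cov(X)
        assert np.max(np.abs(cov - np.eye(5))) < 0.1

    def test_small_sample_shrinks_hard_and_conditions(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((8, 50))
        cov, lam = ledoit_wolf_cov(X)
        assert lam > 0.5
        assert np.linalg.cond(cov) < 1e3

    def test_spherical_covariance_untouched(self):
        # empirical covariance exactly spherical -> target equals S
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        cov, lam = ledoit_wolf_cov(X)
        Xc = X - X.mean(axis=0)
        S = Xc.T @ Xc / len(X)
        np.testing.assert_allclose(cov, S, atol=1e-12)


class TestRLDA:
    def test_separable_gaussians_training_auc(self, rng):
        n = 200
        X = np.concatenate(
            [rng.standard_normal((n, 2)), rng.standard_normal((n, 2)) + 6.0]
        )
        y = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
        model = train_rlda(X, y)
        assert roc_auc(decision_values(model, X), y) >= 0.999

    def test_null_training_auc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((100, 3))
            y = rng.integers(0, 2, size=100).astype(bool)
            if y.sum() < 2 or (~y).sum() < 2:
                continue
            cv = cross_validate(X, y, k_select=None, n_folds=2, seed=seed)
            aucs.append(cv.auc_mean)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_one_dimensional_closed_form(self, rng):
        x_pos = rng.standard_normal(40) + 1.0
        x_neg = rng.standard_normal(40)
        X = np.concatenate([x_pos, x_neg])[:, None]
        y = np.concatenate([np.ones(40, bool), np.zeros(40, bool)])
        model = train_rlda(X, y, shrinkage=0.0)
        mu_p, mu_n = x_pos.mean(), x_neg.mean()
        pooled_var = (
            np.sum((x_pos - mu_p) ** 2) + np.sum((x_neg - mu_n) ** 2)
        ) / len(X)
        assert model.weights[0] == pytest.approx((mu_p - mu_n) / pooled_var, rel=1e-10)

    def test_tiny_class_rejected(self, rng):
        X = rng.standard_normal((4, 2))
        y = np.array([True, False, False, False])
        with pytest.raises(ValueError, match="2 observations"):
            train_rlda(X, y)


class TestCrossValidation:
    def test_separable_data_perfect_auc(self, rng):
        X = np.concatenate(
            [rng.standard_normal((50, 2)), rng.standard_normal((50, 2)) + 8.0]
        )
        y = np.concatenate([np.zeros(50, bool), np.ones(50, bool)])
        cv = cross_validate(X, y, k_select=None, seed=0)
        assert cv.auc_mean == 1.0

    def test_permuted_labels_null(self, rng):
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((120, 8))
            y = np.concatenate([np.zeros(60, bool), np.ones(60, bool)])
            r.shuffle(y)
            aucs.append(cross_validate(X, y, k_select=4, seed=seed).auc_mean)
        assert 0.4 < np.mean(aucs) < 0.6

    def test_full_selection_equals_no_selection(self, rng):
        X = rng.standard_normal((80, 5))
        y = np.concatenate([np.zeros(40, bool), np.ones(40, bool)])
        a = cross_validate(X, y, k_select=5, seed=3)
        b = cross_validate(X, y, k_select=None, seed=3)
        np.testing.assert_allclose(a.fold_scores, b.fold_scores)

    def test_seeded_determinism(self, rng):
        X = rng.standard_normal((60, 6))
        y = np.concatenate([np.zeros(30, bool), np.ones(30, bool)])
        a = cross_validate(X, y, k_select=3, seed=11)
        b = cross_validate(X, y, k_select=3, seed=11)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_array_equal(a.fold_scores, b.fold_scores)
        assert all(
            np.array_equal(s1, s2)
            for s1, s2 in zip(a.selected_per_fold, b.selected_per_fold)
        )

    def test_no_information_leak_from_test_labels(self, rng):
        """Held-out decision values are unchanged when test-fold labels flip:
        selection and training never see the test data."""
        X = rng.standard_normal((60, 6))
        y = np.concatenate([np.zeros(30, bool), np.ones(30, bool)])
        cv = cross_validate(X, y, k_select=3, seed=2)
        # rebuild fold 0 by hand and verify its scores match
        te = cv.fold_assignment == 0
        y_mod = y.copy()
        sel = cv.selected_per_fold[0]
        model = train_rlda(X[~te][:, sel], y_mod[~te], selected=sel)
        np.testing.assert_allclose(
            decision_values(model, X[te][:, sel]), cv.fold_scores[te]
        )

    def test_zero_shrinkage_matches_plugin_oracle(self, rng):
        for d, n in itertools.product((1, 2, 3), (20, 30)):
            X = rng.standard_normal((n, d))
            y = np.concatenate([np.zeros(n // 2, bool), np.ones(n - n // 2, bool)])
            model = train_rlda(X, y, shrinkage=0.0)
            ours = decision_values(model, X)
            oracle = plugin_lda_scores(X, y, X)
            np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_unstratifiable_class_rejected(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.array([True] * 3 + [False] * 9)
        with pytest.raises(ValueError, match="stratify"):
            cross_validate(X, y, k_select=None, n_folds=5)


def test_selected_feature_dump_round_trips(tmp_path, rng):
    import csv

    X = rng.standard_normal((60, 8))  # 2 electrodes x 4 bins
    y = np.concatenate([np.zeros(30, bool), np.ones(30, bool)])
    cv = cross_validate(X, y, k_select=3, seed=5)
    path = tmp_path / "selected.csv"
    from ecogseg.classify import dump_selected_features

    dump_selected_features(cv, path, n_bins=4)
    with open(path) as f:
        rows = list(csv.DictReader(f))
    assert len(rows) == 5 * 3
    first_fold = [r for r in rows if r["fold"] == "0"]
    decoded = [int(r["electrode"]) * 4 + int(r["bin"]) for r in first_fold]
    assert decoded == list(cv.selected_per_fold[0])
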