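"""Lasso-logistic NTCP modelling: solver oracles, penalty selection, repeated CV."""

import warnings

import numpy as np
import pytest

from esotox import modelling
from esotox._lasso import lambda_grid, lasso_logistic_path
from esotox.features import FeatureMatrix, PREDICTOR_CATALOGUE
from esotox.modelling import (
    CVConfig,
    CVIterationResult,
    LassoLogisticNTCP,
    auc,
    brier_and_scaled,
    compare_families,
    lasso_logistic_fit,
    recurrence,
    repeated_cv,
    select_lambda,
)


def logistic_fixture(n=120, p=8, beta=None, intercept=-0.4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    if beta is None:
        beta = np.zeros(p)
        beta[:2] = [1.0, -0.7]
    eta = intercept + X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


def as_feature_matrix(X):
    import pandas as pd

    names = [PREDICTOR_CATALOGUE[i] for i in sorted(PREDICTOR_CATALOGUE)][: X.shape[1]]
    index_map = {i: n for i, n in PREDICTOR_CATALOGUE.items() if n in names}
    return FeatureMatrix(values=pd.DataFrame(X, columns=names), index_map=index_map)


class TestLassoFit:
    def test_full_shrinkage_limit(self):
        X, y = logistic_fixture()
        coef, b0 = lasso_logistic_fit(X, y, lam=10.0)
        assert np.all(coef == 0.0)
        assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-8)

    def test_unpenalized_fit_matches_irls_oracle(self):
        X, y = logistic_fixture(n=200, p=4)
        import statsmodels.api as sm

        oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        coef, b0 = lasso_logistic_fit(X, y, lam=0.0)
        assert np.r_[b0, coef] == pytest.approx(oracle.params, abs=1e-4)

    def test_matches_sklearn_l1_solver_along_path(self):
        from sklearn.linear_model import LogisticRegression

        X, y = logistic_fixture(n=150, p=10)
        grid = lambda_grid(X, y, 30)
        coefs, icpts = lasso_logistic_path(X, y, grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k in (5, 15, 25):
                C = 1.0 / (len(y) * grid[k])
                sk = LogisticRegression(
                    l1_ratio=1.0, C=C, solver="saga", tol=1e-10, max_iter=100000
                ).fit(X, y)
                assert coefs[k] == pytest.approx(sk.coef_[0], abs=2e-4)
                assert icpts[k] == pytest.approx(sk.intercept_[0], abs=2e-4)

    def test_duplicated_predictor_column(self):
        X, y = logistic_fixture(n=150, p=5)
        Xdup = np.column_stack([X, X[:, 0]])
        lam = 0.02
        coef_single, _ = lasso_logistic_fit(X, y, lam)
        coef_dup, _ = lasso_logistic_fit(Xdup, y, lam)
        pair_sum = coef_dup[0] + coef_dup[5]
        assert pair_sum == pytest.approx(coef_single[0], abs=5e-3)

    def test_single_class_outcome_fails(self):
        X, _ = logistic_fixture(n=30)
        with pytest.raises(ValueError):
            lasso_logistic_fit(X, np.ones(30), 0.1)

    def test_nonzero_count_grows_as_penalty_shrinks(self):
        X, y = logistic_fixture(n=150, p=10, seed=3)
        grid = lambda_grid(X, y, 40)
        coefs, _ = lasso_logistic_path(X, y, grid)
        nnz = (coefs != 0).sum(axis=1)
        assert nnz[0] <= 1 and nnz[-1] >= nnz[0]
        # non-increasing in lambda, up to rare single-coefficient swaps
        assert np.all(np.diff(nnz) >= -1)
        assert nnz[-1] == nnz.max()


class TestSelectLambda:
    def test_grid_of_length_one(self):
        X, y = logistic_fixture()
        cfg = CVConfig(lambda_grid=np.array([0.05]))
        assert select_lambda(X, y, cfg) == 0.05

    def test_pure_noise_prefers_strong_shrinkage(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 10))
            y = rng.integers(0, 2, size=80).astype(float)
            if y.min() == y.max():
                continue
            grid = lambda_grid(X, y, 30)
            lam = select_lambda(X, y, CVConfig(lambda_grid=grid, seed=seed))
            if lam >= grid[14]:  # upper (strong-shrinkage) half of the grid
                hits += 1
        assert hits >= 40  # >= 80% of runs

    def test_overwhelming_predictor_survives(self):
        hits = 0
        for seed in range(50):
            beta = np.zeros(8)
            beta[0] = 3.0
            X, y = logistic_fixture(n=120, p=8, beta=beta, seed=seed)
            lam = select_lambda(X, y, CVConfig(seed=seed, n_lambda=30))
            coef, _ = lasso_logistic_fit(X, y, lam)
            if coef[0] != 0:
                hits += 1
        assert hits >= 48  # >= 95% of runs


class TestMetrics:
    def test_auc_examples(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_auc_single_class_fails(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_auc_equals_brute_force_concordance(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 25))
            scores = rng.choice(np.round(rng.uniform(0, 1, 6), 2), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc(scores, labels) == pytest.approx(conc / (len(pos) * len(neg)))

    def test_brier_hand_examples(self):
        assert brier_and_scaled([1.0, 0.0], [1, 0]) == (0.0, 100.0)
        b, s = brier_and_scaled([0.8, 0.3], [1, 0])
        assert b == pytest.approx(0.065)
        assert s == pytest.approx(74.0)
        b, s = brier_and_scaled([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert s == pytest.approx(0.0)  # prevalence model scores 0 by definition

    def test_brier_input_validation(self):
        with pytest.raises(ValueError):
            brier_and_scaled([], [])
        with pytest.raises(ValueError):
            brier_and_scaled([1.2], [1])


class TestRepeatedCV:
    def test_single_iteration_is_bit_reproducible(self):
        fm = as_feature_matrix(logistic_fixture(n=60, p=6)[0])
        y = logistic_fixture(n=60, p=6)[1]
        cfg = CVConfig(n_iterations=1, seed=4, n_lambda=30)
        a = repeated_cv(fm, y, cfg)[0]
        b = repeated_cv(fm, y, cfg)[0]
        assert a == b

    def test_null_labels_give_chance_level_auc(self):
        X, _ = logistic_fixture(n=90, p=10, seed=5)
        rng = np.random.default_rng(5)
        y = rng.permutation([1.0] * 20 + [0.0] * 70)
        cfg = CVConfig(n_iterations=60, seed=5, n_lambda=30)
        res = repeated_cv(as_feature_matrix(X), y, cfg)
        mean_auc = float(np.mean([r.auc_test for r in res]))
        assert 0.40 <= mean_auc <= 0.60

    def test_leakage_guard_perturbing_test_rows_changes_nothing_fitted(self):
        X, y = logistic_fixture(n=80, p=8, seed=6)
        cfg = CVConfig(n_iterations=1, seed=6, n_lambda=30)
        seeds = modelling._iteration_seeds(cfg.seed, 1)
        tr, te = modelling._stratified_split(
            y, cfg.train_fraction, int(seeds[0][0]), True
        )
        Xp = X.copy()
        Xp[te] += 1000.0  # gross corruption of test rows only
        res_clean = repeated_cv(as_feature_matrix(X), y, cfg)[0]
        res_pert = repeated_cv(as_feature_matrix(Xp), y, cfg)[0]
        assert res_clean.chosen_lambda == res_pert.chosen_lambda
        assert res_clean.selected_predictors == res_pert.selected_predictors
        assert res_clean.auc_training == res_pert.auc_training

    def test_families_share_partitions_by_construction(self):
        # split seeds depend only on the master seed and y, so two feature
        # matrices of different width see identical train/test partitions
        y = logistic_fixture(n=70)[1]
        s1 = modelling._iteration_seeds(11, 5)
        s2 = modelling._iteration_seeds(11, 5)
        assert np.array_equal(s1, s2)
        for it in range(5):
            tr1, te1 = modelling._stratified_split(y, 0.75, int(s1[it][0]), True)
            tr2, te2 = modelling._stratified_split(y, 0.75, int(s2[it][0]), True)
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)


class TestComparison:
    def make_result(self, it, auc_t, selected=(1, 2)):
        return CVIterationResult(
            iteration=it, auc_training=auc_t + 0.1, auc_test=auc_t,
            brier_test=0.2, scaled_brier_test=10.0,
            selected_predictors=tuple(selected), chosen_lambda=0.05,
        )

    def test_recurrence_hand_tally(self):
        results = [
            self.make_result(0, 0.7, (1, 3)),
            self.make_result(1, 0.7, (3,)),
            self.make_result(2, 0.7, (1, 3, 50)),
        ]
        assert recurrence(results) == {1: 2, 3: 3, 50: 1}
        assert recurrence([]) == {}

    def test_identical_families_give_null_comparison(self):
        results = [self.make_result(i, 0.7) for i in range(10)]
        report = compare_families(results, list(results))
        assert report.auc_test_ttest == (0.0, 1.0)

    def test_uniform_shift_detected(self):
        base = [self.make_result(i, 0.65 + 0.001 * (i % 7)) for i in range(40)]
        shifted = [self.make_result(i, r.auc_test + 0.05) for i, r in enumerate(base)]
        report = compare_families(shifted, base)
        assert report.summary["with_tag"]["auc_test"][0] > report.summary[
            "without_tag"
        ]["auc_test"][0]
        assert report.auc_test_ttest[1] < 1e-6

    def test_unpaired_inputs_fail(self):
        results = [self.make_result(i, 0.7) for i in range(3)]
        with pytest.raises(ValueError):
            compare_families(results, results[:2])


class TestEstimator:
    def test_sklearn_protocol(self):
        X, y = logistic_fixture(n=100, p=6)
        est = LassoLogisticNTCP(penalty=0.05)
        assert est.get_params()["penalty"] == 0.05
        est.fit(X, y)
        assert est.coef_.shape == (6,)
        proba = est.predict_proba(X)
        assert proba.shape == (100, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(np.unique(est.predict(X))) <= {0.0, 1.0}

    def test_auto_penalty_selection(self):
        X, y = logistic_fixture(n=100, p=6)
        est = LassoLogisticNTCP(penalty="auto", n_lambda=20, random_state=1).fit(X, y)
        assert est.lambda_ > 0

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = LassoLogisticNTCP(penalty=0.1, inner_folds=5)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
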