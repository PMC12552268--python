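"""Solver correctness: softmax, objective, lambda_max, oracle equivalence, CV."""

import numpy as np
import pytest

import dplasso as dp
from dplasso.solver import multinomial_deviance

from _oracles import fista_multinomial, objective as oracle_objective, random_instance
from conftest import balanced_labels


def _unit(p):
    return dp.DPWeightSet.unit(p)


class TestSoftmax:
    def test_zero_fit_is_uniform(self):
        fit = dp.MultinomialFit(np.zeros(4), np.zeros((4, 3)), 0.1, 1.0)
        assert np.allclose(dp.softmax_probabilities(fit, np.ones(3)), 0.25)

    def test_shift_invariance(self, rng):
        eta = rng.standard_normal(5)
        f1 = dp.MultinomialFit(eta, np.zeros((5, 2)), 0.0, 1.0)
        f2 = dp.MultinomialFit(eta + 7.3, np.zeros((5, 2)), 0.0, 1.0)
        x = rng.standard_normal(2)
        assert np.allclose(
            dp.softmax_probabilities(f1, x), dp.softmax_probabilities(f2, x)
        )

    def test_two_class_log_odds(self):
        fit = dp.MultinomialFit(np.array([0.0, np.log(3.0)]), np.zeros((2, 1)), 0.0, 1.0)
        assert np.allclose(dp.softmax_probabilities(fit, np.zeros(1)), [0.25, 0.75])

    def test_overflow_safe_under_extreme_eta(self):
        # without max-subtraction exp(800) overflows; probabilities must stay
        # finite, non-negative and normalized
        fit = dp.MultinomialFit(np.array([800.0, -800.0, 0.0]), np.zeros((3, 1)), 0.0, 1.0)
        pi = dp.softmax_probabilities(fit, np.zeros(1))
        assert np.all(np.isfinite(pi)) and np.all(pi >= 0)
        assert pi.sum() == pytest.approx(1.0)
        mild = dp.MultinomialFit(np.array([30.0, -30.0, 0.0]), np.zeros((3, 1)), 0.0, 1.0)
        assert np.all(dp.softmax_probabilities(mild, np.zeros(1)) > 0)


class TestObjective:
    def test_null_fit_balanced_classes_gives_log_k(self):
        K, n = 3, 10
        y = np.repeat(np.arange(K), n)
        X = np.random.default_rng(0).standard_normal((K * n, 2))
        data = dp.LabeledDataset(X=X, y=y)
        fit = dp.MultinomialFit(np.zeros(K), np.zeros((K, 2)), 0.5, 1.0)
        assert dp.penalized_objective(fit, data, _unit(2)) == pytest.approx(np.log(K))

    def test_lambda_zero_is_pure_loss(self, rng):
        X, y = random_instance(rng, 30, 2, 3)
        data = dp.LabeledDataset(X=X, y=y)
        fit = dp.fit_at_lambda(data, _unit(2), 0.0, standardize=False, tol=1e-10)
        loss = 0.5 * multinomial_deviance(fit, X, y)
        assert dp.penalized_objective(fit, data, _unit(2)) == pytest.approx(loss)

    def test_matches_direct_formula(self, rng):
        X, y = random_instance(rng, 12, 2, 3)
        data = dp.LabeledDataset(X=X, y=y)
        w = dp.DPWeightSet("UNIT", np.ones(2), np.array([0.5, 2.0]))
        fit = dp.fit_at_lambda(data, w, 0.08, alpha=0.7, standardize=False)
        Y = np.zeros((12, 3))
        Y[np.arange(12), y] = 1.0
        theta = np.hstack([fit.intercepts[:, None], fit.coef])
        ref = oracle_objective(theta, X, Y, 0.08, 0.7, w.weight)
        assert dp.penalized_objective(fit, data, w) == pytest.approx(ref, abs=1e-8)


class TestLambdaMax:
    def test_null_model_at_and_above(self, rng):
        X, y = random_instance(rng, 80, 5, 3)
        data = dp.LabeledDataset(X=X, y=y)
        lm = dp.lambda_max(data, _unit(5))
        fit_hi = dp.fit_at_lambda(data, _unit(5), 1.01 * lm, tol=1e-10)
        assert fit_hi.n_selected == 0
        fit_lo = dp.fit_at_lambda(data, _unit(5), 0.99 * lm, tol=1e-10)
        assert fit_lo.n_selected >= 1

    def test_intercepts_reproduce_class_frequencies(self, rng):
        X, y = random_instance(rng, 90, 3, 3)
        data = dp.LabeledDataset(X=X, y=y)
        lm = dp.lambda_max(data, _unit(3))
        fit = dp.fit_at_lambda(data, _unit(3), 1.5 * lm, tol=1e-12)
        freq = np.bincount(y) / len(y)
        expect = np.log(freq) - np.log(freq).mean()
        assert np.allclose(fit.intercepts, expect, atol=1e-5)

    def test_doubling_weights_halves_lambda_max(self, rng):
        X, y = random_instance(rng, 50, 4, 3)
        data = dp.LabeledDataset(X=X, y=y)
        w1 = dp.DPWeightSet("UNIT", np.ones(4), np.array([0.5, 1.0, 2.0, 1.5]))
        w2 = dp.DPWeightSet("UNIT", np.ones(4), 2 * np.array([0.5, 1.0, 2.0, 1.5]))
        assert dp.lambda_max(data, w1) == pytest.approx(2 * dp.lambda_max(data, w2))

    def test_all_zero_weights_rejected(self, rng):
        X, y = random_instance(rng, 30, 2, 3)
        data = dp.LabeledDataset(X=X, y=y)
        with pytest.raises(ValueError):
            dp.lambda_max(data, dp.DPWeightSet("UNIT", np.ones(2), np.zeros(2)))


class TestOracleEquivalence:
    """Coordinate descent agrees with an accelerated proximal-gradient solver
    minimizing the identical penalized objective."""

    def test_twenty_random_instances(self, rng):
        for trial in range(20):
            N = int(rng.integers(40, 81))
            p = int(rng.integers(2, 7))
            K = int(rng.integers(2, 5))
            X, y = random_instance(rng, N, p, K)
            alpha = [1.0, 0.5][trial % 2]
            w = rng.uniform(0.2, 3.0, p)
            if trial % 4 == 0:
                w[0] = 0.0  # an unpenalized feature
            lam = float(rng.uniform(0.02, 0.2))
            data = dp.LabeledDataset(X=X, y=y)
            ws = dp.DPWeightSet("UNIT", w.copy(), w.copy())
            fit = dp.fit_at_lambda(data, ws, lam, alpha=alpha,
                                   standardize=False, tol=1e-13)
            b0, B0 = fista_multinomial(X, y, K, lam, alpha, w)
            Y = np.zeros((N, K))
            Y[np.arange(N), y] = 1.0
            f_cd = oracle_objective(
                np.hstack([fit.intercepts[:, None], fit.coef]), X, Y, lam, alpha, w
            )
            f_or = oracle_objective(np.hstack([b0[:, None], B0]), X, Y, lam, alpha, w)
            assert f_cd <= f_or + 1e-6
            # the softmax is invariant to a per-feature shift across classes
            # and for even K the L1 penalty is flat along part of that
            # direction, so compare the shift-invariant class contrasts
            d_cd = fit.coef - fit.coef.mean(axis=0, keepdims=True)
            d_or = B0 - B0.mean(axis=0, keepdims=True)
            assert np.abs(d_cd - d_or).max() < 1e-4

    def test_excluded_features_stay_zero(self, rng):
        X, y = random_instance(rng, 60, 4, 3)
        data = dp.LabeledDataset(X=X, y=y)
        w = dp.DPWeightSet("UNIT", np.ones(4), np.array([1.0, np.inf, 1.0, np.inf]))
        fit = dp.fit_at_lambda(data, w, 0.01)
        assert np.all(fit.coef[:, [1, 3]] == 0.0)

    def test_unpenalized_feature_has_larger_coefficients(self, rng):
        X, y = random_instance(rng, 70, 3, 3)
        data = dp.LabeledDataset(X=X, y=y)
        lam = 0.05
        w_pen = dp.DPWeightSet("UNIT", np.ones(3), np.ones(3))
        w_free = dp.DPWeightSet("UNIT", np.ones(3), np.array([0.0, 1.0, 1.0]))
        f_pen = dp.fit_at_lambda(data, w_pen, lam, standardize=False, tol=1e-12)
        f_free = dp.fit_at_lambda(data, w_free, lam, standardize=False, tol=1e-12)
        norm_pen = np.abs(f_pen.coef[:, 0]).sum()
        norm_free = np.abs(f_free.coef[:, 0] - f_free.coef[:, 0].mean()).sum()
        assert norm_free > norm_pen

    def test_kkt_conditions_at_convergence(self, rng):
        X, y = random_instance(rng, 60, 5, 3)
        data = dp.LabeledDataset(X=X, y=y)
        lam, alpha = 0.05, 1.0
        fit = dp.fit_at_lambda(data, _unit(5), lam, alpha=alpha,
                               standardize=False, tol=1e-13)
        P = fit.predict_proba(X)
        Y = np.zeros_like(P)
        Y[np.arange(len(y)), y] = 1.0
        G = X.T @ (P - Y) / len(y)  # (p, K)
        for j in range(5):
            for k in range(3):
                g = G[j, k]
                bkj = fit.coef[k, j]
                if bkj != 0:
                    assert abs(g + lam * alpha * np.sign(bkj)) < 1e-6
                else:
                    assert abs(g) <= lam * alpha + 1e-6


class TestPath:
    def test_single_lambda_path_is_null_model(self, rng):
        X, y = random_instance(rng, 50, 4, 3)
        data = dp.LabeledDataset(X=X, y=y)
        path = dp.fit_path(data, _unit(4), n_lambda=1)
        assert len(path.fits) == 1
        assert path.fits[0].n_selected == 0
        assert path.lambdas[0] == pytest.approx(path.lambda_max)

    def test_selection_grows_down_the_path(self, rng):
        X, y = random_instance(rng, 80, 6, 3, signal=1.5)
        data = dp.LabeledDataset(X=X, y=y)
        path = dp.fit_path(data, _unit(6), n_lambda=30)
        assert path.fits[-1].n_selected >= path.fits[0].n_selected

    def test_warm_start_matches_cold_fit(self, rng):
        X, y = random_instance(rng, 60, 5, 3, signal=1.0)
        data = dp.LabeledDataset(X=X, y=y)
        path = dp.fit_path(data, _unit(5), n_lambda=25, tol=1e-15)
        mid = len(path.lambdas) // 2
        lam = float(path.lambdas[mid])
        cold = dp.fit_at_lambda(data, _unit(5), lam, tol=1e-15)
        scale = max(1.0, np.abs(cold.coef).max())
        assert np.abs(path.fits[mid].coef - cold.coef).max() < 1e-6 * scale


class TestCrossValidation:
    def test_reproducible_given_seed(self, rng):
        X, y = random_instance(rng, 80, 5, 3, signal=1.2)
        data = dp.LabeledDataset(X=X, y=y)
        cv1 = dp.cross_validate(data, _unit(5), nfolds=4, seed=7, n_lambda=30)
        cv2 = dp.cross_validate(data, _unit(5), nfolds=4, seed=7, n_lambda=30)
        assert cv1.lambda_min == cv2.lambda_min
        assert np.array_equal(cv1.fold_assignment, cv2.fold_assignment)
        assert np.allclose(cv1.mean_deviance, cv2.mean_deviance)
        assert np.allclose(cv1.selected_fit.coef, cv2.selected_fit.coef)

    def test_pure_noise_selects_almost_nothing(self, rng):
        N, p, K = 120, 10, 3
        y = balanced_labels(rng, N, K)
        X = rng.standard_normal((N, p))
        data = dp.LabeledDataset(X=X, y=y)
        cv = dp.cross_validate(data, _unit(p), nfolds=5, seed=1, n_lambda=40)
        assert cv.selected_fit.n_selected <= 3
        pred = dp.predict_classes(cv.selected_fit, X)
        chance = 1 - np.bincount(y).max() / N
        assert dp.misclassification_rate(pred, y) <= chance + 0.15

    def test_one_se_rule_is_sparser(self, rng):
        design = dp.SimulationDesign(K=4, p=40, N=300, kappa=0.5, seed=5)
        data, _ = dp.simulate_dataset(design)
        w = _unit(40)
        cv_min = dp.cross_validate(data, w, nfolds=5, seed=3, rule="min")
        cv_1se = dp.cross_validate(data, w, nfolds=5, seed=3, rule="1se")
        assert cv_1se.lambda_1se >= cv_min.lambda_min
        assert (
            cv_1se.path.fit_at(cv_1se.lambda_1se).n_selected
            <= cv_min.selected_fit.n_selected
        )

    def test_stratified_folds_reduce_for_small_classes(self, rng):
        y = np.array([0] * 20 + [1] * 20 + [2] * 3)
        X = rng.standard_normal((43, 3))
        data = dp.LabeledDataset(X=X, y=y)
        with pytest.warns(RuntimeWarning, match="reducing folds"):
            cv = dp.cross_validate(data, _unit(3), nfolds=10, seed=0, n_lambda=10)
        assert cv.nfolds == 3


class TestPrediction:
    def test_misclassification_extremes_and_fraction(self):
        truth = np.arange(30) % 3
        assert dp.misclassification_rate(truth, truth) == 0.0
        assert dp.misclassification_rate((truth + 1) % 3, truth) == 1.0
        pred = truth.copy()
        pred[:3] = (pred[:3] + 1) % 3
        assert dp.misclassification_rate(pred, truth) == pytest.approx(0.1)

    def test_ties_break_to_smaller_class_index(self):
        fit = dp.MultinomialFit(np.zeros(3), np.zeros((3, 2)), 0.0, 1.0)
        assert dp.predict_classes(fit, np.zeros((4, 2))).tolist() == [0, 0, 0, 0]

    def test_column_mismatch_rejected(self):
        fit = dp.MultinomialFit(np.zeros(3), np.zeros((3, 2)), 0.0, 1.0)
        with pytest.raises(ValueError):
            fit.predict_proba(np.zeros((2, 5)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dp.misclassification_rate(np.zeros(3), np.zeros(4))
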