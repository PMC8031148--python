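"""PCA regression recipe: basis, scores, AIC selection, prediction, PRESS, patterns."""

import numpy as np
import pytest

from ssmbench.ssm_core import (
    PcBasis,
    derive_pattern,
    expression_scores,
    fit_pca,
    fit_ssm,
    predict,
    press,
    select_n_aic,
    variance_spectrum,
)


def _toy_regression(seed=0, n_vars=40, n_obs=60, n_signal=2, noise=0.05):
    """Data whose outcome is linear in its own leading PC scores plus covariates."""
    rng = np.random.default_rng(seed)
    comps = np.linalg.qr(rng.standard_normal((n_vars, n_signal)))[0]
    latent = rng.standard_normal((n_obs, n_signal)) * [4.0, 2.0][:n_signal]
    data = comps @ latent.T + 0.1 * rng.standard_normal((n_vars, n_obs))
    cov = rng.standard_normal((n_obs, 3))
    scores = expression_scores(data, fit_pca(data), n_signal)
    y = scores @ np.arange(1, n_signal + 1) + cov @ [0.5, -0.3, 0.2]
    y = y + noise * rng.standard_normal(n_obs)
    return data, y, cov


class TestFitPca:
    def test_rank_one_data_recovers_direction(self):
        x = np.array([1.0, -2.0, 3.0])
        data = np.column_stack([x, np.zeros(3)])
        basis = fit_pca(data)
        v1 = basis.V[:, 0]
        assert abs(abs(v1 @ x) - np.linalg.norm(x)) < 1e-10

    def test_orthonormal_basis(self):
        rng = np.random.default_rng(1)
        basis = fit_pca(rng.standard_normal((50, 30)))
        gram = basis.V.T @ basis.V
        assert np.max(np.abs(gram - np.eye(gram.shape[0]))) < 1e-8
        assert np.all(np.diff(basis.eigenvalues) <= 1e-12)

    def test_two_variable_eigenvalues_match_closed_form(self):
        rng = np.random.default_rng(2)
        data = np.linalg.cholesky([[2.0, 0.8], [0.8, 1.0]]) @ rng.standard_normal((2, 5000))
        basis = fit_pca(data, remove_mean=True)
        xc = data - data.mean(axis=1, keepdims=True)
        cov = xc @ xc.T / data.shape[1]
        tr, det = cov[0, 0] + cov[1, 1], cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
        disc = np.sqrt(tr**2 - 4 * det)
        expected = np.array([(tr + disc) / 2, (tr - disc) / 2])  # 2x2 quadratic formula
        np.testing.assert_allclose(basis.eigenvalues, expected, rtol=1e-8)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_pca(np.zeros((4, 4)))


class TestExpressionScores:
    def test_unit_component_projects_to_one(self):
        rng = np.random.default_rng(3)
        basis = fit_pca(rng.standard_normal((20, 10)))
        scores = expression_scores(basis.V[:, [0]], basis, 1)
        assert scores[0, 0] == pytest.approx(1.0)

    def test_zero_components_gives_empty_matrix(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((10, 6))
        basis = fit_pca(data)
        assert expression_scores(data, basis, 0).shape == (6, 0)

    def test_training_scores_match_svd_identity(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((30, 12))
        basis = fit_pca(data)
        scores = expression_scores(data, basis, basis.rank)
        _, s, vt = np.linalg.svd(data, full_matrices=False)
        np.testing.assert_allclose(np.abs(scores), np.abs((vt.T * s)), atol=1e-8)

    def test_variable_mismatch_raises(self):
        basis = fit_pca(np.random.default_rng(6).standard_normal((10, 5)))
        with pytest.raises(ValueError, match="mismatch"):
            expression_scores(np.zeros((9, 5)), basis, 1)


class TestFitSsm:
    def test_noiseless_linear_outcome_fits_exactly(self):
        data, y, cov = _toy_regression(noise=0.0)
        model = fit_ssm(data, y, cov, n=2)
        resid = y - predict(data, cov, model)
        assert np.max(np.abs(resid)) < 1e-8

    def test_intercept_only_outcome(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((15, 25))
        cov = rng.standard_normal((25, 3))
        y = np.full(25, 4.2)
        model = fit_ssm(data, y, cov, n=3)
        assert np.max(np.abs(model.beta[:-1])) < 1e-8
        assert model.beta[-1] == pytest.approx(4.2)

    def test_matches_independent_normal_equations(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((4, 6))
        y = rng.standard_normal(6)
        cov = rng.standard_normal((6, 1))
        model = fit_ssm(data, y, cov, n=1)
        basis = fit_pca(data)
        X = np.column_stack([expression_scores(data, basis, 1), cov, np.ones(6)])
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(model.beta, expected, atol=1e-8)

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((10, 20))
        cov = np.ones((20, 2))  # both collinear with the intercept
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_ssm(data, rng.standard_normal(20), cov, n=1)

    def test_missing_outcomes_excluded_from_regression_only(self):
        data, y, cov = _toy_regression(noise=0.0)
        y2 = y.copy()
        y2[:5] = np.nan
        model = fit_ssm(data, y2, cov, n=2)
        # same answer as fitting on the reduced rows with the full-data basis
        basis = fit_pca(data)
        ref = fit_ssm(data[:, 5:], y[5:], cov[5:], n=2, basis=basis)
        np.testing.assert_allclose(model.beta, ref.beta, atol=1e-8)

    def test_reference_model_equals_plain_covariate_regression(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((8, 30))
        cov = rng.standard_normal((30, 3))
        y = cov @ [1.0, 2.0, -1.0] + rng.standard_normal(30)
        model = fit_ssm(data, y, cov, n=0)
        X = np.column_stack([cov, np.ones(30)])
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(model.beta, expected, atol=1e-8)


class TestSelectN:
    def test_matches_exhaustive_aic_scan(self):
        data, y, cov = _toy_regression(seed=11)
        basis = fit_pca(data)
        chosen, aics = select_n_aic(data, y, cov, n_max=10, basis=basis, return_aic=True)
        # independent scan: plain OLS per candidate, AIC formula re-derived
        scores = expression_scores(data, basis, 10)
        expected = []
        for n in range(1, 11):
            X = np.column_stack([scores[:, :n], cov, np.ones(y.size)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            rss = np.sum((y - X @ beta) ** 2)
            k = n + cov.shape[1] + 1 + 1
            expected.append(y.size * np.log(rss / y.size) + 2 * k)
        np.testing.assert_allclose(aics, expected, atol=1e-8)
        assert chosen == int(np.argmin(expected)) + 1

    def test_recovers_true_component_count(self):
        # AIC never under-selects a real signal component, and exact
        # recovery is the median outcome; the fixed +2-per-parameter
        # penalty admits a ~15%-per-step chance of over-selection, so
        # occasional N > 2 is expected behavior, not failure
        chosen = [select_n_aic(*_toy_regression(seed=s, noise=0.05), n_max=10)
                  for s in range(50)]
        assert min(chosen) >= 2
        assert np.median(chosen) == 2
        assert np.mean(np.array(chosen) == 2) >= 0.6

    def test_training_rss_nonincreasing_in_n(self):
        data, y, cov = _toy_regression(seed=12, noise=1.0)
        basis = fit_pca(data)
        prev = np.inf
        for n in range(0, 8):
            model = fit_ssm(data, y, cov, n, basis=basis)
            rss = np.sum((y - predict(data, cov, model)) ** 2)
            assert rss <= prev + 1e-10
            prev = rss


class TestPredictAndPress:
    def test_n0_predictions_ignore_brain_data(self):
        rng = np.random.default_rng(13)
        data = rng.standard_normal((6, 20))
        cov = rng.standard_normal((20, 3))
        model = fit_ssm(data, rng.standard_normal(20), cov, n=0)
        p1 = predict(data, cov, model)
        p2 = predict(rng.standard_normal((6, 20)), cov, model)
        np.testing.assert_allclose(p1, p2)

    def test_test_observation_equal_to_training_gets_same_fit(self):
        data, y, cov = _toy_regression(seed=14)
        model = fit_ssm(data, y, cov, n=2)
        full = predict(data, cov, model)
        single = predict(data[:, [3]], cov[[3]], model)
        assert single[0] == pytest.approx(full[3])

    def test_press_is_mean_not_sum(self):
        result = press([1.0, 3.0, 0.0], [2.0, 3.0, -2.0])
        assert result.press == pytest.approx(5 / 3)
        assert result.n_test == 3

    def test_perfect_predictions(self):
        assert press([1.0, 2.0], [1.0, 2.0]).press == 0.0

    def test_constant_prediction_gives_outcome_variance(self):
        rng = np.random.default_rng(15)
        y = rng.standard_normal(200)
        result = press(np.full(200, y.mean()), y)
        assert result.press == pytest.approx(y.var())

    def test_missing_outcomes_excluded(self):
        result = press([1.0, 5.0], [1.0, np.nan])
        assert result.press == 0.0 and result.n_test == 1
        with pytest.raises(ValueError, match="no test observations"):
            press([1.0], [np.nan])

    def test_full_rank_in_sample_press_matches_ols_oracle(self):
        rng = np.random.default_rng(16)
        data = rng.standard_normal((5, 40))
        cov = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        basis = fit_pca(data)
        model = fit_ssm(data, y, cov, basis.rank, basis=basis)
        got = press(predict(data, cov, model), y).press
        X = np.column_stack([expression_scores(data, basis, basis.rank), cov, np.ones(40)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert got == pytest.approx(np.mean((y - X @ beta) ** 2))


class TestDerivePattern:
    def test_single_component_pattern(self):
        data, y, cov = _toy_regression(seed=17)
        model = fit_ssm(data, y, cov, n=1)
        np.testing.assert_allclose(derive_pattern(model), model.beta[0] * model.basis.V[:, 0])

    def test_sign_flip_invariance(self):
        data, y, cov = _toy_regression(seed=18)
        basis = fit_pca(data)
        flipped = PcBasis(V=basis.V * np.array([-1, 1, -1] + [1] * (basis.rank - 3)),
                          eigenvalues=basis.eigenvalues)
        m1 = fit_ssm(data, y, cov, 3, basis=basis)
        m2 = fit_ssm(data, y, cov, 3, basis=flipped)
        np.testing.assert_allclose(derive_pattern(m1), derive_pattern(m2), atol=1e-8)

    def test_reference_model_has_no_pattern(self):
        data, y, cov = _toy_regression(seed=19)
        model = fit_ssm(data, y, cov, n=0)
        with pytest.raises(ValueError, match="no brain pattern"):
            derive_pattern(model)


class TestVarianceSpectrum:
    def test_rank_one_concentrates_everything(self):
        x = np.outer([1.0, 2.0, 3.0], [1.0, -1.0, 2.0, 0.5])
        with pytest.warns(UserWarning, match="truncating"):
            spec = variance_spectrum(x, k=300)
        assert spec.cumulative[0] == pytest.approx(1.0)

    def test_iid_noise_spectrum_nearly_flat(self):
        rng = np.random.default_rng(20)
        spec = variance_spectrum(rng.standard_normal((200, 100)), k=100)
        assert spec.eigenvalues[0] < 3 * spec.eigenvalues.mean()

    def test_cumulative_nondecreasing_in_unit_interval(self):
        rng = np.random.default_rng(21)
        spec = variance_spectrum(rng.standard_normal((50, 30)), k=30)
        assert np.all(np.diff(spec.cumulative) >= -1e-12)
        assert 0 <= spec.cumulative[0] and spec.cumulative[-1] <= 1 + 1e-10
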