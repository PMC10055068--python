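"""One-factor g model: FIML estimation, fit indices, factor scores."""

import numpy as np
import pandas as pd
import pytest

from cortexg.latent_g import (GModel, factor_scores, fiml_loglik, fit_indices,
                              fit_one_factor, mvn_em, residualize_tests)


def one_factor_data(n, lam, seed=0, missing_frac=0.0):
    rng = np.random.default_rng(seed)
    lam = np.asarray(lam, dtype=float)
    g = rng.standard_normal(n)
    X = lam * g[:, None] + rng.standard_normal((n, len(lam))) * np.sqrt(1 - lam ** 2)
    if missing_frac:
        mask = rng.random(X.shape) < missing_frac
        X[mask] = np.nan
    cols = [f"t{i + 1}" for i in range(len(lam))]
    return pd.DataFrame(X, columns=cols), g


class TestResidualize:
    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame({"age": rng.normal(60, 8, 500),
                            "sex": rng.integers(0, 2, 500)})
        tab["t1"] = 0.5 * tab.age + 0.3 * tab.sex + rng.standard_normal(500)
        out = residualize_tests(tab, ["t1"])
        assert abs(out["t1"] @ (tab.age - 0)) < 1e-6 * np.abs(tab.age).sum()
        assert abs(out["t1"] @ tab.sex) < 1e-6
        assert abs(out["t1"].mean()) < 1e-10

    def test_planted_age_slope_recovered_before_residualization(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        age = rng.normal(60, 8, 2000)
        y = 0.5 * age + rng.standard_normal(2000)
        fit = sm.OLS(y, sm.add_constant(age)).fit()
        assert fit.params[1] == pytest.approx(0.5, abs=3 * fit.bse[1])

    def test_zero_variance_test_rejected(self):
        tab = pd.DataFrame({"age": [1.0, 2, 3], "sex": [0, 1, 0], "t1": [5.0] * 3})
        with pytest.raises(ValueError, match="zero variance"):
            residualize_tests(tab, ["t1"])


class TestFitOneFactor:
    def test_population_covariance_input_recovers_lambda_exactly(self):
        """Data whitened then coloured to have *exact* sample moments of the
        one-factor model: the ML estimate must equal the population lambda."""
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        sigma = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        rng = np.random.default_rng(5)
        X = rng.standard_normal((600, 4))
        X -= X.mean(0)
        cov = X.T @ X / len(X)
        white = X @ np.linalg.inv(np.linalg.cholesky(cov)).T
        data = pd.DataFrame(white @ np.linalg.cholesky(sigma).T,
                            columns=list("abcd"))
        model = fit_one_factor(data)
        np.testing.assert_allclose(model.lam.to_numpy(), lam, atol=1e-4)
        assert model.chi2 < 1e-6

    def test_lambda_recovered_within_tolerance_at_n5000(self):
        """Averaged over seeds the n=5000 estimates sit within 0.02 of the
        planted loadings (a single seed's sampling error alone is ~0.015)."""
        lam = (0.7, 0.6, 0.5, 0.4)
        estimates = []
        for seed in range(5, 15):
            model = fit_one_factor(one_factor_data(5000, lam, seed=seed)[0])
            assert model.converged
            estimates.append(model.lam.to_numpy())
        np.testing.assert_allclose(np.mean(estimates, axis=0), lam, atol=0.02)

    def test_against_frozen_factanal_oracle(self):
        """Cross-check against R's factanal (ML factor analysis) on the same
        deterministically regenerated data; the frozen reference values were
        computed once with R 4.3 (factanal, rotation='none').  Standardized
        loadings and the ML discrepancy objective must agree."""
        rng = np.random.default_rng(777)
        n, lam = 300, np.array([0.8, 0.7, 0.6, 0.5, 0.65, 0.55])
        g = rng.standard_normal(n)
        X = lam * g[:, None] + rng.standard_normal((n, 6)) * np.sqrt(1 - lam ** 2)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        data = pd.DataFrame(Z, columns=[f"t{i + 1}" for i in range(6)])
        model = fit_one_factor(data)
        lam_hat = model.lam.to_numpy()
        psi_hat = np.diag(model.psi.to_numpy())
        std_mine = lam_hat / np.sqrt(lam_hat ** 2 + psi_hat)
        ref_load = np.array([0.786415, 0.666495, 0.602834, 0.401863,
                             0.639335, 0.579608])
        ref_uniq = np.array([0.381551, 0.555782, 0.636590, 0.838507,
                             0.591251, 0.664054])
        np.testing.assert_allclose(std_mine,
                                   ref_load / np.sqrt(ref_load ** 2 + ref_uniq),
                                   atol=2e-5)
        # ML objective on the correlation metric
        S = np.corrcoef(Z.T)
        d = np.sqrt(lam_hat ** 2 + psi_hat)
        sig = np.outer(lam_hat / d, lam_hat / d) + np.diag(psi_hat / d ** 2)
        F = (np.log(np.linalg.det(sig)) - np.log(np.linalg.det(S))
             + np.trace(S @ np.linalg.inv(sig)) - 6)
        assert F == pytest.approx(0.02810516, abs=1e-6)

    def test_fiml_path_equals_complete_data_ml(self):
        data, _ = one_factor_data(400, (0.7, 0.6, 0.5, 0.55), seed=8)
        fast = fit_one_factor(data)
        slow = fit_one_factor(data, force_fiml=True)
        assert fast.loglik == pytest.approx(slow.loglik, abs=1e-4)
        np.testing.assert_allclose(fast.lam, slow.lam, atol=1e-3)

    def test_missing_data_handled_and_close_to_complete_fit(self):
        data, _ = one_factor_data(3000, (0.75, 0.65, 0.55, 0.45), seed=9,
                                  missing_frac=0.15)
        model = fit_one_factor(data)
        assert model.converged
        np.testing.assert_allclose(model.lam.to_numpy(),
                                   [0.75, 0.65, 0.55, 0.45], atol=0.06)

    def test_residual_covariance_groups_add_parameters_and_likelihood(self):
        rng = np.random.default_rng(10)
        n = 2000
        g = rng.standard_normal(n)
        shared = rng.standard_normal(n)  # method variance within one domain
        lam = np.array([0.7, 0.6, 0.5, 0.6, 0.5])
        X = lam * g[:, None] + rng.standard_normal((n, 5)) * 0.6
        X[:, 0] += 0.5 * shared
        X[:, 1] += 0.5 * shared
        data = pd.DataFrame(X, columns=["a", "b", "c", "d", "e"])
        plain = fit_one_factor(data)
        grouped = fit_one_factor(data, residual_cov_groups={"domain1": ["a", "b"]})
        assert grouped.df == plain.df - 1
        assert grouped.loglik > plain.loglik
        assert grouped.psi.loc["a", "b"] == pytest.approx(0.25, abs=0.05)

    def test_under_identified_and_too_few_tests_rejected(self):
        data, _ = one_factor_data(100, (0.7, 0.6), seed=1)
        with pytest.raises(ValueError, match="at least 3"):
            fit_one_factor(data)
        data3, _ = one_factor_data(100, (0.7, 0.6, 0.5), seed=1)
        with pytest.raises(ValueError, match="under-identified"):
            fit_one_factor(data3, residual_cov_groups={"d": ["t1", "t2", "t3"]})


class TestFitIndices:
    def test_saturated_model_has_perfect_indices(self):
        data, _ = one_factor_data(500, (0.7, 0.6, 0.5), seed=2)  # df = 0
        model = fit_one_factor(data)
        idx = fit_indices(model)
        assert idx["df"] == 0
        assert idx["CFI"] == pytest.approx(1.0, abs=1e-6)
        assert idx["RMSEA"] == 0.0
        assert np.isnan(idx["TLI"])
        assert idx["SRMR"] < 1e-4

    def test_baseline_as_target_gives_cfi_zero(self):
        data, _ = one_factor_data(500, (0.7, 0.6, 0.5, 0.4), seed=3)
        fitted = fit_one_factor(data)
        base = GModel(
            tests=fitted.tests,
            lam=fitted.lam * 0.0,
            psi=pd.DataFrame(np.diag(np.diag(fitted.sample_cov)),
                             index=fitted.tests, columns=fitted.tests),
            mu=fitted.sample_mean, rescov_pairs=[],
            loglik=fitted.ll_baseline, ll_saturated=fitted.ll_saturated,
            ll_baseline=fitted.ll_baseline,
            chi2=fitted.chi2_baseline, df=fitted.df_baseline,
            chi2_baseline=fitted.chi2_baseline, df_baseline=fitted.df_baseline,
            n=fitted.n, converged=True, grad_norm=0.0, heywood=False,
            sample_mean=fitted.sample_mean, sample_cov=fitted.sample_cov,
        )
        assert fit_indices(base)["CFI"] == pytest.approx(0.0, abs=1e-12)

    def test_good_model_has_conventionally_acceptable_fit(self):
        data, _ = one_factor_data(2000, (0.7, 0.6, 0.5, 0.65, 0.45), seed=4)
        idx = fit_indices(fit_one_factor(data))
        assert idx["CFI"] > 0.97 and idx["RMSEA"] < 0.05 and idx["SRMR"] < 0.05


class TestFactorScores:
    def test_noiseless_single_factor_scores_correlate_perfectly(self):
        rng = np.random.default_rng(6)
        g = rng.standard_normal(800)
        lam = np.array([0.8, 0.6, 0.7])
        X = lam * g[:, None] + 1e-6 * rng.standard_normal((800, 3))
        data = pd.DataFrame(X, columns=list("abc"))
        model = fit_one_factor(data)
        scores = factor_scores(model, data)
        assert abs(np.corrcoef(scores, g)[0, 1]) > 0.99999

    def test_equal_loadings_equal_residuals_scores_proportional_to_row_mean(self):
        """Closed form: with lambda_j = l and psi_j = v for all tests, the
        regression-score weights are equal, so g is an affine function of
        the row mean of the tests."""
        data, _ = one_factor_data(400, (0.6, 0.6, 0.6, 0.6), seed=7)
        tests = list(data.columns)
        model = GModel(
            tests=tests,
            lam=pd.Series(0.6, index=tests),
            psi=pd.DataFrame(np.eye(4) * 0.64, index=tests, columns=tests),
            mu=pd.Series(0.0, index=tests), rescov_pairs=[],
            loglik=0.0, ll_saturated=0.0, ll_baseline=0.0, chi2=0.0, df=2,
            chi2_baseline=1.0, df_baseline=6, n=len(data), converged=True,
            grad_norm=0.0, heywood=False,
            sample_mean=pd.Series(0.0, index=tests),
            sample_cov=pd.DataFrame(np.eye(4), index=tests, columns=tests),
        )
        scores = factor_scores(model, data)
        row_mean = data.mean(axis=1)
        assert np.corrcoef(scores, row_mean)[0, 1] > 1 - 1e-12

    def test_orientation_fixed_against_reversed_inputs(self):
        data, g = one_factor_data(1000, (0.7, 0.6, 0.5, 0.4), seed=8)
        model = fit_one_factor(data)
        s1 = factor_scores(model, data)
        flipped = -data
        model2 = fit_one_factor(flipped)
        s2 = factor_scores(model2, flipped)
        # both orientations end up positively aligned with test performance
        z1 = ((data - data.mean()) / data.std()).mean(axis=1)
        z2 = ((flipped - flipped.mean()) / flipped.std()).mean(axis=1)
        assert np.corrcoef(s1, z1)[0, 1] > 0
        assert np.corrcoef(s2, z2)[0, 1] > 0

    def test_incomplete_cases_still_scored(self):
        data, _ = one_factor_data(1500, (0.7, 0.6, 0.5, 0.4), seed=9,
                                  missing_frac=0.2)
        model = fit_one_factor(data)
        scores = factor_scores(model, data)
        has_any = ~data.isna().all(axis=1)
        assert scores[has_any].notna().all()


class TestMvnEm:
    def test_complete_data_is_one_step_sample_moments(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((200, 3)) @ np.diag([1.0, 2.0, 0.5])
        mu, sigma = mvn_em(X)
        np.testing.assert_allclose(mu, X.mean(0), atol=1e-12)
        np.testing.assert_allclose(sigma, np.cov(X.T, bias=True), atol=1e-12)

    def test_loglik_nondecreasing_under_em_and_close_to_truth(self):
        rng = np.random.default_rng(12)
        X = rng.multivariate_normal([0, 1, 2], [[1, .5, .2], [.5, 1, .3], [.2, .3, 1]],
                                    size=2000)
        X[rng.random(X.shape) < 0.2] = np.nan
        mu, sigma = mvn_em(X)
        assert np.isfinite(fiml_loglik(X, mu, sigma))
        np.testing.assert_allclose(mu, [0, 1, 2], atol=0.1)
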