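"""Posterior algebra, marginal likelihood, hyper-parameter estimation, z-scores."""

import numpy as np
import pytest
from scipy import stats

from zdiffkit import (
    BasisSpec,
    WarpSpec,
    fit_posterior,
    gen_cross_sectional,
    optimize_hyperparams,
    predictive,
    warped_marginal_loglik,
    zscore,
    zscore_frame,
)
from zdiffkit.blr import UnknownSiteError


def sequential_loglik(y, Phi, sigma2, omega2):
    """Chain-rule oracle: sum of one-step-ahead log predictive densities
    under online Bayesian updating of the weight posterior."""
    K = Phi.shape[1]
    mu = np.zeros(K)
    Sigma = omega2 * np.eye(K)
    total = 0.0
    for phi, yi in zip(Phi, y):
        pred_var = phi @ Sigma @ phi + sigma2
        total += stats.norm.logpdf(yi, loc=mu @ phi, scale=np.sqrt(pred_var))
        gain = Sigma @ phi / pred_var
        mu = mu + gain * (yi - mu @ phi)
        Sigma = Sigma - np.outer(gain, phi @ Sigma)
    return total


class TestPosterior:
    def test_hand_worked_single_column(self):
        # Phi = [[1],[1]], y = [1,3], sigma2 = omega2 = 1:
        # A = 2 + 1 = 3, w_bar = (1/3) * 4
        m = fit_posterior(np.array([[1.0], [1.0]]), np.array([1.0, 3.0]), 1.0, 1.0)
        np.testing.assert_allclose(m.A, [[3.0]], rtol=1e-12)
        np.testing.assert_allclose(m.w_bar, [4.0 / 3.0], rtol=1e-12)

    def test_no_data_limit_is_prior(self):
        m = fit_posterior(np.empty((0, 3)), np.empty(0), 1.0, 4.0)
        np.testing.assert_allclose(m.w_bar, np.zeros(3))
        np.testing.assert_allclose(m.A, np.eye(3) / 4.0)

    def test_closed_form_identities_on_random_instances(self, rng):
        """fit_posterior == ridge with penalty sigma2/omega2, to 1e-8."""
        for _ in range(100):
            n = int(rng.integers(2, 51))
            K = int(rng.integers(1, 6))
            Phi = rng.normal(size=(n, K))
            y = rng.normal(size=n)
            s2 = float(rng.uniform(0.2, 3.0))
            o2 = float(rng.uniform(0.2, 3.0))
            m = fit_posterior(Phi, y, s2, o2)
            A_expected = Phi.T @ Phi / s2 + np.eye(K) / o2
            w_ridge = np.linalg.solve(Phi.T @ Phi + (s2 / o2) * np.eye(K), Phi.T @ y)
            np.testing.assert_allclose(m.A, A_expected, rtol=1e-8)
            np.testing.assert_allclose(m.w_bar, w_ridge, rtol=1e-8, atol=1e-10)
            assert np.all(np.linalg.eigvalsh(m.A) > 0)

    def test_diffuse_prior_recovers_least_squares(self, rng):
        Phi = np.c_[np.ones(40), rng.normal(size=(40, 2))]
        y = rng.normal(size=40)
        m = fit_posterior(Phi, y, 1.0, 1e12)
        w_ls, *_ = np.linalg.lstsq(Phi, y, rcond=None)
        np.testing.assert_allclose(m.w_bar, w_ls, rtol=1e-4)
        x_new = np.array([1.0, 0.3, -1.2])
        spec = BasisSpec(spline_degree=1, interior_knots=(), boundary_knots=(0, 1),
                         linear_covariates=(), site_labels=())
        assert m.w_bar @ x_new == pytest.approx(w_ls @ x_new, rel=1e-4)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_posterior(np.array([[np.nan]]), np.array([1.0]), 1.0, 1.0)
        with pytest.raises(ValueError):
            fit_posterior(np.array([[1.0]]), np.array([1.0]), -1.0, 1.0)


class TestMarginalLikelihood:
    def test_single_point_evidence(self):
        val = warped_marginal_loglik(np.array([0.0]), np.array([[1.0]]), 1.0, 1.0, WarpSpec())
        assert val == pytest.approx(-0.5 * np.log(4 * np.pi), abs=1e-12)

    def test_matches_sequential_update_oracle(self, rng):
        n, K = 30, 3
        Phi = rng.normal(size=(n, K))
        y = rng.normal(size=n)
        for s2, o2 in [(1.0, 1.0), (0.5, 2.0), (3.0, 0.3)]:
            ours = warped_marginal_loglik(y, Phi, s2, o2, WarpSpec())
            assert ours == pytest.approx(sequential_loglik(y, Phi, s2, o2), abs=1e-8)

    def test_translation_invariance_of_residual_model(self, rng):
        """Shifting targets and the intercept prediction together leaves the
        likelihood of the residuals unchanged (diffuse intercept prior)."""
        n = 50
        Phi = np.ones((n, 1))
        y = rng.normal(size=n)
        base = warped_marginal_loglik(y, Phi, 1.0, 1e8, WarpSpec())
        shifted = warped_marginal_loglik(y + 7.0, Phi, 1.0, 1e8, WarpSpec())
        assert shifted == pytest.approx(base, abs=1e-4)

    def test_jacobian_term_included(self, rng):
        y = rng.normal(size=20) * 0.5 + 2.0
        Phi = np.ones((20, 1))
        wspec = WarpSpec(family="sinh-arcsinh", gamma=(0.3, 1.4), loc=2.0, scale=0.5)
        from zdiffkit import warp, warp_logderiv
        with_jac = warped_marginal_loglik(y, Phi, 1.0, 1.0, wspec)
        evidence_only = warped_marginal_loglik(
            np.asarray(warp(y, wspec)), Phi, 1.0, 1.0, WarpSpec())
        assert with_jac == pytest.approx(evidence_only + warp_logderiv(y, wspec).sum(), abs=1e-10)

    def test_invalid_variances_rejected(self):
        with pytest.raises(ValueError):
            warped_marginal_loglik(np.array([1.0]), np.array([[1.0]]), 0.0, 1.0, WarpSpec())


class TestHyperparamEstimation:
    @pytest.mark.parametrize("true_sigma2", [1.0, 0.25])
    def test_recovers_noise_variance(self, true_sigma2, rng):
        n, K = 2000, 4
        Phi = np.c_[np.ones(n), rng.normal(size=(n, K - 1))]
        w = np.array([0.5, 1.0, -0.7, 0.3])
        y = Phi @ w + rng.normal(0, np.sqrt(true_sigma2), n)
        s2, o2, wspec = optimize_hyperparams(y, Phi, "identity", seed=1)
        assert abs(s2 - true_sigma2) < 0.1 * true_sigma2
        assert wspec.family == "identity"

    def test_degenerate_all_zero_targets(self):
        Phi = np.ones((50, 1))
        s2, o2, _ = optimize_hyperparams(np.zeros(50), Phi, "identity", seed=0)
        assert s2 >= 1e-8  # floor, no crash

    def test_optimum_not_below_initialisations(self, rng):
        n = 200
        Phi = np.c_[np.ones(n), rng.normal(size=n)]
        y = Phi @ np.array([1.0, 2.0]) + rng.normal(0, 1.0, n)
        s2, o2, wspec = optimize_hyperparams(y, Phi, "identity", seed=3)
        opt = warped_marginal_loglik(y, Phi, s2, o2, wspec)
        var0 = np.var(y)
        init = warped_marginal_loglik(y, Phi, var0, max(var0, 1.0), WarpSpec())
        assert opt >= init - 1e-6


class TestScoring:
    def test_prior_only_predictive(self):
        spec = BasisSpec(spline_degree=1, interior_knots=(), boundary_knots=(0, 100),
                         linear_covariates=(), site_labels=(), include_intercept=True)
        # prior-only model over [spline(2), intercept]; at the left boundary the
        # spline contributes (1, 0), so phi = (1, 0, 1) and phi' A^-1 phi = 2 omega^2
        m = fit_posterior(np.empty((0, 3)), np.empty(0), 0.75, 4.0,
                          basis=spec, warp_spec=WarpSpec())
        mean, var = predictive({"age": 0.0}, m)
        assert mean == 0.0
        assert var == pytest.approx(2 * 4.0 + 0.75)
        assert var > m.sigma2

    def test_zscore_trivial_cases(self, ref_model):
        m = ref_model.idps["idp_a"]
        x = {"age": 40.0, "sex": 1, "site": m.basis.site_labels[0]}
        mean, var = predictive(x, m)
        from zdiffkit import unwarp
        y_on_centile = float(unwarp(mean, m.warp))
        assert zscore(y_on_centile, x, m) == pytest.approx(0.0, abs=1e-10)
        # unit denominator: warped residual 1 with variance exactly 1
        y_plus = float(unwarp(mean + np.sqrt(var), m.warp))
        assert zscore(y_plus, x, m) == pytest.approx(1.0, abs=1e-10)

    def test_predictive_variance_shrinks_with_training_size(self, rng):
        spec = BasisSpec(spline_degree=1, interior_knots=(), boundary_knots=(20, 60),
                         linear_covariates=(), site_labels=())
        x = {"age": 37.0}
        from zdiffkit.basis import design_matrix
        variances = []
        for n in [10, 100, 1000]:
            ages = rng.uniform(20, 60, n)
            Phi = design_matrix([{"age": a} for a in ages], spec)
            y = rng.normal(size=n)
            m = fit_posterior(Phi, y, 1.0, 1.0, basis=spec, warp_spec=WarpSpec())
            variances.append(predictive(x, m)[1])
        assert variances[0] > variances[1] > variances[2] > 1.0

    def test_heldout_zscores_standard_normal(self, fitted_model, tracking_spec):
        test = gen_cross_sectional(tracking_spec, seed=909)
        z = zscore_frame(test, fitted_model)
        for idp, grp in z.groupby("idp"):
            assert abs(grp["z"].mean()) < 0.05
            assert abs(grp["z"].var() - 1) < 0.1
            assert stats.kstest(grp["z"], "norm").pvalue > 0.01

    def test_unknown_site_directs_to_adaptation(self, ref_model):
        m = ref_model.idps["idp_a"]
        with pytest.raises(UnknownSiteError, match="adaptation"):
            zscore(1.0, {"age": 40.0, "sex": 0, "site": "brand_new"}, m)
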