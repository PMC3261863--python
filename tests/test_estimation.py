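"""Estimation: pseudolikelihood, beta-step reductions, MCMC-MLE updates, Wald."""

import numpy as np
import pytest
from scipy import optimize

from gergm.estimation import (
    ConvexHullError,
    fit_beta,
    in_convex_hull,
    log_c_ratio,
    mple,
    update_theta,
    vcov_estimate,
    wald_block_test,
)
from gergm.marginals import EdgeDesign
from gergm.networks import RestrictedNetwork, ValuedNetwork, from_edge_vector
from gergm.sampler import GibbsConfig, simulate_restricted, truncexp_logz, truncexp_mean
from gergm.statistics import StatisticSpec, compute_statistics


def _const_restricted(n, value):
    x = np.full((n, n), value)
    np.fill_diagonal(x, 0.0)
    return RestrictedNetwork(x)


class TestMple:
    def test_mean_half_gives_zero(self):
        """Mean edge exactly 1/2 forces theta = 0 in the edge_sum-only model."""
        th = mple(_const_restricted(5, 0.5), StatisticSpec(["edge_sum"]))
        assert np.isclose(th[0], 0.0, atol=1e-8)

    def test_independent_model_solves_mean_equation(self):
        """edge_sum-only MPLE inverts the truncated-exponential mean function."""
        target_mean = 0.719
        oracle = optimize.brentq(lambda a: truncexp_mean(a) - target_mean, -50, 50)
        th = mple(_const_restricted(5, target_mean), StatisticSpec(["edge_sum"]))
        assert np.isclose(th[0], oracle, atol=1e-6)
        assert np.isclose(oracle, 3.0, atol=5e-3)  # 0.719 is the mean at a = 3

    def test_gradient_vanishes_at_optimum(self, random_restricted):
        from gergm.networks import edge_pairs
        from gergm.statistics import delta_matrix

        spec = StatisticSpec(["edge_sum", "reciprocity", "transitive_triads"])
        x = random_restricted(7)
        th = mple(x, spec)
        D = delta_matrix(x, spec, edge_pairs(7))
        grad = D.T @ (x.edge_values() - truncexp_mean(D @ th))
        assert np.max(np.abs(grad)) < 1e-5


class TestFitBeta:
    def test_gaussian_theta_zero_is_least_squares(self, rng):
        n = 8
        m = n * (n - 1)
        Z = np.column_stack([np.ones(m), rng.standard_normal((m, 2))])
        ye = Z @ np.array([1.0, 2.0, -1.0]) + 0.7 * rng.standard_normal(m)
        y = ValuedNetwork(from_edge_vector(ye, n))
        beta = fit_beta(y, "gaussian", EdgeDesign(Z), np.zeros(1), StatisticSpec(["edge_sum"]))
        ols = np.linalg.solve(Z.T @ Z, Z.T @ ye)
        assert np.max(np.abs(beta[:3] - ols)) < 1e-6
        assert np.isclose(np.exp(beta[-1]), np.sqrt(np.mean((ye - Z @ ols) ** 2)), atol=1e-6)

    def test_cauchy_theta_zero_matches_direct_mle(self, rng):
        n = 8
        m = n * (n - 1)
        Z = np.column_stack([np.ones(m), rng.standard_normal((m, 2))])
        ye = Z @ np.array([0.5, 1.5, -1.0]) + 0.8 * rng.standard_cauchy(m)
        y = ValuedNetwork(from_edge_vector(ye, n))
        beta = fit_beta(y, "cauchy", EdgeDesign(Z), np.zeros(1), StatisticSpec(["edge_sum"]))

        def nll(p):
            mu, al = Z @ p[:3], np.exp(p[3])
            return np.sum(np.log(np.pi * al) + np.log1p(((ye - mu) / al) ** 2))

        oracle = optimize.minimize(
            nll, np.array([np.median(ye), 0.0, 0.0, 0.0]), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 40000, "maxfev": 40000},
        )
        assert np.max(np.abs(beta - oracle.x)) < 1e-4

    def test_intercept_only_gaussian_recovers_sample_mean(self, rng):
        n = 6
        ye = rng.standard_normal(n * (n - 1)) + 2.0
        y = ValuedNetwork(from_edge_vector(ye, n))
        beta = fit_beta(
            y, "gaussian", EdgeDesign.intercept_only(len(ye)), np.zeros(1),
            StatisticSpec(["edge_sum"]),
        )
        assert np.isclose(beta[0], ye.mean(), atol=1e-7)

    def test_interval_family_has_no_parameters(self, rng):
        y = ValuedNetwork(from_edge_vector(rng.uniform(-1, 1, 12), 4))
        beta = fit_beta(
            y, "interval", EdgeDesign.intercept_only(12), np.zeros(1),
            StatisticSpec(["edge_sum"]), bounds=(-1, 1),
        )
        assert beta.size == 0


@pytest.fixture(scope="module")
def independent_sample():
    spec = StatisticSpec(["edge_sum"])
    cfg = GibbsConfig(sweeps=5200, burnin=200, thin=1, seed=33)
    return simulate_restricted(np.array([1.0]), spec, 5, cfg).stats


class TestUpdateTheta:
    def test_log_ratio_matches_closed_form(self, independent_sample):
        """Importance estimate of log C(theta)/C(theta~) vs the closed form.

        For the independent-edge model C(theta) = [(e^theta - 1)/theta]^m.
        """
        m = 20
        for th in (0.0, 0.5, 2.0):
            est = log_c_ratio(np.array([th]), np.array([1.0]), independent_sample)
            closed = m * (truncexp_logz(th) - truncexp_logz(1.0))
            vals = np.exp(independent_sample[:, 0] * (th - 1.0))
            se = vals.std(ddof=1) / (vals.mean() * np.sqrt(len(vals)))
            assert abs(est - closed) < max(3 * se, 1e-12)

    def test_ratio_zero_at_anchor(self, independent_sample):
        assert log_c_ratio(np.array([1.0]), np.array([1.0]), independent_sample) == 0.0

    def test_self_consistency_at_truth(self, independent_sample):
        """Updating from data drawn at theta~ moves theta only by MC noise."""
        h_obs = np.array([independent_sample[:, 0].mean()])
        th = update_theta(h_obs, np.array([1.0]), independent_sample)
        assert abs(th[0] - 1.0) < 0.1

    def test_convex_hull_violation_raises(self, independent_sample):
        h_out = np.array([independent_sample[:, 0].max() + 5.0])
        with pytest.raises(ConvexHullError, match="convex hull"):
            update_theta(h_out, np.array([1.0]), independent_sample)

    def test_hull_membership_check(self):
        cloud = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert in_convex_hull(np.array([0.3, 0.3]), cloud)
        assert not in_convex_hull(np.array([0.8, 0.8]), cloud)


class TestVcov:
    def test_null_data_gaussian_beta_block_matches_ols_covariance(self, rng):
        """Data without dependence: the eta block approximates the OLS covariance."""
        from gergm import GERGM

        n = 10
        m = n * (n - 1)
        Z = np.column_stack([np.ones(m), rng.standard_normal((m, 2))])
        design = EdgeDesign(Z)
        ye = Z @ np.array([0.5, 1.0, -0.7]) + 0.9 * rng.standard_normal(m)
        y = ValuedNetwork(from_edge_vector(ye, n))
        res = GERGM(y, ["edge_sum"], family="gaussian", design=design).fit(
            M=500, burnin=300, max_outer=4, tol=1e-3, seed=8
        )
        assert np.all(np.diag(res.vcov) > 0)
        s2_hat = np.exp(res.beta[-1]) ** 2
        ols_cov = s2_hat * np.linalg.inv(Z.T @ Z)
        # non-intercept eta entries are orthogonal to the density ridge
        assert np.allclose(
            np.diag(res.vcov)[2:4], np.diag(ols_cov)[1:], rtol=0.35
        )

    def test_symmetry(self, rng):
        n = 6
        m = n * (n - 1)
        design = EdgeDesign.intercept_only(m)
        ye = rng.standard_normal(m)
        y = ValuedNetwork(from_edge_vector(ye, n))
        spec = StatisticSpec(["edge_sum"])
        beta = fit_beta(y, "gaussian", design, np.zeros(1), spec)
        cfg = GibbsConfig(sweeps=1200, burnin=200, thin=1, seed=9)
        stats_sample = simulate_restricted(np.zeros(1), spec, n, cfg).stats
        V, _ = vcov_estimate(np.zeros(1), beta, y, "gaussian", design, spec, stats_sample)
        assert np.allclose(V, V.T)


class TestWald:
    def test_zero_estimate_gives_unit_p(self):
        out = wald_block_test(np.array([0.0, 1.0]), np.eye(2), [0])
        assert out == {"statistic": 0.0, "df": 1, "p": 1.0}

    def test_single_parameter_is_squared_z(self):
        params = np.array([1.5, -0.3])
        V = np.diag([0.25, 0.04])
        out = wald_block_test(params, V, [0])
        assert np.isclose(out["statistic"], (1.5 / 0.5) ** 2)
        assert out["df"] == 1

    def test_block_statistic_quadratic_form(self, rng):
        params = rng.standard_normal(4)
        A = rng.standard_normal((4, 4))
        V = A @ A.T + 4 * np.eye(4)
        idx = [1, 3]
        out = wald_block_test(params, V, idx)
        g = params[idx]
        Vss = V[np.ix_(idx, idx)]
        assert np.isclose(out["statistic"], g @ np.linalg.solve(Vss, g))
        assert out["df"] == 2

    def test_singular_subcovariance_raises(self):
        with pytest.raises(RuntimeError, match="singular"):
            wald_block_test(np.array([1.0, 1.0]), np.ones((2, 2)), [0, 1])
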