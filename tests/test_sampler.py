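"""Gibbs sampler: exactness of the truncated-exponential conditionals."""

import numpy as np
import pytest
from scipy import optimize, stats

from gergm.marginals import EdgeDesign, MarginalModel
from gergm.networks import RestrictedNetwork
from gergm.sampler import (
    GibbsConfig,
    conditional_coefficient,
    draw_edge,
    gibbs_sweep,
    simulate_observed,
    simulate_restricted,
    truncexp_cdf,
    truncexp_icdf,
    truncexp_logz,
    truncexp_mean,
    truncexp_var,
)
from gergm.statistics import StatisticSpec


class TestTruncExp:
    def test_uniform_limit(self):
        assert draw_edge(0.0, 0.5) == 0.5

    def test_inverse_cdf_against_bisection(self):
        """Closed form vs numerical inversion of (e^{ax}-1)/(e^a-1)."""
        for a in (-5.0, -1.0, 1.0, 5.0, 30.0, -30.0):
            for u in (0.1, 0.5, 0.9):
                root = optimize.brentq(
                    lambda x: np.expm1(a * x) / np.expm1(a) - u, 1e-12, 1 - 1e-12,
                    xtol=1e-14,
                )
                assert np.isclose(draw_edge(a, u), root, atol=1e-9)

    def test_frozen_example(self):
        # ln(1 + 0.5(e - 1)) = 0.620115 (bisection-verified above)
        assert np.isclose(draw_edge(1.0, 0.5), 0.6201145, atol=1e-6)

    def test_reflection_symmetry(self, rng):
        """draw(a, u) + draw(-a, 1-u) = 1: the density reflects about 1/2."""
        for _ in range(50):
            a = rng.uniform(-8, 8)
            u = rng.uniform(0.01, 0.99)
            assert np.isclose(draw_edge(a, u) + draw_edge(-a, 1 - u), 1.0, atol=1e-9)

    def test_rejects_u_outside_unit_interval(self):
        with pytest.raises(ValueError, match="strictly in"):
            draw_edge(1.0, 0.0)

    def test_extreme_coefficient_no_overflow(self):
        x = draw_edge(800.0, 0.5)
        assert 0.99 < x < 1.0
        x = draw_edge(-800.0, 0.5)
        assert 0.0 < x < 0.01

    def test_moments_against_quadrature(self):
        from scipy.integrate import quad

        for a in (-4.0, -0.5, 0.5, 4.0):
            Z = np.expm1(a) / a
            mean_q, _ = quad(lambda x: x * np.exp(a * x) / Z, 0, 1)
            var_q, _ = quad(lambda x: (x - mean_q) ** 2 * np.exp(a * x) / Z, 0, 1)
            assert np.isclose(truncexp_mean(a), mean_q, atol=1e-10)
            assert np.isclose(truncexp_var(a), var_q, atol=1e-10)
            assert np.isclose(truncexp_logz(a), np.log(Z), atol=1e-12)

    def test_series_branches_continuous(self):
        # series and closed form agree at the switch points
        for f in (truncexp_mean, truncexp_var, truncexp_logz):
            lo, hi = f(np.array([0.9e-4])), f(np.array([1.1e-3]))
            mid = f(np.array([5e-4]))
            assert lo <= mid <= hi or hi <= mid <= lo

    @pytest.mark.parametrize("a", [-5.0, -1.0, 1.0, 5.0])
    def test_draws_match_analytic_density_chi2(self, a):
        """Histogram of repeated draws vs the analytic density (chi-squared)."""
        rng = np.random.default_rng(int(abs(a) * 10) + (a > 0))
        u = rng.uniform(1e-12, 1 - 1e-12, size=20000)
        draws = truncexp_icdf(a, u)
        edges = np.linspace(0, 1, 21)
        observed, _ = np.histogram(draws, bins=edges)
        probs = np.diff(truncexp_cdf(a, edges))
        chi2 = ((observed - 20000 * probs) ** 2 / (20000 * probs)).sum()
        # dof = 19; reject only far beyond the 0.001 tail
        assert chi2 < stats.chi2.ppf(0.999, 19)


class TestConditionalCoefficient:
    def test_zero_theta(self, random_restricted):
        spec = StatisticSpec(["edge_sum", "reciprocity"])
        x = random_restricted(4)
        assert conditional_coefficient(x, np.zeros(2), spec, 0, 1) == 0.0

    def test_edge_sum_constant(self, random_restricted):
        x = random_restricted(4)
        a = conditional_coefficient(x, np.array([2.0]), StatisticSpec(["edge_sum"]), 1, 2)
        assert a == 2.0

    def test_reciprocity_reads_opposite_edge(self):
        x = np.array([[0.0, 0.9], [0.4, 0.0]])
        a = conditional_coefficient(x, np.array([1.0]), StatisticSpec(["reciprocity"]), 0, 1)
        assert np.isclose(a, 0.4)

    def test_dimension_mismatch(self, random_restricted):
        with pytest.raises(ValueError, match="length"):
            conditional_coefficient(
                random_restricted(3), np.zeros(2), StatisticSpec(["edge_sum"]), 0, 1
            )


class TestGibbs:
    def test_zero_theta_sweep_returns_iid_uniforms(self, random_restricted):
        """At theta = 0 one sweep replaces all edges by the supplied uniforms."""
        x = random_restricted(5)
        spec = StatisticSpec(["edge_sum", "reciprocity"])
        rng = np.random.default_rng(3)
        uniforms = rng.uniform(0.01, 0.99, size=20)
        out = gibbs_sweep(x, np.zeros(2), spec, rng, uniforms=uniforms)
        assert np.allclose(out.edge_values(), uniforms)

    def test_fixed_seed_deterministic(self):
        spec = StatisticSpec(["edge_sum", "reciprocity"])
        cfg = GibbsConfig(sweeps=50, burnin=10, thin=1, seed=11)
        a = simulate_restricted(np.array([0.5, -0.5]), spec, 5, cfg)
        b = simulate_restricted(np.array([0.5, -0.5]), spec, 5, cfg)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.mean_trace, b.mean_trace)

    def test_numba_and_python_paths_agree(self):
        spec = StatisticSpec(["edge_sum", "transitive_triads", "in_two_stars"])
        cfg = GibbsConfig(sweeps=30, burnin=5, thin=3, seed=21)
        theta = np.array([-0.3, 0.4, 0.2])
        fast = simulate_restricted(theta, spec, 6, cfg, use_numba=True)
        slow = simulate_restricted(theta, spec, 6, cfg, use_numba=False)
        assert len(fast.networks) == len(slow.networks)
        assert np.allclose(fast.samples, slow.samples, atol=1e-12)
        assert np.allclose(fast.mean_trace, slow.mean_trace, atol=1e-12)

    def test_edge_sum_long_run_mean(self):
        """theta = 3 on edge_sum only: mean edge is the truncated-exp mean."""
        spec = StatisticSpec(["edge_sum"])
        cfg = GibbsConfig(sweeps=3000, burnin=200, thin=1, seed=5)
        sim = simulate_restricted(np.array([3.0]), spec, 6, cfg)
        target = 1.0 / (1.0 - np.exp(-3.0)) - 1.0 / 3.0  # = 0.71906...
        assert np.isclose(sim.edge_series.mean(), target, atol=0.01)

    def test_zero_theta_edges_uniform(self):
        """theta = 0: pooled edge values pass a KS uniformity test at 1%."""
        spec = StatisticSpec(["edge_sum", "reciprocity"])
        cfg = GibbsConfig(sweeps=700, burnin=200, thin=1, seed=9)
        sim = simulate_restricted(np.zeros(2), spec, 6, cfg)
        pooled = sim.edge_series.ravel()
        _, p = stats.kstest(pooled, "uniform")
        assert p > 0.01

    def test_degeneracy_probe_extreme_theta(self):
        """Extreme positive/negative theta drives the chain to full/empty graph."""
        spec = StatisticSpec(["edge_sum"])
        cfg = GibbsConfig(sweeps=300, burnin=100, thin=1, seed=2)
        full = simulate_restricted(np.array([30.0]), spec, 6, cfg)
        empty = simulate_restricted(np.array([-30.0]), spec, 6, cfg)
        assert full.edge_series.mean() > 0.95
        assert empty.edge_series.mean() < 0.05

    def test_dispersed_init_is_u_shaped(self):
        cfg = GibbsConfig(sweeps=1, burnin=0, thin=1, seed=4, init="dispersed")
        sim = simulate_restricted(np.zeros(1), StatisticSpec(["edge_sum"]), 10, cfg)
        assert len(sim.networks) == 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="thin"):
            GibbsConfig(sweeps=10, burnin=0, thin=0)
        with pytest.raises(ValueError, match="burnin"):
            GibbsConfig(sweeps=10, burnin=20)


class TestTwoVertexJointDensity:
    def test_chain_matches_quadrature(self):
        """2-vertex reciprocity model: Gibbs joint density vs 2-D quadrature."""
        theta = np.array([-2.0, 3.0])
        spec = StatisticSpec(["edge_sum", "reciprocity"])
        cfg = GibbsConfig(sweeps=21000, burnin=1000, thin=1, seed=17)
        sim = simulate_restricted(theta, spec, 2, cfg)
        x12, x21 = sim.edge_series[:, 0], sim.edge_series[:, 1]
        bins, G = 8, 400
        emp, _, _ = np.histogram2d(x12, x21, bins=bins, range=[[0, 1], [0, 1]])
        emp = emp / emp.sum()
        g = (np.arange(G) + 0.5) / G
        U, V = np.meshgrid(g, g, indexing="ij")
        dens = np.exp(theta[0] * (U + V) + theta[1] * U * V)
        dens /= dens.sum()
        quad = dens.reshape(bins, G // bins, bins, G // bins).sum(axis=(1, 3))
        tv = 0.5 * np.abs(emp - quad).sum()
        assert tv < 0.03  # looser than the long-run check; 20k sweeps here


class TestSimulateObserved:
    def test_gaussian_reduction_normality(self):
        """theta = 0 with a gaussian marginal: simulated edges are normal."""
        spec = StatisticSpec(["edge_sum"])
        model = MarginalModel("gaussian", [0.0, 0.0])
        cfg = GibbsConfig(sweeps=400, burnin=100, thin=1, seed=13)
        nets = simulate_observed(np.zeros(1), spec, model, None, 6, cfg)
        pooled = np.concatenate([n.edge_values() for n in nets])
        _, p = stats.kstest(pooled, "norm")
        assert p > 0.01

    def test_interval_bounds_respected(self):
        spec = StatisticSpec(["edge_sum"])
        model = MarginalModel("interval", [], bounds=(-1.0, 1.0))
        cfg = GibbsConfig(sweeps=120, burnin=20, thin=1, seed=14)
        nets = simulate_observed(np.array([1.0]), spec, model, None, 5, cfg)
        pooled = np.concatenate([n.edge_values() for n in nets])
        assert np.all(pooled >= -1.0) and np.all(pooled <= 1.0)

    def test_cauchy_marginal_heavy_tails(self):
        """Cauchy-transformed simulations have sample kurtosis far above 3."""
        spec = StatisticSpec(["edge_sum"])
        model = MarginalModel("cauchy", [0.0, 0.0])
        cfg = GibbsConfig(sweeps=600, burnin=100, thin=1, seed=15)
        nets = simulate_observed(np.zeros(1), spec, model, None, 6, cfg)
        pooled = np.concatenate([n.edge_values() for n in nets])
        kurt = stats.kurtosis(pooled, fisher=False)
        assert kurt > 10.0
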