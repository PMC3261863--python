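"""The GERGM model and results objects.

`GERGM` bundles an observed valued network, a dependence-statistic
specification, and a marginal family into a fittable model; `fit()` runs the
alternating MLE / MCMC-MLE algorithm and returns a `GERGMResults` carrying
the estimates, their covariance, hypothesis tests, a summary table, and
simulation-based goodness of fit.

Typical use::

    import numpy as np
    from gergm import GERGM

    model = GERGM(y_matrix, ["edge_sum", "reciprocity"], family="gaussian")
    result = model.fit(M=500, seed=7)
    print(result.summary())
    result.wald_test(["reciprocity"])

Fitting algorithm
-----------------
1. beta0 <- independent marginal fit (theta = 0); xhat <- F(y | beta0).
2. theta0 <- maximum pseudolikelihood estimate on xhat.
3. Repeat until max |parameter change| < tol or max_outer iterations:
   a. simulate M restricted networks at the provisional theta (Gibbs);
   b. theta <- importance-sampled likelihood update (requires h(xhat) inside
      the convex hull of the simulated statistics; on violation the sample
      is refreshed once at double size before giving up);
   c. beta <- maximize theta'h(F(y|beta)) + log-Jacobian; xhat updated.
4. Covariance: negative inverse numerical Hessian of the approximate joint
   log-likelihood at the final estimates, over (theta, beta) jointly, with a
   fresh sample anchored at the final theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import estimation as est
from .marginals import EdgeDesign, MarginalModel, to_restricted
from .networks import RestrictedNetwork, ValuedNetwork
from .sampler import GibbsConfig, simulate_restricted
from .statistics import StatisticSpec, compute_statistics


@dataclass
class FitConfig:
    """Knobs of the alternating estimation loop.

    M : networks per MCMC-MLE importance sample (>= 100).
    max_outer : maximum alternating iterations.
    tol : convergence threshold on the max absolute parameter change.
    burnin, thin : Gibbs settings per sample (total sweeps = burnin + M*thin).
    seed : master seed; all chain seeds derive from it.
    """

    M: int = 1000
    max_outer: int = 25
    tol: float = 1e-4
    burnin: int = 500
    thin: int = 1
    seed: int | None = None
    check_hull: bool = True
    use_numba: bool = True
    #: sample size for the final covariance estimate; the curvature of the
    #: log normalizing constant is a statistic covariance, so it needs a
    #: larger, thinned sample than the update steps.  None -> max(2000, 2M).
    M_vcov: int | None = None
    thin_vcov: int = 2

    def __post_init__(self) -> None:
        if self.M < 100:
            raise ValueError("M must be at least 100")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


class GERGM:
    """Generalized exponential random graph model for a valued network.

    Parameters
    ----------
    network : ValuedNetwork or (n, n) array
        Observed directed network with continuous edge values.
    statistics : StatisticSpec or sequence of str
        Dependence statistics defining h and theta.
    family : {"gaussian", "cauchy", "interval"}
        Marginal family of the edgewise transformation.
    design : EdgeDesign, optional
        Per-edge covariates for the location model (intercept-only default).
    bounds : (a, b), required for the interval family.
    """

    def __init__(
        self,
        network,
        statistics,
        family: str = "gaussian",
        design: EdgeDesign | None = None,
        bounds: tuple[float, float] | None = None,
    ) -> None:
        if not isinstance(network, ValuedNetwork):
            network = ValuedNetwork(np.asarray(network, dtype=float))
        if not isinstance(statistics, StatisticSpec):
            statistics = StatisticSpec(statistics)
        statistics.check_directed(network.directed)
        if design is None:
            design = EdgeDesign.intercept_only(network.m)
        elif design.m != network.m:
            raise ValueError(
                f"design has {design.m} rows but the network has {network.m} edges"
            )
        if family == "interval" and bounds is None:
            raise ValueError("interval family requires bounds=(a, b)")
        self.network = network
        self.spec = statistics
        self.family = family
        self.design = design
        self.bounds = bounds

    @classmethod
    def from_dataframe(cls, frame, statistics, family="gaussian", **kwargs):
        """Build from a square pandas DataFrame (index/columns = vertex labels)."""
        values = np.asarray(frame, dtype=float)
        labels = [str(c) for c in frame.columns]
        net = ValuedNetwork(values, directed=True, vertex_labels=labels)
        return cls(net, statistics, family=family, **kwargs)

    @property
    def param_names(self) -> list[str]:
        names = list(self.spec.names)
        if self.family != "interval":
            names += list(self.design.covariate_names) + ["log_scale"]
        return names

    def _beta_model(self, beta: np.ndarray) -> MarginalModel:
        return MarginalModel(self.family, beta, self.bounds)

    def fit(self, config: FitConfig | None = None, **kwargs) -> "GERGMResults":
        """Run the alternating MLE / MCMC-MLE estimation.

        Keyword arguments override :class:`FitConfig` fields, e.g.
        ``model.fit(M=500, seed=3)``.
        """
        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a FitConfig or keyword overrides, not both")
        y, spec, design = self.network, self.spec, self.design
        seeds = np.random.SeedSequence(config.seed)

        beta = est.fit_beta(
            y, self.family, design, np.zeros(len(spec)), spec, self.bounds
        )
        xhat = to_restricted(y, self._beta_model(beta), design)
        theta = est.mple(xhat, spec)

        trace: list[float] = []
        converged = False
        n_iter = 0
        sample_stats = None
        for n_iter in range(1, config.max_outer + 1):
            sample_stats = self._simulate_stats(theta, xhat, config, seeds)
            h_obs = compute_statistics(xhat, spec)
            try:
                theta_new = est.update_theta(
                    h_obs, theta, sample_stats, check_hull=config.check_hull
                )
            except est.ConvexHullError:
                # one retry with a fresh, doubled sample before giving up
                sample_stats = self._simulate_stats(
                    theta, xhat, config, seeds, m_factor=2
                )
                theta_new = est.update_theta(
                    h_obs, theta, sample_stats, check_hull=config.check_hull
                )
            beta_new = est.fit_beta(
                y, self.family, design, theta_new, spec, self.bounds, start=beta
            )
            delta = self._param_change(theta, beta, theta_new, beta_new)
            theta, beta = theta_new, beta_new
            xhat = to_restricted(y, self._beta_model(beta), design)
            trace.append(
                est.joint_loglik(
                    theta, beta, y, self.family, design, spec,
                    theta, sample_stats, self.bounds,
                )
            )
            if delta < config.tol:
                converged = True
                break

        # fresh sample at the final theta anchors the Hessian / gof
        M_vcov = config.M_vcov or max(2000, 2 * config.M)
        final_stats = self._simulate_stats(
            theta, xhat, config, seeds, M_override=M_vcov, thin_override=config.thin_vcov
        )
        vcov, floored = est.vcov_estimate(
            theta, beta, y, self.family, design, spec, final_stats,
            self.bounds, self.param_names,
        )
        return GERGMResults(
            model=self,
            theta=theta,
            beta=beta,
            vcov=vcov,
            loglik_trace=np.asarray(trace),
            converged=converged,
            n_outer=n_iter,
            M_used=config.M,
            config=config,
            xhat=xhat,
            sample_stats=final_stats,
            information_floored=floored,
        )

    # -- helpers ----------------------------------------------------------
    def _simulate_stats(
        self,
        theta: np.ndarray,
        xhat: RestrictedNetwork,
        config: FitConfig,
        seeds: np.random.SeedSequence,
        m_factor: int = 1,
        M_override: int | None = None,
        thin_override: int | None = None,
    ) -> np.ndarray:
        M = (M_override or config.M) * m_factor
        thin = thin_override or config.thin
        seed = int(seeds.spawn(1)[0].generate_state(1)[0] % (2**31))
        gibbs = GibbsConfig(
            sweeps=config.burnin + M * thin,
            burnin=config.burnin,
            thin=thin,
            seed=seed,
            init=xhat,
        )
        sim = simulate_restricted(
            theta, self.spec, self.network.n, gibbs, use_numba=config.use_numba
        )
        return sim.stats

    @staticmethod
    def _param_change(theta, beta, theta_new, beta_new) -> float:
        old = np.concatenate([theta, beta])
        new = np.concatenate([theta_new, beta_new])
        return float(np.max(np.abs(new - old))) if old.size else 0.0


@dataclass
class GERGMResults:
    """Fitted-model container: estimates, uncertainty, tests, simulation."""

    model: GERGM
    theta: np.ndarray
    beta: np.ndarray
    vcov: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_outer: int
    M_used: int
    config: FitConfig
    xhat: RestrictedNetwork
    sample_stats: np.ndarray = field(repr=False)
    #: True when the estimated information matrix was not positive definite
    #: and its spectrum was floored; affected directions get very wide
    #: (conservative) intervals.  A symptom of a nearly unidentified ridge,
    #: typically density (edge_sum) against the location intercept.
    information_floored: bool = False

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.theta, self.beta])

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    def cov_params(self) -> np.ndarray:
        return self.vcov

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * sps.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        zc = sps.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack(
            [self.params - zc * self.bse, self.params + zc * self.bse]
        )

    def _indices(self, which) -> np.ndarray:
        names = self.param_names
        idx = []
        for w in np.atleast_1d(which):
            if isinstance(w, str):
                idx.append(names.index(w))
            else:
                idx.append(int(w))
        return np.asarray(idx, dtype=int)

    def wald_test(self, which) -> dict[str, float]:
        """Wald test of the block restriction that the named parameters are 0."""
        return est.wald_block_test(self.params, self.vcov, self._indices(which))

    def lr_test(self, null_result: "GERGMResults") -> dict[str, float]:
        """Likelihood-ratio test against a nested fit (Monte-Carlo noisy)."""
        if not len(self.loglik_trace) or not len(null_result.loglik_trace):
            raise ValueError("both fits need a log-likelihood trace")
        stat = 2.0 * (self.loglik_trace[-1] - null_result.loglik_trace[-1])
        df = self.params.size - null_result.params.size
        return {"statistic": float(stat), "df": int(df),
                "p": float(sps.chi2.sf(stat, df))}

    def simulate(self, nsim: int, seed: int | None = None,
                 burnin: int | None = None, thin: int = 1):
        """Simulate restricted networks from the fitted dependence model."""
        if nsim <= 0:
            raise ValueError("nsim must be positive")
        burnin = self.config.burnin if burnin is None else burnin
        gibbs = GibbsConfig(
            sweeps=burnin + nsim * thin, burnin=burnin, thin=thin,
            seed=seed, init=self.xhat,
        )
        return simulate_restricted(
            self.theta, self.model.spec, self.model.network.n, gibbs
        )

    def summary(self) -> str:
        """Plain-text coefficient table in the usual estimate/SE/z/p layout."""
        lines = [
            "Generalized ERGM fit",
            f"  family: {self.model.family}   n = {self.model.network.n}   "
            f"edges = {self.model.network.m}",
            f"  converged: {self.converged}   outer iterations: {self.n_outer}   "
            f"M = {self.M_used}",
            "",
            f"{'parameter':<20}{'estimate':>12}{'std err':>12}{'z':>9}{'P>|z|':>9}",
            "-" * 62,
        ]
        for name, estv, se, z, p in zip(
            self.param_names, self.params, self.bse, self.zvalues, self.pvalues
        ):
            lines.append(f"{name:<20}{estv:>12.4f}{se:>12.4f}{z:>9.2f}{p:>9.3f}")
        return "\n".join(lines)
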