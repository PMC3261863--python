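"""Estimation building blocks: MPLE, the beta-step, and the MCMC-MLE theta-step.

The joint log-likelihood splits into a dependence part over the restricted
network and a Jacobian (marginal) part:

    L(theta, beta) = theta' h(xhat(beta)) - log C(theta)
                     + sum_edges log f(y_ij | beta)

where xhat(beta) is the observed network mapped through the marginal CDF and
C(theta) is the intractable normalizing constant of the restricted-network
density.  C does not depend on beta, so the beta-step maximizes
theta'h(xhat(beta)) + log-Jacobian directly; the theta-step approximates the
log-ratio log C(theta)/C(theta_tilde) by importance sampling over networks
simulated at theta_tilde (Geyer-Thompson MCMC-MLE).  The maximum
pseudolikelihood estimate — the product of the truncated-exponential full
conditionals — supplies the starting value for theta.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats

from .marginals import (
    EdgeDesign,
    MarginalModel,
    log_marginal_density,
    to_restricted,
)
from .networks import RestrictedNetwork, ValuedNetwork, edge_pairs
from .sampler import truncexp_logz, truncexp_mean, truncexp_var
from .statistics import StatisticSpec, compute_statistics, delta_matrix


class ConvexHullError(RuntimeError):
    """The observed statistic vector lies outside the sampled convex hull.

    The MCMC-MLE update has no maximizer in this case; a fresh (larger)
    sample simulated at the current provisional theta is required.
    """


def mple(x: RestrictedNetwork, spec: StatisticSpec) -> np.ndarray:
    """Maximum pseudolikelihood estimate of theta on a restricted network.

    Maximizes the exact product of truncated-exponential full conditionals,
    sum_edges [a_ij x_ij - log((e^{a_ij} - 1)/a_ij)] with a_ij the per-edge
    linear coefficient; Newton-CG with analytic gradient and Hessian.
    For the independent-edge (edge_sum only) model this is the exact MLE.
    """
    pairs = edge_pairs(x.n, directed=True)
    D = delta_matrix(x, spec, pairs)  # (m, q), free of x_ij itself
    xe = x.edge_values()
    q = len(spec)

    def negll(theta: np.ndarray) -> float:
        a = D @ theta
        return float(-(a @ xe - truncexp_logz(a).sum()))

    def grad(theta: np.ndarray) -> np.ndarray:
        a = D @ theta
        return -(D.T @ (xe - truncexp_mean(a)))

    def hess(theta: np.ndarray) -> np.ndarray:
        a = D @ theta
        return D.T @ (D * truncexp_var(a)[:, None])

    res = optimize.minimize(
        negll, np.zeros(q), jac=grad, hess=hess, method="Newton-CG",
        options={"xtol": 1e-12, "maxiter": 500},
    )
    if not np.all(np.isfinite(res.x)) or np.max(np.abs(grad(res.x))) > 1e-5:
        raise RuntimeError(f"MPLE optimizer did not converge: {res.message}")
    return res.x


def fit_beta(
    y: ValuedNetwork,
    family: str,
    design: EdgeDesign,
    theta: np.ndarray,
    spec: StatisticSpec,
    bounds: tuple[float, float] | None = None,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Maximize theta'h(F(y|beta)) + log-Jacobian over beta.

    With theta = 0 this is exactly the independent marginal fit (ordinary
    least squares for the gaussian family, the Cauchy regression model for
    the cauchy family).  The interval family has no free parameters.
    """
    if family == "interval":
        return np.empty(0)
    theta = np.asarray(theta, dtype=float)
    ye = y.edge_values()
    Z = design.covariates
    dep = bool(np.any(theta != 0.0))

    def unpack(beta: np.ndarray) -> MarginalModel:
        return MarginalModel(family, beta, bounds)

    def negobj(beta: np.ndarray) -> float:
        model = unpack(beta)
        val = log_marginal_density(y, model, design)
        if dep:
            xhat = to_restricted(y, model, design)
            val += float(theta @ compute_statistics(xhat, spec))
        return -val

    def grad(beta: np.ndarray) -> np.ndarray:
        model = unpack(beta)
        g_eta = Z.T @ model.dlogpdf_dmu(ye, design)
        g_la = model.dlogpdf_dlogalpha(ye, design).sum()
        if dep:
            xhat = to_restricted(y, model, design)
            pairs = edge_pairs(y.n, y.directed)
            a = delta_matrix(xhat, spec, pairs) @ theta  # d(theta'h)/dx_e
            f = model.pdf(ye, design)
            mu = design.covariates @ model.eta
            g_eta = g_eta + Z.T @ (-a * f)  # dx_e/dmu = -f
            g_la = g_la + float((-a * f * (ye - mu)).sum())
        return -np.concatenate([g_eta, [g_la]])

    if start is None:
        eta0, *_ = np.linalg.lstsq(Z, ye, rcond=None)
        resid = ye - Z @ eta0
        if family == "cauchy":
            scale0 = max(stats.median_abs_deviation(resid), 1e-6)
        else:
            scale0 = max(resid.std(), 1e-6)
        start = np.concatenate([eta0, [np.log(scale0)]])

    res = optimize.minimize(
        negobj, start, jac=grad, method="BFGS",
        options={"gtol": 1e-9, "maxiter": 1000},
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"beta optimizer diverged: {res.message}")
    if np.max(np.abs(res.jac)) > 1e-4:
        # one Nelder-Mead polish before declaring failure
        res = optimize.minimize(negobj, res.x, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
    return res.x


def log_c_ratio(
    theta: np.ndarray, theta_tilde: np.ndarray, sample_stats: np.ndarray
) -> float:
    """Importance estimate of log C(theta)/C(theta_tilde).

    ``sample_stats`` holds h(x_m) for networks x_m simulated at theta_tilde;
    the estimator is log[(1/M) sum_m exp((theta - theta_tilde)' h(x_m))],
    evaluated with log-sum-exp.
    """
    w = sample_stats @ (np.asarray(theta) - np.asarray(theta_tilde))
    return float(special.logsumexp(w) - np.log(sample_stats.shape[0]))


def in_convex_hull(point: np.ndarray, cloud: np.ndarray, tol: float = 1e-9) -> bool:
    """Feasibility check: is ``point`` a convex combination of ``cloud`` rows?"""
    M, q = cloud.shape
    A_eq = np.vstack([cloud.T, np.ones((1, M))])
    b_eq = np.concatenate([point, [1.0]])
    res = optimize.linprog(
        np.zeros(M), A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * M,
        method="highs",
    )
    return res.status == 0


def update_theta(
    h_obs: np.ndarray,
    theta_tilde: np.ndarray,
    sample_stats: np.ndarray,
    check_hull: bool = True,
) -> np.ndarray:
    """One MCMC-MLE update of theta given a sample simulated at theta_tilde.

    Maximizes theta'h_obs - log[(1/M) sum_m exp((theta - theta_tilde)'h_m)].
    A maximizer exists and is unique only when h_obs lies inside the convex
    hull of the sampled statistics, which is checked up front.
    """
    h_obs = np.asarray(h_obs, dtype=float)
    theta_tilde = np.asarray(theta_tilde, dtype=float)
    H = np.asarray(sample_stats, dtype=float)
    if check_hull and not in_convex_hull(h_obs, H):
        raise ConvexHullError(
            "observed statistics lie outside the convex hull of the simulated "
            "sample; draw a fresh (larger) sample at the current theta"
        )

    def negobj(th: np.ndarray) -> float:
        return float(-(th @ h_obs) + log_c_ratio(th, theta_tilde, H))

    def grad(th: np.ndarray) -> np.ndarray:
        w = H @ (th - theta_tilde)
        w -= w.max()
        p = np.exp(w)
        p /= p.sum()
        return -(h_obs - H.T @ p)

    res = optimize.minimize(
        negobj, theta_tilde, jac=grad, method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"theta update diverged: {res.message}")
    return res.x


def joint_loglik(
    theta: np.ndarray,
    beta: np.ndarray,
    y: ValuedNetwork,
    family: str,
    design: EdgeDesign,
    spec: StatisticSpec,
    theta_tilde: np.ndarray,
    sample_stats: np.ndarray,
    bounds: tuple[float, float] | None = None,
) -> float:
    """Approximate joint log-likelihood with the importance-sampled log C ratio.

    Up to the additive constant -log C(theta_tilde), which cancels in all
    derivatives and likelihood differences.
    """
    model = MarginalModel(family, beta, bounds)
    xhat = to_restricted(y, model, design)
    val = float(np.asarray(theta) @ compute_statistics(xhat, spec))
    val -= log_c_ratio(theta, theta_tilde, sample_stats)
    val += log_marginal_density(y, model, design)
    return val


def numerical_hessian(f, x0: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Symmetric central-difference Hessian with relative steps."""
    x0 = np.asarray(x0, dtype=float)
    k = x0.size
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                val = (f(x0 + ei) - 2.0 * f(x0) + f(x0 - ei)) / h[i] ** 2
            else:
                val = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4.0 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return H


def vcov_estimate(
    theta: np.ndarray,
    beta: np.ndarray,
    y: ValuedNetwork,
    family: str,
    design: EdgeDesign,
    spec: StatisticSpec,
    sample_stats: np.ndarray,
    bounds: tuple[float, float] | None = None,
    param_names: list[str] | None = None,
    theta_tilde: np.ndarray | None = None,
) -> np.ndarray:
    """Negative-inverse Hessian of the approximate joint log-likelihood.

    Taken jointly over (theta, beta) at the final estimates.  The theta
    block is analytic — the curvature of the importance-sampled log
    normalizing constant is the importance-weighted covariance of the
    sampled statistic vectors (plain covariance when theta equals the
    anchor theta_tilde the sample was simulated at) — while the beta block
    and the theta/beta cross terms differentiate the deterministic parts
    (theta'h(xhat(beta)) and the log-Jacobian) by central differences,
    which keeps Monte-Carlo noise out of the numerical derivatives.
    """
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    q, k = theta.size, beta.size
    H = np.zeros((q + k, q + k))

    # theta block: -d2 logC/dtheta2 = -Cov_w(h), w the importance weights
    if theta_tilde is None:
        theta_tilde = theta
    lw = sample_stats @ (theta - np.asarray(theta_tilde, dtype=float))
    lw -= lw.max()
    w = np.exp(lw)
    w /= w.sum()
    hbar = w @ sample_stats
    centered = sample_stats - hbar
    H[:q, :q] = -(centered.T * w) @ centered

    def h_of_beta(b: np.ndarray) -> np.ndarray:
        model = MarginalModel(family, b, bounds)
        return compute_statistics(to_restricted(y, model, design), spec)

    if k:
        # cross block: d h(xhat(beta)) / d beta, deterministic
        hb = beta.copy()
        steps = 1e-5 * np.maximum(np.abs(beta), 1.0)
        J = np.empty((q, k))
        for j in range(k):
            hb[j] = beta[j] + steps[j]
            hi = h_of_beta(hb)
            hb[j] = beta[j] - steps[j]
            lo = h_of_beta(hb)
            hb[j] = beta[j]
            J[:, j] = (hi - lo) / (2.0 * steps[j])
        H[:q, q:] = J
        H[q:, :q] = J.T

        def g(b: np.ndarray) -> float:
            model = MarginalModel(family, b, bounds)
            xhat = to_restricted(y, model, design)
            return float(
                theta @ compute_statistics(xhat, spec)
                + log_marginal_density(y, model, design)
            )

        H[q:, q:] = numerical_hessian(g, beta)
    H = 0.5 * (H + H.T)

    info = -H
    eigval, eigvec = np.linalg.eigh(info)
    if eigval.max() <= 0:
        names = param_names or [f"p{i}" for i in range(H.shape[0])]
        block = "theta" if q and np.all(np.diag(info)[:q] <= 0) else "beta"
        raise RuntimeError(
            f"singular information matrix (offending block: {block}; "
            f"parameters {names})"
        )
    # Near-unidentified ridge (typically edge_sum against the location
    # intercept): Monte-Carlo noise can push a small eigenvalue of the
    # information matrix non-positive.  Floor the spectrum so the affected
    # direction reports a very large, conservative variance instead of an
    # invalid one; callers see `floored=True`.
    floor = 1e-6 * eigval.max()
    floored = bool(eigval.min() < floor)
    eigval = np.maximum(eigval, floor)
    vcov = (eigvec / eigval) @ eigvec.T
    return 0.5 * (vcov + vcov.T), floored


def wald_block_test(
    params: np.ndarray, vcov: np.ndarray, indices
) -> dict[str, float]:
    """Wald test of the block restriction params[indices] = 0.

    W = g' V_SS^{-1} g with g the restricted subvector; W ~ chi^2_{|S|}
    under the null.
    """
    indices = np.atleast_1d(np.asarray(indices, dtype=int))
    g = np.asarray(params, dtype=float)[indices]
    V = np.asarray(vcov, dtype=float)[np.ix_(indices, indices)]
    if np.all(g == 0.0):
        return {"statistic": 0.0, "df": int(indices.size), "p": 1.0}
    try:
        W = float(g @ np.linalg.solve(V, g))
    except np.linalg.LinAlgError as err:
        raise RuntimeError("singular sub-covariance in Wald test") from err
    df = int(indices.size)
    return {"statistic": W, "df": df, "p": float(stats.chi2.sf(W, df))}
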