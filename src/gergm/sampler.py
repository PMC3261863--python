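"""Gibbs sampling of restricted networks.

Because every dependence statistic is multilinear in the edges, the full
conditional of a single restricted edge x_ij given the rest of the network is
a truncated exponential on (0, 1):

    p(x_ij | rest) = a e^{a x_ij} / (e^a - 1),   a = theta' edge_delta(x, i, j)

which is sampled exactly by inverting its CDF.  When a = 0 the conditional is
uniform on (0, 1).  A Gibbs sweep redraws every ordered pair once, in the
fixed package edge enumeration, so a complete network is produced per sweep.

The sweep is implemented twice: a pure-NumPy reference (`gibbs_sweep`) and a
numba-compiled kernel used by `simulate_restricted` for long chains.  Both
consume the same pre-drawn uniform stream, so they produce identical chains
for identical seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .marginals import EdgeDesign, MarginalModel, to_observed
from .networks import CLAMP_EPS, RestrictedNetwork, ValuedNetwork, edge_pairs
from .statistics import StatisticSpec, compute_statistics_batch, edge_delta

#: |a| at or below this triggers the exact uniform limit of the conditional;
#: the closed-form inverse CDF is numerically unstable near a = 0.
A_TOL = 1e-8

# ---------------------------------------------------------------------------
# Truncated exponential on (0, 1): density a e^{ax}/(e^a - 1)
# ---------------------------------------------------------------------------


def truncexp_icdf(a: float, u) -> np.ndarray | float:
    """Inverse CDF of the (0,1)-truncated exponential with coefficient a.

    Evaluated in log-space for large |a| so that e^a never overflows.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly in (0, 1)")
    if abs(a) <= A_TOL:
        out = u.copy()
    elif a > 0:
        # log(1 + u(e^a - 1))/a = 1 + log(u + (1-u) e^{-a})/a
        out = 1.0 + np.log(u + (1.0 - u) * np.exp(-a)) / a
    else:
        out = np.log1p(u * np.expm1(a)) / a
    return out if out.ndim else float(out)


def draw_edge(a: float, u: float) -> float:
    """Exact draw of one restricted edge from its full conditional."""
    return float(truncexp_icdf(a, u))


def truncexp_cdf(a: float, x) -> np.ndarray:
    """CDF (e^{ax} - 1)/(e^a - 1) on (0, 1); uniform limit at a = 0."""
    x = np.asarray(x, dtype=float)
    if abs(a) <= A_TOL:
        return x.copy()
    if a > 0:
        # stable: expm1(ax)/expm1(a) with both positive
        return np.expm1(a * x) / np.expm1(a)
    return np.expm1(a * x) / np.expm1(a)


def truncexp_mean(a) -> np.ndarray | float:
    """Mean 1/(1 - e^{-a}) - 1/a, with the series 1/2 + a/12 - a^3/720 near 0."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = np.abs(a) < 1e-4
    s = a[small]
    out[small] = 0.5 + s / 12.0 - s**3 / 720.0
    b = a[~small]
    out[~small] = 1.0 / (-np.expm1(-b)) - 1.0 / b
    return out if out.ndim else float(out)


def truncexp_var(a) -> np.ndarray | float:
    """Variance 1/a^2 - 1/(4 sinh^2(a/2)); 1/12 - a^2/240 near 0."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = np.abs(a) < 1e-3
    s = a[small]
    out[small] = 1.0 / 12.0 - s**2 / 240.0
    b = a[~small]
    with np.errstate(over="ignore"):
        sinh2 = np.sinh(b / 2.0) ** 2
    out[~small] = np.where(
        np.isfinite(sinh2), 1.0 / b**2 - 0.25 / sinh2, 1.0 / b**2
    )
    return out if out.ndim else float(out)


def truncexp_logz(a) -> np.ndarray | float:
    """log[(e^a - 1)/a], the log normalizer; series a/2 + a^2/24 near 0."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = np.abs(a) < 1e-5
    s = a[small]
    out[small] = s / 2.0 + s**2 / 24.0
    b = a[~small]
    pos = b > 0
    bp, bn = b[pos], b[~pos]
    res = np.empty_like(b)
    res[pos] = bp + np.log1p(-np.exp(-bp)) - np.log(bp)
    res[~pos] = np.log(-np.expm1(bn)) - np.log(-bn)
    out[~small] = res
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Gibbs sweeps
# ---------------------------------------------------------------------------

_STAT_IDS = {
    "edge_sum": 0,
    "reciprocity": 1,
    "transitive_triads": 2,
    "cyclic_triads": 3,
    "in_two_stars": 4,
    "out_two_stars": 5,
}


def conditional_coefficient(
    x, theta: np.ndarray, spec: StatisticSpec, i: int, j: int
) -> float:
    """Linear coefficient a of x_ij in theta'h(x)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(spec),):
        raise ValueError(f"theta must have length {len(spec)}, got {theta.shape}")
    return float(theta @ edge_delta(x, spec, i, j))


def gibbs_sweep(
    x: RestrictedNetwork,
    theta: np.ndarray,
    spec: StatisticSpec,
    rng: np.random.Generator,
    uniforms: np.ndarray | None = None,
) -> RestrictedNetwork:
    """One full Gibbs sweep (reference implementation).

    Every off-diagonal edge is resampled once from its full conditional, in
    the fixed enumeration order, using the current values of all other edges.
    """
    values = x.values.copy()
    pairs = edge_pairs(x.n, directed=True)
    if uniforms is None:
        uniforms = rng.random(len(pairs))
    for e, (i, j) in enumerate(pairs):
        a = conditional_coefficient(values, theta, spec, int(i), int(j))
        values[i, j] = draw_edge(a, float(uniforms[e]))
    return RestrictedNetwork(values, directed=True, vertex_labels=x.vertex_labels)


def _kernel():
    """Build (once) the numba-compiled chain runner."""
    import numba

    @numba.njit(cache=False)
    def run(x, theta, stat_ids, scaling, pairs, uniforms, burnin, thin, samples, means):
        n = x.shape[0]
        sweeps = uniforms.shape[0]
        q = theta.shape[0]
        m = pairs.shape[0]
        kept = 0
        for s in range(sweeps):
            for e in range(m):
                i = pairs[e, 0]
                j = pairs[e, 1]
                a = 0.0
                for t in range(q):
                    sid = stat_ids[t]
                    if sid == 0:
                        d = 1.0
                    elif sid == 1:
                        d = x[j, i]
                    elif sid == 2:
                        d = 0.0
                        for c in range(n):
                            if c != i and c != j:
                                d += (
                                    x[i, c] * x[j, c]
                                    + x[c, i] * x[c, j]
                                    + x[i, c] * x[c, j]
                                )
                    elif sid == 3:
                        d = 0.0
                        for c in range(n):
                            if c != i and c != j:
                                d += x[j, c] * x[c, i]
                    elif sid == 4:
                        d = 0.0
                        for c in range(n):
                            if c != i and c != j:
                                d += x[c, j]
                    else:
                        d = 0.0
                        for c in range(n):
                            if c != i and c != j:
                                d += x[i, c]
                    a += theta[t] * d / scaling[t]
                u = uniforms[s, e]
                if abs(a) <= 1e-8:
                    val = u
                elif a > 0.0:
                    val = 1.0 + np.log(u + (1.0 - u) * np.exp(-a)) / a
                else:
                    val = np.log1p(u * np.expm1(a)) / a
                x[i, j] = val
            tot = 0.0
            for i in range(n):
                for j in range(n):
                    if i != j:
                        tot += x[i, j]
            means[s] = tot / m
            if s >= burnin and (s - burnin) % thin == 0 and kept < samples.shape[0]:
                samples[kept] = x
                kept += 1
        return kept

    return run


_compiled_kernel = None


def _get_kernel():
    global _compiled_kernel
    if _compiled_kernel is None:
        _compiled_kernel = _kernel()
    return _compiled_kernel


@dataclass
class GibbsConfig:
    """Chain configuration.

    ``sweeps`` is the total chain length including burn-in; the sampler keeps
    every ``thin``-th network after ``burnin`` sweeps.  ``init`` is one of
    "uniform", "dispersed" (U-shaped Beta(1/2, 1/2) start values, the
    overdispersed start used for multi-chain diagnostics) or a
    RestrictedNetwork to start from.
    """

    sweeps: int = 1000
    burnin: int = 200
    thin: int = 1
    seed: int | None = None
    init: object = "uniform"

    def __post_init__(self) -> None:
        if self.sweeps < 0 or self.burnin < 0:
            raise ValueError("sweeps and burnin must be nonnegative")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burnin > self.sweeps:
            raise ValueError("burnin exceeds total sweeps")


@dataclass
class SimulationResult:
    """Gibbs output: kept networks, their statistics, and the mean-edge trace."""

    samples: np.ndarray  # (n_kept, n, n) raw kept networks
    stats: np.ndarray  # (n_kept, q)
    mean_trace: np.ndarray  # (sweeps,) mean edge value per sweep
    chain_id: int = 0
    edge_series: np.ndarray | None = None  # (n_kept, m) kept per-edge values
    _networks: list | None = field(default=None, repr=False)

    @property
    def networks(self) -> list[RestrictedNetwork]:
        """Kept networks as containers (built lazily; samples is the fast path)."""
        if self._networks is None:
            self._networks = [
                RestrictedNetwork(v, directed=True) for v in self.samples
            ]
        return self._networks


def _init_values(n: int, init, rng: np.random.Generator) -> np.ndarray:
    if isinstance(init, RestrictedNetwork):
        if init.n != n:
            raise ValueError("init network size mismatch")
        return init.values.copy()
    if init == "uniform":
        values = rng.random((n, n))
    elif init == "dispersed":
        values = rng.beta(0.5, 0.5, size=(n, n))
    else:
        raise ValueError(f"unknown init {init!r}")
    np.fill_diagonal(values, 0.0)
    return np.clip(values, 1e-10, 1 - 1e-10)


def simulate_restricted(
    theta: np.ndarray,
    spec: StatisticSpec,
    n: int,
    config: GibbsConfig,
    use_numba: bool = True,
) -> SimulationResult:
    """Run one Gibbs chain and return the thinned post-burn-in networks."""
    if n < 2:
        raise ValueError("network needs at least 2 vertices")
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(spec),):
        raise ValueError(f"theta must have length {len(spec)}")
    rng = np.random.default_rng(config.seed)
    x = _init_values(n, config.init, rng)
    pairs = edge_pairs(n, directed=True)
    m = len(pairs)
    n_keep = max(0, (config.sweeps - config.burnin + config.thin - 1) // config.thin)
    # rng.random can return exactly 0.0, outside the open interval draw_edge needs
    uniforms = np.clip(rng.random((config.sweeps, m)), 1e-16, 1.0 - 1e-16)
    means = np.empty(config.sweeps)
    samples = np.empty((n_keep, n, n))

    if use_numba:
        kernel = _get_kernel()
        stat_ids = np.array([_STAT_IDS[s] for s in spec.names], dtype=np.int64)
        kept = kernel(
            x,
            theta,
            stat_ids,
            spec.scaling,
            pairs.astype(np.int64),
            uniforms,
            config.burnin,
            config.thin,
            samples,
            means,
        )
    else:
        kept = 0
        net = RestrictedNetwork(x, directed=True)
        for s in range(config.sweeps):
            net = gibbs_sweep(net, theta, spec, rng, uniforms=uniforms[s])
            means[s] = net.edge_values().mean()
            if s >= config.burnin and (s - config.burnin) % config.thin == 0:
                samples[kept] = net.values
                kept += 1
    samples = np.clip(samples[:kept], CLAMP_EPS, 1.0 - CLAMP_EPS)
    for v in samples:
        np.fill_diagonal(v, 0.0)
    stats = compute_statistics_batch(samples, spec) if kept else np.empty((0, len(spec)))
    edge_series = samples[:, pairs[:, 0], pairs[:, 1]] if kept else None
    return SimulationResult(
        samples=samples, stats=stats, mean_trace=means, edge_series=edge_series
    )


def simulate_observed(
    theta: np.ndarray,
    spec: StatisticSpec,
    model: MarginalModel,
    design: EdgeDesign | None,
    n: int,
    config: GibbsConfig,
) -> list[ValuedNetwork]:
    """Simulate restricted networks and map them onto the observed support."""
    sim = simulate_restricted(theta, spec, n, config)
    return [to_observed(x, model, design) for x in sim.networks]
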