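"""Synthetic-data scenarios: reproducible networks with known ground truth.

Every scenario simulates an observed network from a stated truth — a theta
vector on named dependence statistics plus a marginal family with known
beta — via a long Gibbs run on the restricted network followed by the
quantile transformation.  The generating parameters are returned alongside
the data so estimation can be tested for parameter recovery.

The module also houses the summary quantities used in the behavioral
simulation experiments on a 25-vertex network: the Pearson correlation
between the two edges of a dyad (reciprocity), the variance of in-degrees
(in-two-stars), and the conditional mean of the third edge of a transitive
triad given the other two (transitivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .marginals import EdgeDesign, MarginalModel, to_observed
from .networks import RestrictedNetwork, ValuedNetwork, edge_pairs
from .sampler import GibbsConfig, SimulationResult, simulate_restricted
from .statistics import StatisticSpec


@dataclass
class ScenarioSpec:
    """Fully reproducible generating recipe for one synthetic network."""

    name: str
    n: int
    statistics: tuple[str, ...]
    theta: np.ndarray
    family: str = "gaussian"
    beta: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0]))
    bounds: tuple[float, float] | None = None
    n_node_covariates: int = 0
    seed: int = 0
    burnin: int = 2000
    scaling: np.ndarray | None = None

    def spec(self) -> StatisticSpec:
        return StatisticSpec(self.statistics, self.scaling)


#: Truths kept inside the non-degenerate region (|theta| <= 2 at n <= 25);
#: outside a narrow region the chain collapses to the full or empty graph.
SCENARIOS: dict[str, ScenarioSpec] = {
    # two vertices, negative density and positive reciprocity effects;
    # the bivariate edge density is exactly computable by 2-D quadrature
    "two_vertex_reciprocity": ScenarioSpec(
        name="two_vertex_reciprocity",
        n=2,
        statistics=("edge_sum", "reciprocity"),
        theta=np.array([-2.0, 3.0]),
        family="gaussian",
        beta=np.array([0.0, 0.0]),
    ),
    # the main recovery target: modest dependence, gaussian marginal with
    # two node covariates expanded to sender/receiver columns
    "gaussian_recovery": ScenarioSpec(
        name="gaussian_recovery",
        n=15,
        statistics=("edge_sum", "reciprocity"),
        theta=np.array([-0.5, 0.8]),
        family="gaussian",
        beta=np.array([0.0, 1.0, -0.5, 0.0]),  # intercept, 2 covariates, log alpha
        n_node_covariates=2,
    ),
    # a miniature heavy-tailed flow network: cauchy marginal,
    # sender/receiver covariates, anti-reciprocal dependence
    "heavy_tail_flows": ScenarioSpec(
        name="heavy_tail_flows",
        n=20,
        statistics=("edge_sum", "reciprocity"),
        theta=np.array([0.5, -0.8]),
        family="cauchy",
        beta=np.array([0.0, 0.8, -0.6, 0.0]),
        n_node_covariates=2,
    ),
}


def _covariate_design(
    n: int, n_node_covariates: int, rng: np.random.Generator
) -> EdgeDesign:
    """Standard-normal node attributes expanded to sender/receiver columns."""
    m_pairs = edge_pairs(n, directed=True)
    cols = [np.ones(len(m_pairs))]
    names = ["intercept"]
    for k in range(n_node_covariates):
        attr = rng.standard_normal(n)
        if k % 2 == 0:
            cols.append(attr[m_pairs[:, 0]])
            names.append(f"attr{k}_sender")
        else:
            cols.append(attr[m_pairs[:, 1]])
            names.append(f"attr{k}_receiver")
    return EdgeDesign(np.column_stack(cols), names)


def make_scenario(spec: ScenarioSpec | str, seed: int | None = None) -> dict:
    """Simulate one observed network from a scenario's stated truth.

    Returns a dict with keys ``network`` (ValuedNetwork), ``restricted``
    (the latent draw), ``design`` (EdgeDesign) and ``truth`` (ScenarioSpec).
    """
    if isinstance(spec, str):
        if spec not in SCENARIOS:
            raise ValueError(f"unknown scenario {spec!r}; have {sorted(SCENARIOS)}")
        spec = SCENARIOS[spec]
    if seed is not None:
        spec = ScenarioSpec(**{**spec.__dict__, "seed": seed})
    rng = np.random.default_rng(spec.seed)
    design = _covariate_design(spec.n, spec.n_node_covariates, rng)
    stat_spec = spec.spec()
    gibbs = GibbsConfig(
        sweeps=spec.burnin + 1,
        burnin=spec.burnin,
        thin=1,
        seed=int(rng.integers(2**31)),
        init="uniform",
    )
    sim = simulate_restricted(np.asarray(spec.theta, float), stat_spec, spec.n, gibbs)
    x = sim.networks[-1]
    if spec.family == "interval":
        model = MarginalModel("interval", np.empty(0), spec.bounds)
    else:
        model = MarginalModel(spec.family, np.asarray(spec.beta, float), spec.bounds)
    y = to_observed(x, model, design)
    return {"network": y, "restricted": x, "design": design, "truth": spec}


# ---------------------------------------------------------------------------
# Behavioral summaries over sets of simulated networks
# ---------------------------------------------------------------------------


def _as_value_list(networks) -> list[np.ndarray]:
    out = []
    for net in networks:
        if isinstance(net, (RestrictedNetwork, ValuedNetwork)):
            out.append(net.values)
        else:
            out.append(np.asarray(net, dtype=float))
    if len(out) < 1:
        raise ValueError("need at least one network")
    return out


def dyad_correlation(networks) -> float:
    """Pearson correlation between x_ij and x_ji pooled over dyads and networks."""
    mats = _as_value_list(networks)
    n = mats[0].shape[0]
    iu, ju = np.triu_indices(n, k=1)
    a = np.concatenate([m[iu, ju] for m in mats])
    b = np.concatenate([m[ju, iu] for m in mats])
    if a.size < 2:
        raise ValueError("need at least two dyad observations")
    return float(np.corrcoef(a, b)[0, 1])


def indegree_variance(networks) -> float:
    """Mean (over networks) variance of the column sums (valued in-degrees)."""
    mats = _as_value_list(networks)
    return float(np.mean([m.sum(axis=0).var() for m in mats]))


def third_edge_mean_surface(networks, bins: int = 5) -> np.ndarray:
    """Mean of the closing edge x_ik binned by the path edges (x_ij, x_jk).

    Returns a (bins, bins) grid; cell (r, c) averages x_ik over all ordered
    triples (across all networks) whose x_ij falls in bin r and x_jk in bin
    c.  Under positive transitivity the surface increases toward the
    high/high corner.  Empty cells are NaN.
    """
    mats = _as_value_list(networks)
    n = mats[0].shape[0]
    edges = np.linspace(0.0, 1.0, bins + 1)
    total = np.zeros((bins, bins))
    count = np.zeros((bins, bins))
    idx = np.arange(n)
    for m in mats:
        for i in idx:
            for j in idx:
                if j == i:
                    continue
                for k in idx:
                    if k == i or k == j:
                        continue
                    r = min(int(m[i, j] * bins), bins - 1)
                    c = min(int(m[j, k] * bins), bins - 1)
                    total[r, c] += m[i, k]
                    count[r, c] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / count, np.nan)


def dependence_grid(
    statistic: str,
    grid,
    n: int = 25,
    nsim: int = 1000,
    seed: int | None = None,
    burnin: int = 500,
    scaling: float | None = None,
) -> dict[float, SimulationResult]:
    """Simulate ``nsim`` networks at each parameter value of a one-statistic model.

    The workhorse of the behavioral experiments: vary one dependence
    parameter over ``grid`` and return the simulated networks per point.
    ``scaling`` divides the statistic (useful to keep star statistics O(1)
    on larger networks).
    """
    spec = StatisticSpec([statistic], None if scaling is None else [scaling])
    seeds = np.random.SeedSequence(seed).spawn(len(list(grid)))
    out = {}
    for point, ss in zip(grid, seeds):
        gibbs = GibbsConfig(
            sweeps=burnin + nsim,
            burnin=burnin,
            thin=1,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            init="uniform",
        )
        out[float(point)] = simulate_restricted(np.array([point]), spec, n, gibbs)
    return out
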