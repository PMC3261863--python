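"""MCMC convergence and degeneracy diagnostics, and simulation-based GOF.

Exponential-family network distributions can be degenerate: for much of the
parameter space the chain collapses toward the full graph (all edges near
their maximum) or the empty graph.  An estimated model is checked by
simulating long chains and asking (a) whether the grand mean edge value
stays near the observed mean rather than near 0 or 1, and (b) whether
standard MCMC diagnostics — the Geweke two-window z and the Gelman-Rubin
shrink factor — show any evidence of non-convergence.  Values of |z| above
about 2, or shrink factors at or above 1.1, conventionally flag trouble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .sampler import SimulationResult
from .statistics import compute_statistics


@dataclass
class ChainSummary:
    """Per-chain traces used by the diagnostics.

    per_sweep_mean : mean edge value at every sweep (trace-plot series).
    per_edge_series : optional (kept sweeps, m) array of thinned edge values.
    """

    per_sweep_mean: np.ndarray
    per_edge_series: np.ndarray | None = None
    chain_id: int = 0

    @classmethod
    def from_simulation(cls, sim: SimulationResult, chain_id: int = 0):
        return cls(
            per_sweep_mean=sim.mean_trace,
            per_edge_series=sim.edge_series,
            chain_id=chain_id,
        )


def spectral_density_zero(series: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density of a series at frequency zero via an AR fit.

    Fits autoregressions of order 0..max_order by least squares, picks the
    order by AIC, and returns sigma^2 / (1 - sum(phi))^2 — the standard
    time-series variance estimate used by the Geweke diagnostic.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if max_order is None:
        max_order = min(20, n // 20)
    x = series - series.mean()
    best = (np.inf, float(x.var()), 0.0)
    for p in range(max_order + 1):
        if p == 0:
            sigma2 = float(x.var())
            phi_sum = 0.0
        else:
            Y = x[p:]
            Xlag = np.column_stack([x[p - k: n - k] for k in range(1, p + 1)])
            phi, *_ = np.linalg.lstsq(Xlag, Y, rcond=None)
            resid = Y - Xlag @ phi
            sigma2 = float(resid @ resid / Y.size)
            phi_sum = float(phi.sum())
        if sigma2 <= 0:
            continue
        aic = (n - p) * np.log(sigma2) + 2.0 * (p + 1)
        if aic < best[0]:
            best = (aic, sigma2, phi_sum)
    _, sigma2, phi_sum = best
    denom = (1.0 - phi_sum) ** 2
    if denom <= 0:
        denom = 1e-12
    return sigma2 / denom


def geweke_z(
    series: np.ndarray, first_frac: float = 0.1, last_frac: float = 0.5
) -> float:
    """Geweke two-window convergence z-score.

    Compares the mean of an early window (first ``first_frac`` of the chain)
    with a late window (last ``last_frac``), standardized by
    spectral-density-at-zero estimates of each window's variance.  Under
    convergence the statistic is standard normal; |z| > 2 flags trouble.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 100:
        raise ValueError("series too short for the Geweke diagnostic (need >= 100)")
    if not (0 < first_frac and 0 < last_frac and first_frac + last_frac <= 1.0):
        raise ValueError("windows overlap: first_frac + last_frac must be <= 1")
    na, nb = int(np.floor(first_frac * n)), int(np.floor(last_frac * n))
    a, b = series[:na], series[n - nb:]
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("degenerate (constant) window; Geweke z undefined")
    s_a = spectral_density_zero(a)
    s_b = spectral_density_zero(b)
    return float((a.mean() - b.mean()) / np.sqrt(s_a / na + s_b / nb))


def gelman_rubin(chains, dof_correction: bool = False) -> float:
    """Gelman-Rubin shrink factor R-hat for >= 2 chains of equal length.

    W is the mean within-chain variance, B = n * variance of the chain
    means; the pooled variance is ((n-1)/n) W + B/n and
    R-hat = sqrt(pooled / W).  Values at or above 1.1 conventionally
    indicate non-convergence.  ``dof_correction`` applies the
    (m+1)/m - (n-1)/(m n) sampling-variability correction.
    """
    chains = [np.asarray(c, dtype=float) for c in chains]
    if len(chains) < 2:
        raise ValueError("Gelman-Rubin needs at least 2 chains")
    n = chains[0].size
    if n < 10 or any(c.size != n for c in chains):
        raise ValueError("chains must share a common length >= 10")
    mchains = len(chains)
    means = np.array([c.mean() for c in chains])
    W = float(np.mean([c.var(ddof=1) for c in chains]))
    if W == 0.0:
        raise ValueError("zero within-chain variance; R-hat undefined")
    B = n * float(means.var(ddof=1))
    sigma2 = (n - 1) / n * W + B / n
    r2 = sigma2 / W
    if dof_correction:
        r2 = (mchains + 1) / mchains * r2 - (n - 1) / (mchains * n)
    return float(np.sqrt(r2))


@dataclass
class DegeneracyReport:
    degenerate: bool
    grand_mean: float
    observed_mean: float
    geweke_z: np.ndarray | None
    share_abs_z_gt_2: float | None
    rhat: np.ndarray | None
    n_rhat_ge_1_1: int | None
    gelman_rubin_available: bool

    def verdict(self) -> str:
        lines = []
        if self.degenerate:
            lines.append(
                f"DEGENERATE: simulated grand mean edge value {self.grand_mean:.4f} "
                f"is closer to 0 or 1 than to the observed mean "
                f"{self.observed_mean:.4f}."
            )
        else:
            lines.append(
                f"no degeneracy: grand mean {self.grand_mean:.4f} vs observed "
                f"{self.observed_mean:.4f}"
            )
        if self.share_abs_z_gt_2 is not None:
            lines.append(f"share of per-edge |Geweke z| > 2: {self.share_abs_z_gt_2:.3f}")
        if self.gelman_rubin_available:
            lines.append(f"per-edge R-hat >= 1.1: {self.n_rhat_ge_1_1}")
        else:
            lines.append("Gelman-Rubin: unavailable (needs >= 2 chains)")
        return "\n".join(lines)


def degeneracy_report(
    chains: list[ChainSummary], observed_mean: float
) -> DegeneracyReport:
    """Two-pronged degeneracy check on one or more simulated chains.

    Flags the model as degenerate when the grand mean edge value over all
    chains sits closer to 0 or to 1 than to the observed network's mean edge
    value.  When per-edge series are present, per-edge Geweke z-scores are
    compared against the null standard normal; with >= 2 chains per-edge
    Gelman-Rubin shrink factors and the count at or above 1.1 are reported.
    """
    if not chains:
        raise ValueError("need at least one chain")
    grand_mean = float(np.mean([c.per_sweep_mean.mean() for c in chains]))
    degenerate = min(abs(grand_mean - 0.0), abs(grand_mean - 1.0)) < abs(
        grand_mean - observed_mean
    )

    zs = None
    share = None
    have_series = all(c.per_edge_series is not None for c in chains)
    if have_series:
        zlist = []
        for c in chains:
            for e in range(c.per_edge_series.shape[1]):
                s = c.per_edge_series[:, e]
                if s.size >= 100 and s.std() > 0:
                    zlist.append(geweke_z(s))
        if zlist:
            zs = np.asarray(zlist)
            share = float(np.mean(np.abs(zs) > 2.0))

    rhat = None
    n_flag = None
    gr_ok = len(chains) >= 2 and have_series
    if gr_ok:
        m_edges = chains[0].per_edge_series.shape[1]
        rhat = np.array(
            [
                gelman_rubin([c.per_edge_series[:, e] for c in chains])
                for e in range(m_edges)
            ]
        )
        n_flag = int(np.sum(rhat >= 1.1))
    return DegeneracyReport(
        degenerate=degenerate,
        grand_mean=grand_mean,
        observed_mean=float(observed_mean),
        geweke_z=zs,
        share_abs_z_gt_2=share,
        rhat=rhat,
        n_rhat_ge_1_1=n_flag,
        gelman_rubin_available=gr_ok,
    )


def gof_dependence(
    result, nsim: int, seed: int | None = None, burnin: int | None = None
) -> dict[str, dict]:
    """Simulation-based goodness of fit on the dependence statistics.

    Simulates ``nsim`` restricted networks from the fitted dependence model,
    computes every statistic in the fitted spec on each, and locates the
    statistic of the estimated latent network xhat among them.  A statistic
    whose observed value falls inside the simulated inter-quartile range is
    taken as well fit.
    """
    if nsim <= 0:
        raise ValueError("nsim must be positive")
    spec = result.model.spec
    sim = result.simulate(nsim, seed=seed, burnin=burnin)
    observed = compute_statistics(result.xhat, spec)
    out = {}
    for k, name in enumerate(spec.names):
        simulated = sim.stats[:, k]
        pct = float(np.mean(simulated <= observed[k]))
        q1, q3 = np.percentile(simulated, [25, 75])
        out[name] = {
            "simulated": simulated,
            "observed": float(observed[k]),
            "percentile": pct,
            "in_iqr": bool(q1 <= observed[k] <= q3),
        }
    return out
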