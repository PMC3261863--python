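# Methods

This note records the statistical model the package implements, the
numerical choices behind the implementation, what the synthetic scenarios
do and do not emulate, and the known limitations.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model

The observed network `Y` (n vertices, directed, continuous edges, no
self-loops) is modeled in two layers.

**Dependence layer.**  A latent restricted network `X` with off-diagonal
entries in (0, 1) follows

    p(X | θ) = exp(θ' h(X)) / C(θ),   C(θ) = ∫ exp(θ' h(X)) dX,

with the integral over the unit hypercube of edge values.  Each statistic
in `h` is a sum of edge products over subgraphs:

| name | definition | configurations at size n |
| --- | --- | --- |
| `edge_sum` | Σ_{i≠j} x_ij | n(n−1) |
| `reciprocity` | Σ_{i<j} x_ij x_ji | n(n−1)/2 |
| `transitive_triads` | Σ over ordered distinct triples x_ij x_jk x_ik | n(n−1)(n−2) |
| `cyclic_triads` | both directed 3-cycles per unordered triple | n(n−1)(n−2)/3 |
| `in_two_stars` | Σ_j Σ_{i<k} x_ij x_kj | n(n−1)(n−2)/2 |
| `out_two_stars` | Σ_i Σ_{j<k} x_ij x_ik | n(n−1)(n−2)/2 |

The transitive-triad convention is the six-term-per-unordered-triple
ordered sum (matching standard ERGM practice); on the complete 3-vertex
digraph the statistics evaluate to their configuration counts
(6, 3, 6, 2, 3, 3), which the test suite pins against brute-force
enumeration.  All statistics are bounded on the hypercube, so C(θ) is
finite for every θ — the property that makes arbitrary product statistics
admissible for continuous edges.  Each statistic accepts an optional
positive scaling divisor (`StatisticSpec.scaling`); dividing by the
configuration count keeps statistics, and hence θ, comparable across
network sizes.  Statistics involving edge direction raise an error on
undirected networks rather than silently collapsing.

**Marginal layer.**  Observed edges are `y_ij = T(x_ij)` with `T` the
quantile function of a location–scale family: gaussian or Cauchy with
`μ_ij = z_ij' η` on per-edge covariates (intercept first) and a single
scale α shared across edges, or the fixed linear map onto an interval
(a, b) for bounded edges.  `X = F(Y)` is therefore the network of joint
quantiles of `Y`.  The joint density of `Y` is the restricted-network
density times the diagonal Jacobian Π f(y_ij), so

    log L(θ, β) = θ' h(F(Y|β)) − log C(θ) + Σ log f(y_ij | β).

At θ = 0 the latent edges are jointly uniform, the edges of `Y` are
independent with the stated marginals, and the fit reduces exactly to the
corresponding regression (verified against closed-form least squares and a
direct Cauchy-regression MLE in the acceptance suite).  The scale is
carried as log α during optimization so positivity is structural.  Any
object with `cdf` / `quantile` / `log_pdf` in the same signature plugs in
as a further family; discrete marginals are out of scope.

Edge enumeration is fixed everywhere: row-major over ordered pairs (i, j),
i ≠ j, 0-based (upper triangle for undirected containers).  Restricted
values are clamped to [1e−10, 1 − 1e−10] because CDF transforms of extreme
observations can reach machine 0/1.

## Simulation

Multilinearity gives each edge the full conditional

    p(x_ij | rest) ∝ exp(a x_ij) on (0, 1),
    a = θ' [h(x_ij = 1) − h(x_ij = 0)],

whose coefficient has a closed form per statistic (`edge_delta`).  The
inverse CDF is `log(1 + u(e^a − 1))/a`, evaluated as
`1 + log(u + (1−u)e^{−a})/a` for a > 0 so that e^a never overflows; the
uniform limit is used for |a| ≤ 1e−8, where the closed form loses
precision.  A Gibbs sweep redraws every ordered pair once in enumeration
order (fixed scan — chosen for reproducibility).  The truncated-exponential
mean, variance and log-normalizer used throughout estimation switch to
series expansions near a = 0 (thresholds 1e−4, 1e−3, 1e−5 respectively,
set where the direct formulas lose about half their digits).

The sweep exists twice: a pure-NumPy reference implementation (the tested
contract) and a numba kernel used for long chains.  Both consume one
pre-drawn uniform stream, so they produce identical chains for identical
seeds — asserted to 1e−12 in the tests.  Uniform variates are clipped to
(1e−16, 1 − 1e−16) because the generator can return exactly 0.  Dispersed
multi-chain starts draw from Beta(1/2, 1/2), a U-shaped distribution on
the unit interval.

## Estimation

The fitting loop (`GERGM.fit`) is:

1. β⁰ ← independent marginal MLE (θ = 0); x̂ ← F(Y | β⁰).
2. θ⁰ ← maximum pseudolikelihood estimate on x̂: the product of
   truncated-exponential full conditionals is maximized by Newton–CG with
   analytic gradient and Hessian (the per-edge coefficient matrix does not
   depend on the edge itself, so the pseudolikelihood is globally concave
   in θ).  For the edge_sum-only model MPLE equals the MLE.
3. Repeat until max |Δparameter| < tol or `max_outer` iterations:
   simulate M networks at the provisional θ̃ (Gibbs, burn-in, thinning,
   chain started at x̂); update θ by maximizing
   θ'h(x̂) − log[(1/M) Σ_m exp((θ − θ̃)' h(x_m))] (log-sum-exp, BFGS with
   analytic gradient); update β by maximizing θ'h(F(Y|β)) + Σ log f
   (BFGS with analytic gradient — the chain rule through the CDF uses the
   per-edge conditional coefficients and the marginal score).
4. Covariance: negative inverse Hessian of the approximated joint
   log-likelihood at the final estimates, from a fresh, larger sample
   anchored at the final θ.

A maximizer of the importance-sampled objective exists and is unique only
when h(x̂) lies inside the convex hull of the simulated statistics; this
is checked by linear programming before every update, and a violation
triggers one fresh doubled-size sample before raising `ConvexHullError`.

**Covariance details.**  The θ-block of the Hessian is analytic: the
curvature of the importance-sampled log C is the (weighted) covariance of
the sampled statistic vectors.  The θ/β cross block differentiates the
deterministic map h(x̂(β)) by central differences, and the β block is the
central-difference Hessian (relative step 1e−5) of the deterministic part
θ'h(F(Y|β)) + Σ log f — this keeps Monte-Carlo noise out of every
numerical derivative.  Because a covariance estimate needs more precision
than a point update, the final sample defaults to max(2000, 2M) networks
thinned by 2 (`FitConfig.M_vcov`, `thin_vcov`).

Density-type and location parameters (edge_sum against the marginal
intercept) span a nearly unidentified ridge: both shift the overall edge
level, and the joint information along that direction is small.  Sampling
noise can push the estimated information matrix indefinite there.  The
spectrum is floored at 1e−6 of the largest eigenvalue, so an affected
direction reports a very large (conservative) variance rather than an
invalid one; `GERGMResults.information_floored` records when this
happened.  A matrix with no positive eigenvalues raises an error naming
the offending block.

Defaults: M = 1000 per update, burn-in 500 sweeps, thinning 1,
tol = 1e−4, max 25 outer iterations.  With Monte-Carlo jitter at moderate
M the parameter change rarely falls below a tight tolerance; the result
then carries `converged = False` with the final iterates, which is a
statement about the stopping rule, not about estimate validity.  Wald
block tests use W = γ̂' V̂⁻¹ γ̂ against χ²; a likelihood-ratio variant based
on differences of the approximated log-likelihood is provided but flagged
as Monte-Carlo-noisy.  The Hessian is joint over (θ, β); a blockwise
variant is not exposed.

## Diagnostics

Exponential-family network models degenerate over much of their parameter
space: the chain collapses toward the all-maximal or all-minimal graph.
`degeneracy_report` flags a fitted model when the grand mean edge value of
its simulated chains is closer to 0 or 1 than to the observed mean, and
aggregates per-edge convergence diagnostics:

* **Geweke z** — compares the first 10% and last 50% of a chain (standard
  window choice), standardized by spectral-density-at-zero estimates from
  an autoregression fitted by least squares with AIC order selection (up
  to order 20).  Constant windows raise a degenerate-series error.
* **Gelman–Rubin R̂** — W the mean within-chain variance, B = n·var of
  chain means, σ̂² = ((n−1)/n)W + B/n, R̂ = √(σ̂²/W); reported without
  degrees-of-freedom correction by default (the corrected variant is a
  flag).  Two identical chains give exactly √((n−1)/n).  Requires ≥ 2
  chains; with one chain the report marks the section unavailable.

Calibration, measured by the acceptance suite: on iid chains of length
10,000 the Geweke |z| > 1.96 rate sits near 5% and iid-chain R̂ stays
below 1.01.  Simulation-based goodness of fit (`gof_dependence`) draws
networks from the fitted dependence model, computes each statistic, and
locates the statistic of x̂ among them; falling inside the simulated
inter-quartile range is taken as adequate fit.

## Synthetic scenarios

`gergm.scenarios` generates every test input programmatically.  A scenario
fixes n, the statistic list, true θ, a marginal family with true β, a
covariate recipe (standard-normal node attributes expanded to sender or
receiver columns), and a seed; data are produced by a 2,000-sweep Gibbs
run followed by the quantile transformation, and regenerate byte-identically
from the seed.  Shipped truths sit inside the non-degenerate region
(|θ| ≤ 2 at n ≤ 25, scaled star statistics); the tests assert their latent
mean edge values stay in (0.1, 0.9).

Study sizes used by the verification suite, chosen to resolve each
quantity while keeping the default run in minutes: 100,000 draws for
sampler exactness; M = 5,000 for the normalizing-constant check on the
n = 5 independent model; 50 recovery replicates at n = 15 with
θ = (−0.5, 0.8), M = 500 per update; 100,000 sweeps for the two-vertex
density comparison on a 10×10 histogram against a 400×400 quadrature grid;
1,000 networks per grid point at n = 25 for the behavioral monotonicity
experiments (the in-two-star statistic scaled by n − 2 = 23 to keep its
conditional coefficient O(1)); 500 replicates of length-10,000 chains for
Geweke calibration.

What the scenarios do **not** emulate about real valued networks: missing
or censored dyads (the model requires all ordered pairs observed), zero
inflation, temporal dependence, covariate measurement error, and
marginal-family misspecification (except where a test constructs it
deliberately).  Passing recovery tests therefore demonstrate correctness
of the estimation machinery under the stated model, not robustness to
violations of it.

## Known limitations

* Dependence is specified on the joint-quantile network, so inference
  about θ is conditional on the marginal family; substantially different
  marginal choices change the latent network and can change dependence
  conclusions.  Nested marginal alternatives can be compared with Wald
  tests, simulation-based GOF, or the (noisy) LR variant.
* Subgraph-product statistics are degeneracy-prone outside a narrow
  parameter region, like their binary-ERGM counterparts; the package
  diagnoses degeneracy but does not implement degeneracy-resistant
  statistic families (e.g. geometrically weighted terms).
* The asymptotic Wald intervals are honest but approximate at small n:
  in the n = 15 recovery study the dependence-parameter coverage sits
  near the nominal boundary, and the information matrix can need the
  spectrum floor described above.
* Single shared scale α (no per-edge dispersion model); directed networks
  are the primary target — undirected input is accepted by the containers
  but only `edge_sum` among the statistics applies.
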