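"""Edgewise marginal transformations between restricted and observed scales.

The joint model places exponential-family dependence on a latent network X
with edges in (0, 1) and maps each latent edge onto the observed support by a
strictly increasing parameterized transformation T — exactly the quantile
function of a chosen marginal family.  Its inverse T^{-1} is the family CDF,
so X is the network of joint quantiles of Y, and the Jacobian of the change
of variables is diagonal with the marginal densities on the diagonal.

Families
--------
gaussian : location mu_ij = z_ij' eta, shared scale alpha > 0.
cauchy   : location-scale Cauchy; heavy tails (the natural choice when the
           empirical edge kurtosis dwarfs the normal's 3).
interval : fixed bounds a < b, the linear map y = a + (b - a) x; suited to
           networks of correlation coefficients via (a, b) = (-1, 1).

The per-edge location is a linear model mu_ij = z_ij' eta on an
:class:`EdgeDesign` whose rows follow the package edge enumeration
(row-major over ordered pairs, 0-based).  The scale alpha is shared across
edges (constant-variance analogue) and is carried on the log scale during
optimization to stay positive.  Any object exposing ``cdf``, ``quantile``
and ``log_pdf`` with the same signatures plugs in as an additional family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .networks import (
    RestrictedNetwork,
    ValuedNetwork,
    edge_pairs,
    from_edge_vector,
    n_edges,
)

FAMILIES = ("gaussian", "cauchy", "interval")


@dataclass
class EdgeDesign:
    """Per-edge covariate matrix z with an intercept first column.

    ``covariates`` is (m, p), rows in the package edge enumeration order.
    """

    covariates: np.ndarray
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        Z = np.asarray(self.covariates, dtype=float)
        if Z.ndim != 2 or Z.shape[1] < 1:
            raise ValueError("covariates must be an (m, p) array with p >= 1")
        if not np.allclose(Z[:, 0], 1.0):
            raise ValueError("first design column must be a constant intercept")
        self.covariates = Z
        if self.covariate_names is None:
            self.covariate_names = ["intercept"] + [
                f"x{k}" for k in range(1, Z.shape[1])
            ]
        if len(self.covariate_names) != Z.shape[1]:
            raise ValueError("covariate_names length must equal p")

    @property
    def m(self) -> int:
        return self.covariates.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @classmethod
    def intercept_only(cls, m: int) -> "EdgeDesign":
        return cls(np.ones((m, 1)), ["intercept"])


def edge_locations(design: EdgeDesign, eta: np.ndarray) -> np.ndarray:
    """Per-edge locations mu_ij = z_ij' eta in enumeration order."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (design.p,):
        raise ValueError(f"eta must have length p={design.p}, got {eta.shape}")
    return design.covariates @ eta


@dataclass
class MarginalModel:
    """Marginal family plus its parameter vector beta.

    For gaussian/cauchy, ``beta = (eta_1, ..., eta_p, log alpha)``; for the
    interval family beta is empty and ``bounds = (a, b)`` is fixed.
    """

    family: str
    beta: np.ndarray
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.family == "interval":
            if self.bounds is None or not self.bounds[0] < self.bounds[1]:
                raise ValueError("interval family needs bounds (a, b) with a < b")
            if self.beta.size != 0:
                raise ValueError("interval family takes no free parameters")
        else:
            if self.beta.size < 2:
                raise ValueError("beta must hold eta (>=1) plus log alpha")

    @property
    def eta(self) -> np.ndarray:
        return self.beta[:-1]

    @property
    def alpha(self) -> float:
        """Scale parameter (> 0 by the log parameterization)."""
        return float(np.exp(self.beta[-1]))

    def n_params(self) -> int:
        return self.beta.size

    # -- per-edge distribution functions ----------------------------------
    def _loc(self, design: EdgeDesign) -> np.ndarray:
        if self.family == "interval":
            raise ValueError("interval family has no location model")
        return edge_locations(design, self.eta)

    def cdf(self, y: np.ndarray, design: EdgeDesign) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.family == "gaussian":
            return stats.norm.cdf(y, loc=self._loc(design), scale=self.alpha)
        if self.family == "cauchy":
            mu = self._loc(design)
            return 0.5 + np.arctan((y - mu) / self.alpha) / np.pi
        a, b = self.bounds
        if np.any(y < a) or np.any(y > b):
            raise ValueError(f"edge values outside interval support [{a}, {b}]")
        return (y - a) / (b - a)

    def quantile(self, x: np.ndarray, design: EdgeDesign) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "gaussian":
            return stats.norm.ppf(x, loc=self._loc(design), scale=self.alpha)
        if self.family == "cauchy":
            mu = self._loc(design)
            return mu + self.alpha * np.tan(np.pi * (x - 0.5))
        a, b = self.bounds
        return a + (b - a) * x

    def log_pdf(self, y: np.ndarray, design: EdgeDesign) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.family == "gaussian":
            mu, alpha = self._loc(design), self.alpha
            return -0.5 * np.log(2.0 * np.pi) - np.log(alpha) - 0.5 * ((y - mu) / alpha) ** 2
        if self.family == "cauchy":
            mu, alpha = self._loc(design), self.alpha
            return -np.log(np.pi * alpha) - np.log1p(((y - mu) / alpha) ** 2)
        a, b = self.bounds
        if np.any(y < a) or np.any(y > b):
            raise ValueError(f"edge values outside interval support [{a}, {b}]")
        return np.full(y.shape, -np.log(b - a))

    # -- score pieces used by the beta-step optimizer ---------------------
    def pdf(self, y: np.ndarray, design: EdgeDesign) -> np.ndarray:
        return np.exp(self.log_pdf(y, design))

    def dlogpdf_dmu(self, y: np.ndarray, design: EdgeDesign) -> np.ndarray:
        """d log f / d mu per edge (location-scale families only)."""
        y = np.asarray(y, dtype=float)
        mu, alpha = self._loc(design), self.alpha
        r = y - mu
        if self.family == "gaussian":
            return r / alpha**2
        if self.family == "cauchy":
            return 2.0 * r / (alpha**2 + r**2)
        raise ValueError("interval family has no location parameters")

    def dlogpdf_dlogalpha(self, y: np.ndarray, design: EdgeDesign) -> np.ndarray:
        """d log f / d log(alpha) per edge."""
        y = np.asarray(y, dtype=float)
        mu, alpha = self._loc(design), self.alpha
        r2 = (y - mu) ** 2
        if self.family == "gaussian":
            return r2 / alpha**2 - 1.0
        if self.family == "cauchy":
            return 2.0 * r2 / (alpha**2 + r2) - 1.0
        raise ValueError("interval family has no scale parameter")


def _check_design(net_n: int, directed: bool, design: EdgeDesign | None) -> EdgeDesign:
    m = n_edges(net_n, directed)
    if design is None:
        return EdgeDesign.intercept_only(m)
    if design.m != m:
        raise ValueError(f"design has {design.m} rows but network has {m} edges")
    return design


def to_restricted(
    y: ValuedNetwork, model: MarginalModel, design: EdgeDesign | None = None
) -> RestrictedNetwork:
    """Map the observed network onto (0,1) by the edgewise marginal CDF."""
    design = _check_design(y.n, y.directed, design)
    x_edges = model.cdf(y.edge_values(), design)
    values = from_edge_vector(x_edges, y.n, y.directed)
    return RestrictedNetwork(values, directed=y.directed, vertex_labels=y.vertex_labels)


def to_observed(
    x: RestrictedNetwork, model: MarginalModel, design: EdgeDesign | None = None
) -> ValuedNetwork:
    """Map a restricted network onto the observed support by the quantile function."""
    design = _check_design(x.n, x.directed, design)
    y_edges = model.quantile(x.edge_values(), design)
    values = from_edge_vector(y_edges, x.n, x.directed)
    return ValuedNetwork(values, directed=x.directed, vertex_labels=x.vertex_labels)


def log_marginal_density(
    y: ValuedNetwork, model: MarginalModel, design: EdgeDesign | None = None
) -> float:
    """Sum of per-edge log densities: the log-Jacobian of the transformation."""
    design = _check_design(y.n, y.directed, design)
    return float(model.log_pdf(y.edge_values(), design).sum())
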