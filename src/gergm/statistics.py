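"""Dependence statistics h(X) on restricted networks.

Every statistic is a sum of products of edge values over small subgraphs
(dyads, triads, stars), so each is multilinear in the edges: holding all
other edges fixed, h is affine in any single edge x_ij.  That multilinearity
is what makes the Gibbs full conditional of one edge a truncated exponential
with a closed-form linear coefficient (see :mod:`gergm.sampler`), and it is
exploited here through :func:`edge_delta`, the exact per-edge coefficient
h(x_ij = 1) - h(x_ij = 0).

Implemented statistics (directed networks; X has zero diagonal):

``edge_sum``          sum_{i != j} x_ij
``reciprocity``       sum_{i < j} x_ij x_ji
``transitive_triads`` sum over ordered distinct triples (i,j,k) of
                      x_ij x_jk x_ik  (six terms per unordered triple)
``cyclic_triads``     both directed 3-cycles per unordered triple
``in_two_stars``      sum_j sum_{i<k, i,k != j} x_ij x_kj
``out_two_stars``     sum_i sum_{j<k, j,k != i} x_ij x_ik
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import RestrictedNetwork

STATISTIC_NAMES = (
    "edge_sum",
    "reciprocity",
    "transitive_triads",
    "cyclic_triads",
    "in_two_stars",
    "out_two_stars",
)

#: Statistics that are only meaningful on directed networks.
DIRECTED_ONLY = frozenset(
    {"reciprocity", "transitive_triads", "cyclic_triads", "in_two_stars", "out_two_stars"}
)


@dataclass
class StatisticSpec:
    """Ordered list of named dependence statistics with optional scaling.

    Parameters
    ----------
    names : sequence of str
        Unique names drawn from ``STATISTIC_NAMES``; order fixes the order of
        the statistic vector h and the parameter vector theta.
    scaling : sequence of float, optional
        Per-statistic positive divisor (default 1 for each).  Dividing a
        statistic by its number of subgraph configurations keeps values
        comparable across network sizes.
    """

    names: tuple[str, ...]
    scaling: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __init__(self, names, scaling=None):
        names = tuple(names)
        if len(names) == 0:
            raise ValueError("StatisticSpec needs at least one statistic")
        if len(set(names)) != len(names):
            raise ValueError("statistic names must be unique")
        for name in names:
            if name not in STATISTIC_NAMES:
                raise ValueError(
                    f"unknown statistic {name!r}; choose from {STATISTIC_NAMES}"
                )
        self.names = names
        if scaling is None:
            scaling = np.ones(len(names))
        scaling = np.asarray(scaling, dtype=float)
        if scaling.shape != (len(names),) or np.any(scaling <= 0):
            raise ValueError("scaling must be one positive divisor per statistic")
        self.scaling = scaling

    def __len__(self) -> int:
        return len(self.names)

    def check_directed(self, directed: bool) -> None:
        if not directed:
            bad = [s for s in self.names if s in DIRECTED_ONLY]
            if bad:
                raise ValueError(
                    f"statistics {bad} require a directed network"
                )

    def config_counts(self, n: int) -> np.ndarray:
        """Number of subgraph configurations per statistic at size n.

        This is the upper bound of each unscaled statistic when all edges
        are 1, and the natural scaling divisor for cross-n comparability.
        """
        counts = {
            "edge_sum": n * (n - 1),
            "reciprocity": n * (n - 1) // 2,
            "transitive_triads": n * (n - 1) * (n - 2),
            "cyclic_triads": n * (n - 1) * (n - 2) // 3,
            "in_two_stars": n * (n - 1) * (n - 2) // 2,
            "out_two_stars": n * (n - 1) * (n - 2) // 2,
        }
        return np.array([counts[s] for s in self.names], dtype=float)


def _stat_matrix(x) -> np.ndarray:
    if isinstance(x, RestrictedNetwork):
        return x.values
    x = np.asarray(x, dtype=float).copy()
    np.fill_diagonal(x, 0.0)
    return x


def compute_statistics(x, spec: StatisticSpec) -> np.ndarray:
    """Evaluate the statistic vector h(x) in spec order (scaled)."""
    X = _stat_matrix(x)
    out = np.empty(len(spec))
    XX = None
    for idx, name in enumerate(spec.names):
        if name == "edge_sum":
            val = X.sum()
        elif name == "reciprocity":
            val = (X * X.T).sum() / 2.0
        elif name == "transitive_triads":
            if XX is None:
                XX = X @ X
            # path i->j->k closed by i->k; zero diagonal kills i=j, j=k, i=k
            val = (XX * X).sum()
        elif name == "cyclic_triads":
            if XX is None:
                XX = X @ X
            # trace(X^3) counts each directed 3-cycle three times
            val = (XX * X.T).sum() / 3.0
        elif name == "in_two_stars":
            col = X.sum(axis=0)
            val = ((col**2 - (X**2).sum(axis=0)) / 2.0).sum()
        elif name == "out_two_stars":
            row = X.sum(axis=1)
            val = ((row**2 - (X**2).sum(axis=1)) / 2.0).sum()
        else:  # pragma: no cover - guarded by StatisticSpec
            raise ValueError(f"unknown statistic {name!r}")
        out[idx] = val / spec.scaling[idx]
    return out


def compute_statistics_batch(samples: np.ndarray, spec: StatisticSpec) -> np.ndarray:
    """Evaluate h on a (k, n, n) stack of networks at once; returns (k, q).

    Identical to mapping :func:`compute_statistics` over the stack, but using
    batched matrix products — the fast path for simulation output.
    """
    S = np.asarray(samples, dtype=float)
    if S.ndim != 3:
        raise ValueError("samples must be a (k, n, n) stack")
    k = S.shape[0]
    out = np.empty((k, len(spec)))
    SS = None
    for idx, name in enumerate(spec.names):
        if name == "edge_sum":
            val = S.sum(axis=(1, 2))
        elif name == "reciprocity":
            val = np.einsum("kij,kji->k", S, S) / 2.0
        elif name == "transitive_triads":
            if SS is None:
                SS = S @ S
            val = (SS * S).sum(axis=(1, 2))
        elif name == "cyclic_triads":
            if SS is None:
                SS = S @ S
            val = np.einsum("kij,kji->k", SS, S) / 3.0
        elif name == "in_two_stars":
            col = S.sum(axis=1)
            val = ((col**2 - (S**2).sum(axis=1)) / 2.0).sum(axis=1)
        elif name == "out_two_stars":
            row = S.sum(axis=2)
            val = ((row**2 - (S**2).sum(axis=2)) / 2.0).sum(axis=1)
        else:  # pragma: no cover
            raise ValueError(f"unknown statistic {name!r}")
        out[:, idx] = val / spec.scaling[idx]
    return out


def edge_delta(x, spec: StatisticSpec, i: int, j: int) -> np.ndarray:
    """Per-edge linear coefficients: h(x_ij = 1) - h(x_ij = 0), closed form.

    By multilinearity theta'h(x) = a * x_ij + const with
    a = theta' edge_delta(x, spec, i, j); this feeds the Gibbs conditional.
    """
    if i == j:
        raise ValueError("self-loops are undefined (i must differ from j)")
    X = _stat_matrix(x)
    n = X.shape[0]
    mask = np.ones(n, dtype=bool)
    mask[[i, j]] = False
    out = np.empty(len(spec))
    for idx, name in enumerate(spec.names):
        if name == "edge_sum":
            val = 1.0
        elif name == "reciprocity":
            val = X[j, i]
        elif name == "transitive_triads":
            # x_ij closes i->j->c, appears in paths i->c->j and c->i,c->j
            xc_i, xc_j = X[mask, i], X[mask, j]
            xi_c, xj_c = X[i, mask], X[j, mask]
            val = (xi_c * xj_c + xi_c * xc_j + xc_i * xc_j).sum()
        elif name == "cyclic_triads":
            val = (X[j, mask] * X[mask, i].T).sum()
        elif name == "in_two_stars":
            val = X[mask, j].sum()
        elif name == "out_two_stars":
            val = X[i, mask].sum()
        else:  # pragma: no cover
            raise ValueError(f"unknown statistic {name!r}")
        out[idx] = val / spec.scaling[idx]
    return out


def delta_matrix(x, spec: StatisticSpec, pairs: np.ndarray) -> np.ndarray:
    """Stack edge_delta over an (m, 2) pair enumeration into an (m, q) array."""
    return np.array([edge_delta(x, spec, int(i), int(j)) for i, j in pairs])
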