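"""Network containers for valued-edge graph models.

Two containers are used throughout the package:

* :class:`ValuedNetwork` — the observed network ``Y`` whose edges take
  continuous values on an arbitrary support (all reals, an interval, ...).
* :class:`RestrictedNetwork` — the latent network ``X`` whose off-diagonal
  entries lie strictly inside the unit interval.  The exponential-family
  dependence structure is placed on ``X``; the observed network is an
  edgewise monotone transformation of it.

Self-loops are undefined: the diagonal is zeroed on construction and ignored
by every computation.  Edge enumeration everywhere in the package is
row-major over ordered pairs ``(i, j)``, ``i != j`` (directed) or over the
upper triangle ``i < j`` (undirected), with 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Off-diagonal values of a RestrictedNetwork are clamped into
#: [CLAMP_EPS, 1 - CLAMP_EPS]; CDF transforms can hit machine 0/1.
CLAMP_EPS = 1e-10


def edge_pairs(n: int, directed: bool = True) -> np.ndarray:
    """Return the fixed edge enumeration as an ``(m, 2)`` index array.

    Row-major over ordered pairs (i, j), i != j for directed networks;
    upper-triangle pairs i < j otherwise.
    """
    if directed:
        i, j = np.where(~np.eye(n, dtype=bool))
    else:
        i, j = np.triu_indices(n, k=1)
    return np.column_stack([i, j])


def n_edges(n: int, directed: bool = True) -> int:
    """Number of edge variables m: n(n-1) directed, n(n-1)/2 undirected."""
    return n * (n - 1) if directed else n * (n - 1) // 2


def _validate_square(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got shape {values.shape}")
    if values.shape[0] < 2:
        raise ValueError("network needs at least 2 vertices")
    off = ~np.eye(values.shape[0], dtype=bool)
    if not np.all(np.isfinite(values[off])):
        raise ValueError("non-finite off-diagonal entry in adjacency matrix")
    return values


@dataclass
class ValuedNetwork:
    """An observed network with continuous edge values.

    Parameters
    ----------
    values : (n, n) array
        Adjacency matrix; the diagonal is ignored (zeroed).
    directed : bool
        If False, ``values`` must be symmetric within tolerance and only the
        upper triangle is used.
    vertex_labels : sequence of str, optional
        External identifiers for the vertices.
    """

    values: np.ndarray
    directed: bool = True
    vertex_labels: list[str] | None = None

    def __post_init__(self) -> None:
        values = _validate_square(self.values)
        if not self.directed:
            off = ~np.eye(values.shape[0], dtype=bool)
            if not np.allclose(values[off], values.T[off], atol=1e-8):
                raise ValueError("asymmetric adjacency matrix declared undirected")
        values = values.copy()
        np.fill_diagonal(values, 0.0)
        self.values = values
        if self.vertex_labels is not None:
            self.vertex_labels = [str(v) for v in self.vertex_labels]
            if len(self.vertex_labels) != values.shape[0]:
                raise ValueError("vertex_labels length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return n_edges(self.n, self.directed)

    def edge_values(self) -> np.ndarray:
        """Edge values as a length-m vector in enumeration order."""
        pairs = edge_pairs(self.n, self.directed)
        return self.values[pairs[:, 0], pairs[:, 1]]


@dataclass
class RestrictedNetwork:
    """A network with off-diagonal entries strictly inside (0, 1).

    Values are clamped into ``[CLAMP_EPS, 1 - CLAMP_EPS]`` on construction so
    that marginal CDF transforms that hit machine 0 or 1 remain usable.
    """

    values: np.ndarray
    directed: bool = True
    vertex_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        values = _validate_square(self.values).copy()
        off = ~np.eye(values.shape[0], dtype=bool)
        if np.any(values[off] < 0.0) or np.any(values[off] > 1.0):
            raise ValueError("restricted network entries must lie in [0, 1]")
        values[off] = np.clip(values[off], CLAMP_EPS, 1.0 - CLAMP_EPS)
        np.fill_diagonal(values, 0.0)
        if not self.directed:
            if not np.allclose(values, values.T, atol=1e-8):
                raise ValueError("asymmetric adjacency matrix declared undirected")
        self.values = values

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return n_edges(self.n, self.directed)

    def edge_values(self) -> np.ndarray:
        pairs = edge_pairs(self.n, self.directed)
        return self.values[pairs[:, 0], pairs[:, 1]]


def validate_network(
    values: np.ndarray,
    directed: bool = True,
    vertex_labels: list[str] | None = None,
) -> ValuedNetwork:
    """Validate a raw matrix and wrap it as a :class:`ValuedNetwork`."""
    return ValuedNetwork(values=values, directed=directed, vertex_labels=vertex_labels)


def from_edge_vector(
    edges: np.ndarray, n: int, directed: bool = True
) -> np.ndarray:
    """Scatter a length-m edge vector back into an (n, n) matrix."""
    edges = np.asarray(edges, dtype=float)
    m = n_edges(n, directed)
    if edges.shape != (m,):
        raise ValueError(f"expected {m} edge values, got {edges.shape}")
    out = np.zeros((n, n))
    pairs = edge_pairs(n, directed)
    out[pairs[:, 0], pairs[:, 1]] = edges
    if not directed:
        out[pairs[:, 1], pairs[:, 0]] = edges
    return out
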