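"""Global topology metrics for weighted undirected brain networks.

All metrics operate on max-normalized weights (w / max(w)), which makes
them invariant to the overall weight scale.  Shortest-path distances use
edge length 1/w_hat, the standard mapping that makes strong connections
short.  Conventions for sparse/disconnected graphs:

* clustering coefficient Cp — geometric-mean (Onnela) triangle formula per
  node, averaged over all nodes; degree-<2 nodes contribute 0;
* characteristic path length Lp — mean finite distance over ordered pairs
  within the largest connected component;
* global efficiency Eg — mean of 1/d over all ordered pairs with
  1/inf = 0 for disconnected pairs;
* local efficiency Eloc — mean over nodes of the global efficiency of the
  neighbour-induced subgraph (re-normalized within each subgraph);
  nodes with fewer than 2 neighbours contribute 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "WeightedGraph",
    "GlobalMetrics",
    "BasicProperties",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "global_metrics",
    "basic_properties",
]


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected graph as a symmetric non-negative weight matrix, zero diagonal."""

    weights: np.ndarray
    labels: tuple[str, ...] | None = None
    modality: str = "generic"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-loops are not allowed")
        w = (w + w.T) / 2.0  # enforce exact symmetry
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)
        if self.labels is not None and len(self.labels) != w.shape[0]:
            raise ValueError("label count must match node count")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int((self.weights > 0).sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=0)

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(u, v, w) arrays over unique edges, u < v."""
        iu, iv = np.nonzero(np.triu(self.weights, k=1))
        return iu, iv, self.weights[iu, iv]


@dataclass(frozen=True)
class GlobalMetrics:
    cp: float
    lp: float
    eg: float
    eloc: float

    def as_dict(self) -> dict[str, float]:
        return {"cp": self.cp, "lp": self.lp, "eg": self.eg, "eloc": self.eloc}


@dataclass(frozen=True)
class BasicProperties:
    density: float
    strength: float
    largest_component: int

    def as_dict(self) -> dict[str, float]:
        return {
            "density": self.density,
            "strength": self.strength,
            "largest_component": float(self.largest_component),
        }


def _normalize(w: np.ndarray) -> np.ndarray:
    mx = w.max()
    return w / mx if mx > 0 else w


def _distance_matrix(w_hat: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/w_hat."""
    with np.errstate(divide="ignore"):
        lengths = np.where(w_hat > 0, 1.0 / np.where(w_hat > 0, w_hat, 1.0), 0.0)
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def clustering_coefficient(g: WeightedGraph) -> tuple[np.ndarray, float]:
    """Per-node Onnela clustering and its unweighted mean over all nodes.

    C_i = [1/(k_i (k_i - 1))] * sum_{j,h} (w_hat_ij w_hat_ih w_hat_jh)^(1/3).
    """
    if g.n_edges == 0:
        warnings.warn("clustering of an empty graph is 0", stacklevel=2)
        return np.zeros(g.n_nodes), 0.0
    w = _normalize(g.weights)
    k = g.degrees.astype(float)
    cbrt = np.cbrt(w)
    triangles = np.einsum("ij,jh,hi->i", cbrt, cbrt, cbrt)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(k >= 2, triangles / (k * (k - 1)), 0.0)
    return c, float(c.mean())


def characteristic_path_length(g: WeightedGraph) -> float:
    """Mean shortest-path distance over ordered pairs in the largest component."""
    if g.n_nodes == 0:
        raise ValueError("empty graph has no path length")
    n_comp, comp = connected_components(
        csr_matrix(g.weights > 0), directed=False
    )
    sizes = np.bincount(comp, minlength=n_comp)
    big = int(np.argmax(sizes))
    members = np.flatnonzero(comp == big)
    if members.size < 2:
        raise ValueError(
            "characteristic path length requires a connected component with "
            ">= 2 nodes"
        )
    d = _distance_matrix(_normalize(g.weights))[np.ix_(members, members)]
    off = ~np.eye(members.size, dtype=bool)
    return float(d[off].mean())


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d), 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def global_efficiency(g: WeightedGraph) -> float:
    """Mean inverse shortest-path distance (disconnected pairs contribute 0)."""
    if g.n_nodes < 2:
        return 0.0
    return _efficiency_from_distances(_distance_matrix(_normalize(g.weights)))


def local_efficiency(g: WeightedGraph) -> float:
    """Mean over nodes of the neighbour-subgraph global efficiency."""
    w = g.weights
    total = 0.0
    for i in range(g.n_nodes):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        total += _efficiency_from_distances(_distance_matrix(_normalize(sub)))
    return total / g.n_nodes if g.n_nodes else 0.0


def global_metrics(g: WeightedGraph) -> GlobalMetrics:
    """Cp, Lp, Eg, Eloc in one pass (shared distance matrix for Lp/Eg)."""
    _, cp = clustering_coefficient(g)
    d = _distance_matrix(_normalize(g.weights))
    n_comp, comp = connected_components(csr_matrix(g.weights > 0), directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    members = np.flatnonzero(comp == int(np.argmax(sizes)))
    if members.size < 2:
        raise ValueError("graph has no connected component with >= 2 nodes")
    sub = d[np.ix_(members, members)]
    lp = float(sub[~np.eye(members.size, dtype=bool)].mean())
    eg = _efficiency_from_distances(d)
    eloc = local_efficiency(g)
    return GlobalMetrics(cp=cp, lp=lp, eg=eg, eloc=eloc)


def basic_properties(g: WeightedGraph) -> BasicProperties:
    """Density, mean nodal strength (raw weights), largest-component size."""
    n = g.n_nodes
    density = 2.0 * g.n_edges / (n * (n - 1)) if n > 1 else 0.0
    strength = float(g.weights.sum(axis=0).mean()) if n else 0.0
    if n == 0:
        return BasicProperties(0.0, 0.0, 0)
    _, comp = connected_components(csr_matrix(g.weights > 0), directed=False)
    largest = int(np.bincount(comp).max())
    return BasicProperties(density, strength, largest)
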