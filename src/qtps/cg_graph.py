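"""Coarse-grained graph representation of Langevin dynamics on an intrinsic manifold.

A sparse set of configurations :math:`Q_i` sampled on the low-dimensional
manifold where the equilibrium density concentrates is turned into an
undirected graph: each configuration is a node (implicitly, the centre of its
cell), and edges connect configurations that are structurally close.  The
discretised overdamped-Langevin propagator assigns every directed step
``i -> j`` a weight

.. math::

    w_{ij} = \\frac{1}{2 m D_{cg}}
             \\left( \\frac{m\\,|Q_i - Q_j|^2}{2\\,\\Delta t}
                     + V_{cg}(Q_i)\\,\\Delta t \\right),

with :math:`D_{cg} = \\sigma^2 / (2\\Delta t)` the coarse-grained diffusion
coefficient, :math:`\\sigma` the spatial resolution (mean distance between
neighbouring configurations) and :math:`V_{cg}` the effective potential of the
coarse-grained theory.  The effective action of a coarse-grained path
``I = (i_1, ..., i_N)`` is the sum of its step weights,
:math:`S(I) = \\sum_k w_{i_k i_{k+1}}`, and path probabilities are
:math:`P(I) \\propto e^{-S(I)}`.

Because the undirected encoding downstream carries a single coefficient per
edge, both directed weights are stored and the symmetrised weight
``w_sym = (w_ij + w_ji) / 2`` is used wherever one number per edge is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Configuration",
    "CGParams",
    "Edge",
    "ManifoldGraph",
    "CGPath",
    "estimate_sigma",
    "build_adjacency",
    "estimate_cg_potential",
    "edge_weight",
    "path_action",
    "build_graph",
]


@dataclass(frozen=True)
class Configuration:
    """A sampled configuration on the intrinsic manifold.

    Parameters
    ----------
    id
        Integer node label.
    coords
        Flattened coordinate vector (arbitrary, consistent length).
    count
        Number of raw samples assigned to this configuration's cell; feeds the
        effective-potential estimate.
    """

    id: int
    coords: np.ndarray
    count: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 1:
            c = c.ravel()
        if not np.all(np.isfinite(c)):
            raise ValueError(f"configuration {self.id}: non-finite coordinates")
        if self.count < 0:
            raise ValueError(f"configuration {self.id}: negative count")
        object.__setattr__(self, "coords", c)


@dataclass(frozen=True)
class CGParams:
    """Parameters of the coarse-grained Langevin theory (reduced units).

    ``D_cg`` is derived, never free: ``D_cg = sigma**2 / (2 * dt)`` by
    construction.
    """

    mass: float = 1.0
    dt: float = 1.0
    sigma: float = 1.0
    kBT: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mass", "dt", "sigma", "kBT"):
            if not getattr(self, name) > 0:
                raise ValueError(f"CGParams.{name} must be positive")

    @property
    def D_cg(self) -> float:
        return self.sigma**2 / (2.0 * self.dt)


@dataclass(frozen=True)
class Edge:
    """Undirected graph edge with both directed weights and their mean."""

    i: int
    j: int
    dist2: float
    w_ij: float  # weight of the directed step i -> j
    w_ji: float
    w_sym: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-edges are not allowed")


@dataclass
class ManifoldGraph:
    """Nodes ``(Configuration, V_cg)`` plus weighted undirected edges."""

    configurations: list[Configuration]
    V_cg: np.ndarray
    edges: list[Edge]
    params: CGParams

    _adj: dict[int, dict[int, Edge]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.V_cg = np.asarray(self.V_cg, dtype=float)
        if len(self.V_cg) != len(self.configurations):
            raise ValueError("V_cg length must match node count")
        self._by_id = {c.id: k for k, c in enumerate(self.configurations)}
        if len(self._by_id) != len(self.configurations):
            raise ValueError("duplicate node ids")
        self._adj = {c.id: {} for c in self.configurations}
        for e in self.edges:
            if e.i not in self._by_id or e.j not in self._by_id:
                raise ValueError(f"edge ({e.i},{e.j}) references unknown node")
            self._adj[e.i][e.j] = e
            self._adj[e.j][e.i] = e

    @property
    def nu(self) -> int:
        """Number of nodes."""
        return len(self.configurations)

    @property
    def node_ids(self) -> list[int]:
        return [c.id for c in self.configurations]

    def index(self, node_id: int) -> int:
        return self._by_id[node_id]

    def configuration(self, node_id: int) -> Configuration:
        return self.configurations[self._by_id[node_id]]

    def potential(self, node_id: int) -> float:
        return float(self.V_cg[self._by_id[node_id]])

    def neighbors(self, node_id: int) -> list[int]:
        return sorted(self._adj[node_id])

    def edge(self, i: int, j: int) -> Edge:
        try:
            return self._adj[i][j]
        except KeyError:
            raise KeyError(f"no edge between {i} and {j}") from None

    def has_edge(self, i: int, j: int) -> bool:
        return j in self._adj.get(i, ())

    def edge_keys(self) -> list[tuple[int, int]]:
        """Canonical (sorted-pair) edge keys, sorted; fixes variable order."""
        return sorted((min(e.i, e.j), max(e.i, e.j)) for e in self.edges)

    def total_symmetric_weight(self) -> float:
        return float(sum(e.w_sym for e in self.edges))

    def connected_components(self) -> list[set[int]]:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from((e.i, e.j) for e in self.edges)
        return [set(c) for c in nx.connected_components(g)]

    def same_component(self, s: int, t: int) -> bool:
        for comp in self.connected_components():
            if s in comp:
                return t in comp
        return False


@dataclass(frozen=True)
class CGPath:
    """An ordered node sequence with its effective action."""

    nodes: tuple[int, ...]
    action: float

    def __len__(self) -> int:
        return len(self.nodes)


def estimate_sigma(
    configs: list[Configuration], adjacency: list[tuple[int, int]]
) -> float:
    """Mean Euclidean distance between adjacent configurations.

    This is the spatial resolution sigma of the coarse-grained theory.  With
    flattened all-atom coordinates and no superposition it equals
    ``delta_RMSD * sqrt(N_atoms)``.
    """
    if not adjacency:
        raise ValueError("no edges: cannot estimate resolution")
    by_id = {c.id: c for c in configs}
    dists = [
        float(np.linalg.norm(by_id[i].coords - by_id[j].coords))
        for i, j in adjacency
    ]
    sigma = float(np.mean(dists))
    if sigma <= 0.0:
        raise ValueError("degenerate resolution: adjacent configurations coincide")
    return sigma


def build_adjacency(
    configs: list[Configuration], k: int = 6, d_max: float = math.inf
) -> list[tuple[int, int]]:
    """Mutual k-nearest-neighbour adjacency with a distance cutoff.

    Edges join pairs that are within each other's ``k`` nearest neighbours and
    closer than ``d_max``.  Returned as sorted canonical pairs of node ids.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not d_max > 0:
        raise ValueError("d_max must be positive")
    if len(configs) < 2:
        return []
    ids = [c.id for c in configs]
    X = np.vstack([c.coords for c in configs])
    tree = cKDTree(X)
    kq = min(k + 1, len(configs))  # +1: the query point itself
    dist, idx = tree.query(X, k=kq)
    neigh: list[set[int]] = []
    for a in range(len(configs)):
        s = {int(b) for d, b in zip(dist[a], idx[a]) if b != a and d <= d_max}
        neigh.append(s)
    edges = set()
    for a in range(len(configs)):
        for b in neigh[a]:
            if a in neigh[b]:
                u, v = sorted((ids[a], ids[b]))
                edges.add((u, v))
    return sorted(edges)


def estimate_cg_potential(
    configs: list[Configuration], kBT: float = 1.0
) -> np.ndarray:
    """Effective potential from local sample counts.

    ``V_cg(Q_i) = -kBT * ln(n_i / sum(n))``, shifted so the minimum over nodes
    is zero; the shift keeps the downstream edge weights non-negative.  If any
    count is zero, add-one smoothing is applied to every node.
    """
    counts = np.array([c.count for c in configs], dtype=float)
    if counts.sum() <= 0:
        raise ValueError("all counts are zero: cannot estimate potential")
    if np.any(counts == 0):
        counts = counts + 1.0
    v = -kBT * np.log(counts / counts.sum())
    return v - v.min()


def edge_weight(
    Q_i: np.ndarray, Q_j: np.ndarray, Vcg_i: float, params: CGParams
) -> float:
    """Directed step weight of the coarse-grained propagator.

    ``w_ij = (m |Q_i-Q_j|^2 / (2 dt) + V_cg(Q_i) dt) / (2 m D_cg)``.  The
    kinetic term reduces to ``|Q_i-Q_j|^2 / (2 sigma^2)``.
    """
    d2 = float(np.sum((np.asarray(Q_i, float) - np.asarray(Q_j, float)) ** 2))
    m, dt = params.mass, params.dt
    return (m * d2 / (2.0 * dt) + Vcg_i * dt) / (2.0 * m * params.D_cg)


def path_action(graph: ManifoldGraph, nodes: "list[int] | tuple[int, ...]") -> float:
    """Effective action of a simple path: sum of symmetrised step weights."""
    nodes = tuple(int(n) for n in nodes)
    if len(set(nodes)) != len(nodes):
        raise ValueError("path revisits a node (not simple)")
    s = 0.0
    for a, b in zip(nodes, nodes[1:]):
        if not graph.has_edge(a, b):
            raise ValueError(f"broken path: nodes {a} and {b} are not adjacent")
        s += graph.edge(a, b).w_sym
    return s


def build_graph(
    configs: list[Configuration],
    params: CGParams | None = None,
    *,
    adjacency: list[tuple[int, int]] | None = None,
    k: int = 6,
    d_max_sigmas: float = 3.0,
    kBT: float = 1.0,
    mass: float = 1.0,
    dt: float | None = 1.0,
    sigma: float | None = None,
) -> ManifoldGraph:
    """Assemble a :class:`ManifoldGraph` from configurations.

    The adjacency defaults to mutual k-NN; the distance cutoff is
    ``d_max_sigmas`` times a first-pass sigma estimate.  ``sigma`` (and hence
    ``D_cg``) defaults to the mean adjacent-pair distance; pass ``params`` or
    ``sigma`` to override.  ``dt=None`` selects the diffusive time step
    ``sigma**2 / (2 kBT)`` — the mean time an overdamped walker with
    diffusion coefficient ``D = kBT`` (mobility 1) takes to cross one
    resolution cell, which makes ``D_cg`` equal ``D`` and keeps the edge
    weights order one.
    """
    if adjacency is None:
        adjacency = build_adjacency(configs, k=k)
        if adjacency:
            sig0 = estimate_sigma(configs, adjacency)
            adjacency = build_adjacency(configs, k=k, d_max=d_max_sigmas * sig0)
    if not adjacency:
        raise ValueError("no edges in adjacency")
    if params is None:
        sig = sigma if sigma is not None else estimate_sigma(configs, adjacency)
        if dt is None:
            dt = sig**2 / (2.0 * kBT)
        params = CGParams(mass=mass, dt=dt, sigma=sig, kBT=kBT)
    V = estimate_cg_potential(configs, kBT=params.kBT)
    by_id = {c.id: k_ for k_, c in enumerate(configs)}
    edges = []
    for i, j in adjacency:
        ci, cj = configs[by_id[i]], configs[by_id[j]]
        d2 = float(np.sum((ci.coords - cj.coords) ** 2))
        wij = edge_weight(ci.coords, cj.coords, float(V[by_id[i]]), params)
        wji = edge_weight(cj.coords, ci.coords, float(V[by_id[j]]), params)
        edges.append(
            Edge(i=i, j=j, dist2=d2, w_ij=wij, w_ji=wji, w_sym=0.5 * (wij + wji))
        )
    return ManifoldGraph(configurations=list(configs), V_cg=V, edges=edges, params=params)
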