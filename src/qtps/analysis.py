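"""Post-processing of transition path ensembles.

Covers the most probable path (least action, found with Dijkstra's algorithm
on the symmetrised weights), the node transition-path density (how often
sampled paths pass each configuration, i.e. its statistical weight in the
transition path ensemble), a path autocorrelation function G(N) over chain
lag N, and an exhaustive small-graph path distribution used as the analytic
reference ``P(I) = e^{-S(I)} / Z``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .cg_graph import CGPath, ManifoldGraph, path_action

__all__ = [
    "PathEnsemble",
    "AutocorrStat",
    "dijkstra_path",
    "node_visit_density",
    "autocorrelation",
    "exact_path_distribution",
    "enumerate_simple_paths",
]


@dataclass
class PathEnsemble:
    """Chain-ordered list of sampled paths sharing endpoints on one graph."""

    paths: list[CGPath]
    graph: ManifoldGraph

    def __post_init__(self) -> None:
        if self.paths:
            s, t = self.paths[0].nodes[0], self.paths[0].nodes[-1]
            for p in self.paths:
                if p.nodes[0] != s or p.nodes[-1] != t:
                    raise ValueError("ensemble paths must share start and end nodes")

    def __len__(self) -> int:
        return len(self.paths)


@dataclass
class AutocorrStat:
    """G per lag and its normalised form G(N)/G(0)."""

    G: np.ndarray
    normalized: np.ndarray | None  # None when G(0) == 0 (all paths identical)


def dijkstra_path(graph: ManifoldGraph, s: int, t: int) -> CGPath:
    """Least-action (most probable) s->t path on symmetrised weights.

    Ties are broken deterministically toward the lexicographically smallest
    node sequence.
    """
    if s not in graph.node_ids or t not in graph.node_ids:
        raise ValueError("endpoint not in graph")
    # heap entries: (distance, node sequence); the sequence doubles as the
    # lexicographic tie-break, so equal-length frontiers pop deterministically
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    heap: list[tuple[float, tuple[int, ...]]] = [(0.0, (s,))]
    while heap:
        d, seq = heapq.heappop(heap)
        node = seq[-1]
        if node in best and (d, seq) >= best[node]:
            continue
        best[node] = (d, seq)
        if node == t:
            continue
        for nb in graph.neighbors(node):
            if nb in seq:
                continue
            nd = d + graph.edge(node, nb).w_sym
            if nb not in best or (nd, seq + (nb,)) < best[nb]:
                heapq.heappush(heap, (nd, seq + (nb,)))
    if t not in best:
        raise ValueError(f"nodes {s} and {t} are not connected")
    d, seq = best[t]
    return CGPath(nodes=seq, action=path_action(graph, seq))


def node_visit_density(ensemble: PathEnsemble) -> dict[int, float]:
    """Fraction of ensemble paths visiting each node (endpoints at exactly 1)."""
    if not ensemble.paths:
        raise ValueError("empty ensemble")
    counts = {i: 0 for i in ensemble.graph.node_ids}
    for p in ensemble.paths:
        for n in p.nodes:
            counts[n] += 1
    L = len(ensemble.paths)
    return {i: c / L for i, c in counts.items()}


def _indicator_matrix(ensemble: PathEnsemble) -> np.ndarray:
    ids = sorted(ensemble.graph.node_ids)
    pos = {n: k for k, n in enumerate(ids)}
    X = np.zeros((len(ensemble.paths), len(ids)))
    for r, p in enumerate(ensemble.paths):
        for n in p.nodes:
            X[r, pos[n]] = 1.0
    return X


def autocorrelation(ensemble: PathEnsemble, max_lag: int) -> AutocorrStat:
    """Path autocorrelation over chain lag.

    Each path is represented by its node-indicator vector ``x_n``; with the
    ensemble mean ``xbar``,
    ``G(N) = (1/(L-N)) * sum_n (x_n - xbar).(x_{n+N} - xbar)``.
    Near-zero ``G(N)/G(0)`` for N >= 1 is the signature of one-shot
    decorrelated proposals.
    """
    L = len(ensemble.paths)
    if L <= max_lag + 1:
        raise ValueError("ensemble too short for requested max_lag")
    X = _indicator_matrix(ensemble)
    Xc = X - X.mean(axis=0)
    G = np.empty(max_lag + 1)
    for N in range(max_lag + 1):
        G[N] = np.sum(Xc[: L - N] * Xc[N:]) / (L - N)
    normalized = G / G[0] if G[0] > 0 else None
    return AutocorrStat(G=G, normalized=normalized)


def enumerate_simple_paths(
    graph: ManifoldGraph, s: int, t: int, max_paths: int = 100_000
) -> list[CGPath]:
    """All simple s->t paths (explosion-guarded), sorted by node sequence."""
    g = nx.Graph()
    g.add_nodes_from(graph.node_ids)
    g.add_edges_from((e.i, e.j) for e in graph.edges)
    out = []
    for nodes in nx.all_simple_paths(g, s, t):
        out.append(CGPath(nodes=tuple(nodes), action=path_action(graph, nodes)))
        if len(out) > max_paths:
            raise ValueError(f"more than {max_paths} simple paths; refusing to enumerate")
    return sorted(out, key=lambda p: p.nodes)


def exact_path_distribution(
    graph: ManifoldGraph, s: int, t: int, max_nodes: int = 12, max_paths: int = 100_000
) -> list[tuple[CGPath, float]]:
    """Exhaustive path ensemble with Boltzmann-like probabilities e^{-S}/Z."""
    if graph.nu > max_nodes:
        raise ValueError(f"graph too large ({graph.nu} > {max_nodes} nodes) for enumeration")
    paths = enumerate_simple_paths(graph, s, t, max_paths=max_paths)
    if not paths:
        raise ValueError(f"no simple paths between {s} and {t}")
    actions = np.array([p.action for p in paths])
    w = np.exp(-(actions - actions.min()))  # shift for numerical safety
    w /= w.sum()
    return [(p, float(pr)) for p, pr in zip(paths, w)]
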