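"""QUBO / Ising encoding of start-to-end path sampling on a weighted graph.

Two families of binary variables describe a candidate path: one bit per node
(``Gamma1[i] = 1`` iff node ``i`` is visited) and one bit per undirected graph
edge (``Gamma2[ij] = 1`` iff the step between ``i`` and ``j`` is taken, in
either direction).  The classical Hamiltonian

.. math::  H = \\alpha H_C + H_T

combines a positive constraint part ``H_C = H_s + H_t + H_r`` — anchoring the
path at the start node ``s`` and end node ``t`` and enforcing flux
conservation at every other node — with the target function
``H_T = sum_ij w_ij Gamma2[ij]`` whose value on any valid path equals the path
action ``S(I)``.  The penalty strength ``alpha`` defaults to the sum of all
(symmetrised) edge weights, large enough to push topology-violating
configurations out of the low-energy sector while wasting as little energy
resolution as possible.

As printed, the anchor terms evaluate to ``-1`` each on a valid path, so the
raw constraint minimum is ``-2``; a constant offset of ``+2`` is folded into
the constraint model so that its minimum is exactly zero, attained exactly on
s--t flux-conserving edge subgraphs (an s--t path possibly accompanied by
disjoint cycles).  Disjoint cycles ("subtours") cost zero constraint energy
but positive target energy, so they never occur in the ground state; excited
samples containing them are rejected by :func:`decode`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .cg_graph import CGPath, ManifoldGraph, path_action

__all__ = [
    "PathProblem",
    "BinaryConfiguration",
    "QuadraticModel",
    "IsingModel",
    "Invalid",
    "build_constraint",
    "build_target",
    "assemble",
    "to_ising",
    "encode_path",
    "decode",
]

# variable labels: ("n", node_id) for node bits, ("e", (i, j)) i<j for edge bits
Var = tuple


def node_var(i: int) -> Var:
    return ("n", int(i))


def edge_var(i: int, j: int) -> Var:
    a, b = sorted((int(i), int(j)))
    return ("e", (a, b))


@dataclass(frozen=True)
class PathProblem:
    """A start-to-end path-sampling problem on a manifold graph."""

    graph: ManifoldGraph
    s: int
    t: int
    alpha: float | None = None  # None -> default heuristic sum(w_sym)

    def __post_init__(self) -> None:
        g = self.graph
        if self.s == self.t:
            raise ValueError("start and end nodes must differ")
        for n in (self.s, self.t):
            if n not in g.node_ids:
                raise ValueError(f"node {n} not in graph")
        if not g.same_component(self.s, self.t):
            raise ValueError(
                f"start {self.s} and end {self.t} lie in different connected components"
            )
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError("alpha must be positive")

    @property
    def alpha_value(self) -> float:
        if self.alpha is not None:
            return float(self.alpha)
        return self.graph.total_symmetric_weight()

    def variables(self) -> list[Var]:
        """Canonical variable order: node bits by id, then edge bits by pair."""
        g = self.graph
        return [node_var(i) for i in sorted(g.node_ids)] + [
            edge_var(i, j) for i, j in g.edge_keys()
        ]

    @property
    def n_qubits(self) -> int:
        """Qubit count of the encoding: number of nodes plus edges."""
        return self.graph.nu + len(self.graph.edges)


@dataclass
class BinaryConfiguration:
    """One annealer state: a bit per node and a bit per graph edge."""

    gamma1: dict[int, int]
    gamma2: dict[tuple[int, int], int]

    def __post_init__(self) -> None:
        for d in (self.gamma1, self.gamma2):
            for k, v in d.items():
                if v not in (0, 1):
                    raise ValueError(f"bit {k} is {v}, not 0/1")

    def value(self, var: Var) -> int:
        kind, key = var
        return self.gamma1[key] if kind == "n" else self.gamma2[key]

    def as_vector(self, variables: list[Var]) -> np.ndarray:
        return np.array([self.value(v) for v in variables], dtype=np.int8)

    @classmethod
    def from_vector(cls, variables: list[Var], x: np.ndarray) -> "BinaryConfiguration":
        g1, g2 = {}, {}
        for var, b in zip(variables, x):
            kind, key = var
            (g1 if kind == "n" else g2)[key] = int(b)
        return cls(gamma1=g1, gamma2=g2)


@dataclass
class QuadraticModel:
    """A quadratic binary model ``E(x) = offset + l.x + sum q_uv x_u x_v``."""

    variables: list[Var]
    linear: dict[Var, float] = field(default_factory=dict)
    quadratic: dict[tuple[Var, Var], float] = field(default_factory=dict)
    offset: float = 0.0

    def __post_init__(self) -> None:
        self._index = {v: k for k, v in enumerate(self.variables)}
        if len(self._index) != len(self.variables):
            raise ValueError("duplicate variable labels")

    def _canon(self, u: Var, v: Var) -> tuple[Var, Var]:
        iu, iv = self._index[u], self._index[v]
        if iu == iv:
            raise ValueError("quadratic term on a single variable")
        return (u, v) if iu < iv else (v, u)

    def add_linear(self, v: Var, coeff: float) -> None:
        self.linear[v] = self.linear.get(v, 0.0) + coeff

    def add_quadratic(self, u: Var, v: Var, coeff: float) -> None:
        key = self._canon(u, v)
        self.quadratic[key] = self.quadratic.get(key, 0.0) + coeff

    def add_squared_linear(self, terms: list[tuple[Var, float]], const: float = 0.0) -> None:
        """Add ``(const + sum a_v x_v)**2``, using ``x**2 = x`` for bits."""
        self.offset += const * const
        for v, a in terms:
            self.add_linear(v, a * a + 2.0 * const * a)
        for (u, a), (v, b) in itertools.combinations(terms, 2):
            self.add_quadratic(u, v, 2.0 * a * b)

    def energy(self, conf: "BinaryConfiguration | np.ndarray") -> float:
        x = conf.as_vector(self.variables) if isinstance(conf, BinaryConfiguration) else np.asarray(conf)
        e = self.offset
        for v, a in self.linear.items():
            e += a * x[self._index[v]]
        for (u, v), q in self.quadratic.items():
            e += q * x[self._index[u]] * x[self._index[v]]
        return float(e)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Dense ``(h, Q, offset)`` with Q symmetric, zero diagonal.

        ``E = offset + h.x + x' Q x / 2`` restricted to binary x (each pair
        counted once in the model maps to ``Q[u,v] = Q[v,u] = q_uv``).
        """
        n = len(self.variables)
        h = np.zeros(n)
        Q = np.zeros((n, n))
        for v, a in self.linear.items():
            h[self._index[v]] += a
        for (u, v), q in self.quadratic.items():
            iu, iv = self._index[u], self._index[v]
            Q[iu, iv] += q
            Q[iv, iu] += q
        return h, Q, float(self.offset)

    def energies(self, X: np.ndarray) -> np.ndarray:
        """Vectorised energies for a (batch, n) 0/1 array."""
        h, Q, off = self.to_arrays()
        X = np.asarray(X, dtype=float)
        return off + X @ h + 0.5 * np.einsum("bi,ij,bj->b", X, Q, X)

    def scaled(self, factor: float) -> "QuadraticModel":
        return QuadraticModel(
            variables=list(self.variables),
            linear={v: factor * a for v, a in self.linear.items()},
            quadratic={k: factor * q for k, q in self.quadratic.items()},
            offset=factor * self.offset,
        )

    def __add__(self, other: "QuadraticModel") -> "QuadraticModel":
        if self.variables != other.variables:
            raise ValueError("models must share an identical variable order")
        out = QuadraticModel(variables=list(self.variables), offset=self.offset + other.offset)
        for src in (self, other):
            for v, a in src.linear.items():
                out.add_linear(v, a)
            for (u, v), q in src.quadratic.items():
                out.add_quadratic(u, v, q)
        return out


@dataclass
class IsingModel:
    """Spin model ``E(s) = offset + sum h_i s_i + sum J_uv s_u s_v``, s in {-1,+1}."""

    variables: list[Var]
    h: dict[Var, float]
    J: dict[tuple[Var, Var], float]
    offset: float

    def energy(self, spins: np.ndarray) -> float:
        idx = {v: k for k, v in enumerate(self.variables)}
        s = np.asarray(spins)
        e = self.offset
        for v, a in self.h.items():
            e += a * s[idx[v]]
        for (u, v), j in self.J.items():
            e += j * s[idx[u]] * s[idx[v]]
        return float(e)


def build_constraint(problem: PathProblem) -> QuadraticModel:
    """Path-topology constraint Hamiltonian, offset so its minimum is zero.

    ``H_s = -Gamma1[s] + (Gamma1[s] - sum_i Gamma2[si])**2`` (and likewise for
    ``t``) anchors the endpoints; ``H_r = sum_{j != s,t} (2 Gamma1[j] -
    sum_i Gamma2[ji])**2`` conserves flux elsewhere.  The constant ``+2``
    cancels the ``-2`` the anchor terms contribute on any valid path.
    """
    g = problem.graph
    m = QuadraticModel(variables=problem.variables())
    for j in sorted(g.node_ids):
        incident = [edge_var(j, nb) for nb in g.neighbors(j)]
        nv = node_var(j)
        if j in (problem.s, problem.t):
            # -(Gamma1)^2 = -Gamma1 for bits
            m.add_linear(nv, -1.0)
            m.add_squared_linear([(nv, 1.0)] + [(e, -1.0) for e in incident])
        else:
            m.add_squared_linear([(nv, 2.0)] + [(e, -1.0) for e in incident])
    m.offset += 2.0
    return m


def build_target(problem: PathProblem) -> QuadraticModel:
    """Target function: linear in edge bits with symmetrised weights."""
    m = QuadraticModel(variables=problem.variables())
    for e in problem.graph.edges:
        m.add_linear(edge_var(e.i, e.j), e.w_sym)
    return m


def assemble(problem: PathProblem) -> QuadraticModel:
    """``H = alpha * H_C + H_T`` with the default heuristic ``alpha = sum w``."""
    alpha = problem.alpha_value
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    return build_constraint(problem).scaled(alpha) + build_target(problem)


def to_ising(model: QuadraticModel) -> IsingModel:
    """Exact change of variables ``sigma = 2*Gamma - 1``."""
    h: dict[Var, float] = {v: 0.0 for v in model.variables}
    J: dict[tuple[Var, Var], float] = {}
    offset = model.offset
    for v, a in model.linear.items():
        # a*x = a*(s+1)/2
        h[v] += a / 2.0
        offset += a / 2.0
    for (u, v), q in model.quadratic.items():
        # q*x_u*x_v = q*(s_u+1)(s_v+1)/4
        J[(u, v)] = J.get((u, v), 0.0) + q / 4.0
        h[u] += q / 4.0
        h[v] += q / 4.0
        offset += q / 4.0
    h = {v: a for v, a in h.items() if a != 0.0}
    J = {k: j for k, j in J.items() if j != 0.0}
    return IsingModel(variables=list(model.variables), h=h, J=J, offset=offset)


def encode_path(problem: PathProblem, nodes: "list[int] | tuple[int, ...]") -> BinaryConfiguration:
    """Bits of a simple s->t path: visited nodes and traversed edges on."""
    nodes = tuple(int(n) for n in nodes)
    if len(nodes) < 2 or nodes[0] != problem.s or nodes[-1] != problem.t:
        raise ValueError("path must run from the start node to the end node")
    if len(set(nodes)) != len(nodes):
        raise ValueError("path is not simple")
    g = problem.graph
    g1 = {i: 0 for i in g.node_ids}
    g2 = {(min(e.i, e.j), max(e.i, e.j)): 0 for e in g.edges}
    for n in nodes:
        g1[n] = 1
    for a, b in zip(nodes, nodes[1:]):
        if not g.has_edge(a, b):
            raise ValueError(f"path step {a}->{b} is not a graph edge")
        g2[(min(a, b), max(a, b))] = 1
    return BinaryConfiguration(gamma1=g1, gamma2=g2)


@dataclass(frozen=True)
class Invalid:
    """Marker for a binary configuration that is not a simple s->t path."""

    reason: str  # broken_flux | subtour_present | node_edge_mismatch | not_simple

    def __bool__(self) -> bool:
        return False


def decode(problem: PathProblem, conf: BinaryConfiguration) -> "CGPath | Invalid":
    """Recover the simple s->t path a configuration encodes, if any.

    Valid iff the on-edges form exactly one simple s--t path, the node bits
    equal its vertex set, and nothing else is on.  Otherwise an
    :class:`Invalid` with one of four reasons is returned (never raised):
    ``node_edge_mismatch`` (node/edge bits disagree), ``broken_flux`` (edge
    degrees are not those of an s--t path), ``subtour_present`` (a correct
    path plus disjoint cycles), ``not_simple`` (defensive; repeated visits).
    """
    g = problem.graph
    on_edges = [pair for pair, b in conf.gamma2.items() if b]
    on_nodes = {i for i, b in conf.gamma1.items() if b}
    deg: dict[int, int] = {i: 0 for i in g.node_ids}
    for a, b in on_edges:
        deg[a] += 1
        deg[b] += 1
    touched = {i for i, d in deg.items() if d > 0}
    if touched != on_nodes:
        return Invalid("node_edge_mismatch")
    s, t = problem.s, problem.t
    if deg.get(s, 0) != 1 or deg.get(t, 0) != 1:
        return Invalid("broken_flux")
    if any(d != 2 for i, d in deg.items() if i in on_nodes and i not in (s, t)):
        return Invalid("broken_flux")
    # walk from s; degrees guarantee a unique continuation
    adj: dict[int, list[int]] = {}
    for a, b in on_edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    walk = [s]
    prev, cur = None, s
    seen = {s}
    while cur != t:
        nxt = [n for n in adj[cur] if n != prev]
        if not nxt:
            return Invalid("broken_flux")
        step = nxt[0]
        if step in seen:
            return Invalid("not_simple")
        walk.append(step)
        seen.add(step)
        prev, cur = cur, step
    if len(walk) - 1 < len(on_edges):
        return Invalid("subtour_present")
    return CGPath(nodes=tuple(walk), action=path_action(g, walk))
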