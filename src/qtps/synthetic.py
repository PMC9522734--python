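"""Synthetic inputs: a two-basin toy landscape and hand-coded fixture graphs.

The toy landscape is a symmetric 2-D double well,

.. math::  V(x, y) = h\\,(x^2 - 1)^2 + \\tfrac{\\omega}{2}\\,y^2,

with minima at (-1, 0) and (+1, 0) and a saddle of height ``h`` at the
origin — the analytically transparent stand-in for a molecular free-energy
surface with two metastable basins separated by a barrier.  Overdamped
Langevin (Euler--Maruyama) sampling of this landscape, binned onto a grid of
resolution comparable to the coarse-graining scale, produces the sparse
two-basin configuration sets the method consumes.

The fixtures are tiny graphs with literal weights, used throughout the tests:

============  ======================================================
name          contents
============  ======================================================
line3         0-1-2, weights 1.0 and 0.5; unique path, action 1.5
triangle      0-1-2 plus direct edge 0-2 (weight 3.0 vs 1.0 + 1.0)
two_channel   exactly two simple 0->3 paths with actions 1.0 and 2.0
four_channel  four parallel 2-hop channels, actions 1.0, 1.0, 2.0, 2.0
ladder8       2x4 grid ladder with mixed literal weights, 0 -> 7
subtour5      direct edge 0-1 plus a disjoint triangle 2-3-4
============  ======================================================
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .cg_graph import CGParams, Configuration, Edge, ManifoldGraph

__all__ = ["ToyLandscape", "langevin_sample", "fixture", "FIXTURE_NAMES"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ToyLandscape:
    """Symmetric double well ``V = h (x^2-1)^2 + (omega/2) y^2``.

    ``h`` is the barrier height in units of kBT=1 (default 3), ``omega`` the
    transverse stiffness (default 2).
    """

    h: float = 3.0
    omega: float = 2.0

    def potential(self, x: float, y: float) -> float:
        return self.h * (x * x - 1.0) ** 2 + 0.5 * self.omega * y * y

    def gradient(self, x: float, y: float) -> tuple[float, float]:
        return 4.0 * self.h * x * (x * x - 1.0), self.omega * y

    @property
    def minima(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (-1.0, 0.0), (1.0, 0.0)

    @property
    def saddle(self) -> tuple[float, float]:
        return (0.0, 0.0)


def _simulate(
    landscape: ToyLandscape,
    n_steps: int,
    step_size: float,
    kBT: float,
    rng: np.random.Generator,
    start: tuple[float, float],
) -> np.ndarray:
    noise = rng.standard_normal((n_steps, 2)) * math.sqrt(2.0 * kBT * step_size)
    traj = np.empty((n_steps, 2))
    x, y = start
    for k in range(n_steps):
        gx, gy = landscape.gradient(x, y)
        x = x - step_size * gx + noise[k, 0]
        y = y - step_size * gy + noise[k, 1]
        traj[k, 0], traj[k, 1] = x, y
        if abs(x) > 1e3 or abs(y) > 1e3:
            raise RuntimeError(
                "Langevin integration diverged; reduce step_size "
                "(stability needs step_size << 1/(8h) and << 1/omega)"
            )
    return traj


def langevin_sample(
    landscape: ToyLandscape = ToyLandscape(),
    n_steps: int = 200_000,
    step_size: float = 0.01,
    kBT: float = 1.0,
    seed: int = 0,
    start: tuple[float, float] = (-1.0, 0.0),
    bin_width: float = 0.35,
    min_count: int = 5,
    max_attempts: int = 5,
    require_both_basins: bool = True,
) -> list[Configuration]:
    """Overdamped Langevin sampling binned into a sparse configuration set.

    Positions are binned onto a square grid of spacing ``bin_width``
    (comparable to the intended coarse-graining resolution); each occupied
    cell becomes one configuration at the cell centre, carrying the number of
    raw samples that fell into it.  Cells visited fewer than ``min_count``
    times are dropped: their local density (hence effective potential) is not
    meaningfully estimated, and they correspond to excursions off the
    well-sampled manifold.  If the trajectory has not visited both basins,
    the run is repeated with doubled length and a fresh child seed (logged)
    until it has.
    """
    if step_size * max(8.0 * landscape.h, landscape.omega) > 0.5:
        raise ValueError("step_size too large for stable integration")
    ss = np.random.SeedSequence(seed)
    for attempt in range(max_attempts):
        rng = np.random.default_rng(ss.spawn(1)[0])
        traj = _simulate(landscape, n_steps, step_size, kBT, rng, start)
        left = np.any(traj[:, 0] < -0.5)
        right = np.any(traj[:, 0] > 0.5)
        if (left and right) or not require_both_basins:
            break
        log.warning(
            "attempt %d: trajectory visited only one basin; doubling length", attempt
        )
        n_steps *= 2
    else:
        raise RuntimeError("trajectory never visited both basins")
    cells = np.floor(traj / bin_width).astype(int)
    keys, counts = np.unique(cells, axis=0, return_counts=True)
    keep = counts >= min_count
    configs = []
    for k, (cell, cnt) in enumerate(zip(keys[keep], counts[keep])):
        centre = (cell + 0.5) * bin_width
        configs.append(Configuration(id=k, coords=centre, count=int(cnt)))
    return configs


def _literal_graph(
    coords: dict[int, tuple[float, ...]],
    weights: dict[tuple[int, int], float],
    sigma: float = 1.0,
) -> ManifoldGraph:
    params = CGParams(sigma=sigma)
    configs = [Configuration(id=i, coords=np.asarray(c, float)) for i, c in sorted(coords.items())]
    edges = []
    for (i, j), w in sorted(weights.items()):
        d2 = float(np.sum((np.asarray(coords[i]) - np.asarray(coords[j])) ** 2))
        edges.append(Edge(i=i, j=j, dist2=d2, w_ij=w, w_ji=w, w_sym=w))
    V = np.zeros(len(configs))
    return ManifoldGraph(configurations=configs, V_cg=V, edges=edges, params=params)


FIXTURE_NAMES = ("line3", "triangle", "two_channel", "four_channel", "ladder8", "subtour5")


def fixture(name: str) -> tuple[ManifoldGraph, int, int]:
    """Return ``(graph, s, t)`` for a named fixture graph."""
    if name == "line3":
        g = _literal_graph(
            {0: (0.0, 0.0), 1: (1.0, 0.0), 2: (2.0, 0.0)},
            {(0, 1): 1.0, (1, 2): 0.5},
        )
        return g, 0, 2
    if name == "triangle":
        g = _literal_graph(
            {0: (0.0, 0.0), 1: (1.0, 1.0), 2: (2.0, 0.0)},
            {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 3.0},
        )
        return g, 0, 2
    if name == "two_channel":
        g = _literal_graph(
            {0: (0.0, 0.0), 1: (1.0, 1.0), 2: (1.0, -1.0), 3: (2.0, 0.0)},
            {(0, 1): 0.5, (1, 3): 0.5, (0, 2): 1.0, (2, 3): 1.0},
        )
        return g, 0, 3
    if name == "four_channel":
        # two action-degenerate pairs: the valid spectrum has exactly two
        # levels, the regime in which the Gaussian response model's
        # log-density ratios can be faithful to a monotone annealer response
        coords = {0: (0.0, 0.0), 5: (2.0, 0.0)}
        weights = {}
        for k, action in enumerate((1.0, 1.0, 2.0, 2.0), start=1):
            coords[k] = (1.0, float(k) - 2.5)
            weights[(0, k)] = action / 2.0
            weights[(k, 5)] = action / 2.0
        return _literal_graph(coords, weights), 0, 5
    if name == "ladder8":
        coords = {i: (float(i % 4), float(i // 4)) for i in range(8)}
        weights = {
            (0, 1): 0.3, (1, 2): 0.7, (2, 3): 0.4,
            (4, 5): 0.6, (5, 6): 0.2, (6, 7): 0.5,
            (0, 4): 0.8, (1, 5): 0.25, (2, 6): 0.9, (3, 7): 0.35,
        }
        return _literal_graph(coords, weights), 0, 7
    if name == "subtour5":
        # direct s-t edge plus a disjoint 3-cycle: the classic subtour trap
        g = _literal_graph(
            {0: (0.0, 0.0), 1: (1.0, 0.0), 2: (3.0, 0.0), 3: (4.0, 0.0), 4: (3.5, 1.0)},
            {(0, 1): 0.7, (2, 3): 0.2, (3, 4): 0.3, (2, 4): 0.4},
        )
        return g, 0, 1
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
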