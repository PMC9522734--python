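"""Canned study protocols: fixture chain experiments and the double-well pipeline.

These functions bundle the package's recommended operating points so that
examples, tests and reproduction scripts run the same protocol.

Fixture chains
--------------
On the small fixture graphs the proposal annealer is run *warm*
(``beta_end`` below 1 in model-energy units) with the constraint strength
raised to twice the sum-of-weights heuristic.  Rationale: the Metropolis
reweighting is exact only insofar as the Gaussian (lowest-cumulant) response
model describes the annealer's actual outcome distribution.  A cold annealer
on a tiny problem is nearly deterministic, and a Gaussian fitted to an
almost-degenerate outcome distribution misstates the proposal-density ratios;
keeping the terminal temperature warm leaves the response dispersed, while
the stiffer constraint keeps essentially every warm sample a valid path
topology.  These are method parameters: they change proposal efficiency and
response fidelity, never the target ensemble e^{-S}/Z.

Double-well pipeline
--------------------
On the synthetic landscape the graph has hundreds of edges, and a
single-bit-flip annealer imposes a scale constraint the sum-of-weights alpha
heuristic violates: once ``beta * alpha`` exceeds a few, the path topology is
frozen, so the action term can only shape the outcome if ``beta * w`` is
already order one at that point — i.e. the constraint strength must sit only
a few times above the typical edge weight.  The pipeline therefore uses the
diffusive time step (keeping edge weights order one), sets ``alpha`` to a
small multiple of the median edge weight, and anneals from
``beta_start ~ 0.05`` (fluid topology) to ``beta_end ~ 6`` (topology and
action both frozen).  A minority of anneals still terminate in
constraint-satisfying states carrying disjoint cycles; these are rejected at
decode and the valid fraction is simply below one, exactly as hardware
annealers return a finite fraction of correct-topology sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cg_graph import ManifoldGraph, build_graph
from .mc import ChainRecord, SweepParams, run_chain
from .qubo import PathProblem, assemble
from .response import ResponseProfile, calibrate
from .samplers import AnnealConfig, SimulatedAnnealer
from .synthetic import ToyLandscape, fixture, langevin_sample

__all__ = [
    "FIXTURE_CHAIN_DEFAULTS",
    "fixture_chain",
    "DoubleWellRun",
    "double_well_pipeline",
]

log = logging.getLogger(__name__)

#: operating point for chain experiments on the literal fixtures
FIXTURE_CHAIN_DEFAULTS = dict(
    alpha_multiplier=2.0,   # x the sum-of-weights heuristic
    beta_start=0.1,
    beta_end=0.9,           # warm terminal temperature: dispersed response
    calibration_grid=(15.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0),
    calibration_reps=1600,
)


def fixture_chain(
    name: str,
    n_steps: int,
    seed: int,
    *,
    alpha_multiplier: float = FIXTURE_CHAIN_DEFAULTS["alpha_multiplier"],
    beta_end: float = FIXTURE_CHAIN_DEFAULTS["beta_end"],
    calibration_reps: int = FIXTURE_CHAIN_DEFAULTS["calibration_reps"],
    sweep_params: SweepParams | None = None,
) -> tuple[PathProblem, ResponseProfile, ChainRecord]:
    """Calibrate and run the hybrid chain on a named fixture graph."""
    g, s, t = fixture(name)
    prob = PathProblem(
        graph=g, s=s, t=t, alpha=alpha_multiplier * g.total_symmetric_weight()
    )
    sampler = SimulatedAnnealer(
        prob, AnnealConfig(beta_start=FIXTURE_CHAIN_DEFAULTS["beta_start"],
                           beta_end=beta_end)
    )
    profile = calibrate(
        sampler, FIXTURE_CHAIN_DEFAULTS["calibration_grid"],
        n_reps=calibration_reps, seed=seed + 1,
    )
    params = sweep_params or SweepParams()
    record = run_chain(prob, sampler, profile, params, n_steps=n_steps, seed=seed)
    return prob, profile, record


@dataclass
class DoubleWellRun:
    """Everything the end-to-end synthetic pipeline produced."""

    graph: ManifoldGraph
    problem: PathProblem
    profile: ResponseProfile
    record: ChainRecord
    s: int
    t: int


def _nearest_node(graph: ManifoldGraph, point) -> int:
    X = np.vstack([c.coords for c in graph.configurations])
    k = int(np.argmin(np.sum((X - np.asarray(point)) ** 2, axis=1)))
    return graph.configurations[k].id


def double_well_pipeline(
    seed: int,
    n_langevin: int = 200_000,
    n_chain: int = 200,
    landscape: ToyLandscape = ToyLandscape(),
    bin_width: float = 0.35,
    knn: int = 6,
    alpha_over_median_weight: float = 2.5,
    beta_start: float = 0.05,
    beta_end: float = 6.0,
    sweeps_per_second: float = 60.0,
    calibration_reps: int = 80,
    calibration_grid=(75.0, 150.0, 225.0, 300.0),
    sweep_params: SweepParams | None = None,
) -> DoubleWellRun:
    """Sample the double well, build the graph, and run the full chain.

    The start and end nodes are the graph nodes nearest the two minima of the
    landscape; the coarse time step is diffusive (``dt = sigma**2/2`` at
    ``kBT = 1``) and the constraint strength is
    ``alpha_over_median_weight`` times the median symmetrised edge weight
    (see module docstring for why the sum-of-weights heuristic is not usable
    with a single-bit-flip annealer at this problem size).
    """
    ss = np.random.SeedSequence(seed)
    s_lang, s_cal, s_chain = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
    configs = langevin_sample(
        landscape, n_steps=n_langevin, seed=s_lang, bin_width=bin_width
    )
    graph = build_graph(configs, k=knn, dt=None)
    s = _nearest_node(graph, landscape.minima[0])
    t = _nearest_node(graph, landscape.minima[1])
    w_med = float(np.median([e.w_sym for e in graph.edges]))
    prob = PathProblem(graph=graph, s=s, t=t, alpha=alpha_over_median_weight * w_med)
    sampler = SimulatedAnnealer(
        prob,
        AnnealConfig(beta_start=beta_start, beta_end=beta_end,
                     sweeps_per_second=sweeps_per_second),
    )
    log.info("double well: %d nodes, %d edges, %d qubits, alpha=%.3g",
             graph.nu, len(graph.edges), prob.n_qubits, prob.alpha_value)
    profile = calibrate(sampler, calibration_grid, n_reps=calibration_reps, seed=s_cal)
    if sweep_params is None:
        # below ~75 s of abstract sweep time the annealer rarely returns a
        # valid topology on problems this size; excluding that region spends
        # the proposal budget where trials are viable
        sweep_params = SweepParams(t_min=75.0, t_max=300.0)
    record = run_chain(prob, sampler, profile, sweep_params, n_steps=n_chain, seed=s_chain)
    return DoubleWellRun(graph=graph, problem=prob, profile=profile,
                         record=record, s=s, t=t)
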