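"""Hybrid Metropolis chain over (path, sweep time).

The chain targets the joint equilibrium distribution

.. math::  \\rho(t_{sweep}, I) = p_0(t_{sweep})\\, e^{-S(I)},

so that its path marginal is the transition path ensemble
:math:`P(I) \\propto e^{-S(I)}`.  Each step (i) updates the sweep time by one
step of Brownian dynamics with a harmonic drift toward a target time ``t0``,

.. math::  t' = t - \\delta t\\,k\\,(t - t_0) + \\sqrt{2\\,\\delta t}\\;\\xi,

reflected into ``[t_min, t_max]``; (ii) draws a fresh, independent path
proposal by annealing at the new sweep time; (iii) accepts with the Metropolis
probability

.. math::  \\min\\!\\left[1,\\;
    \\frac{p_0(t')\\,P(t|t')}{p_0(t)\\,P(t'|t)}\\;
    \\frac{P(I|t)}{P(I'|t')}\\;
    \\frac{e^{-S(I')}}{e^{-S(I)}}\\right],

where the annealer's proposal density ``P(I|t)`` is evaluated through the
calibrated Gaussian response model at ``E = S(I)``.  Proposals with invalid
path topology are rejected outright (the sweep time is not updated either):
they correspond to constraint-violating excitations excluded from the target
ensemble.  ``p_0`` is chosen as the stationary law of the drift,
``N(t0, 1/k)`` truncated to the bounds, which makes the sweep-time factors
nearly cancel.  All arithmetic is done in log space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, truncnorm

from .cg_graph import CGPath
from .qubo import PathProblem
from .response import ResponseProfile

__all__ = [
    "SweepParams",
    "ChainState",
    "ChainRecord",
    "propose_tsweep",
    "tsweep_transition_density",
    "p0_density",
    "acceptance_probability",
    "run_chain",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepParams:
    """Sweep-time dynamics: target t0 (s), stiffness k (1/s), step delta_t (s)."""

    t0: float = 150.0
    k: float = 2e-4
    delta_t: float = 50.0
    t_min: float | None = None  # default t0 / 10
    t_max: float | None = None  # default 2 * t0

    def __post_init__(self) -> None:
        if self.t_min is None:
            object.__setattr__(self, "t_min", self.t0 / 10.0)
        if self.t_max is None:
            object.__setattr__(self, "t_max", 2.0 * self.t0)
        if not (0 < self.t_min < self.t0 < self.t_max):
            raise ValueError("need 0 < t_min < t0 < t_max")
        if not (self.k > 0 and self.delta_t > 0):
            raise ValueError("k and delta_t must be positive")
        if self.delta_t * self.k >= 1.0:
            raise ValueError("delta_t * k must be < 1 for a stable drift")

    def drift_mean(self, t: float) -> float:
        return t - self.delta_t * self.k * (t - self.t0)

    @property
    def step_sd(self) -> float:
        return math.sqrt(2.0 * self.delta_t)


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
        if x > hi:
            x = 2.0 * hi - x
        # pathological jumps (> width) terminate via successive folds
        if width <= 0:  # pragma: no cover - guarded by SweepParams
            raise ValueError("empty reflection interval")
    return x


def propose_tsweep(t: float, params: SweepParams, rng: np.random.Generator) -> float:
    """One Brownian sweep-time update, reflected into the bounds."""
    xi = rng.standard_normal()
    t_new = params.drift_mean(t) + params.step_sd * xi
    return _reflect(t_new, params.t_min, params.t_max)


def tsweep_transition_density(t_to: float, t_from: float, params: SweepParams) -> float:
    """Density of the reflected drift-diffusion step ``t_from -> t_to``.

    Gaussian with mean ``t_from - delta_t*k*(t_from - t0)`` and variance
    ``2*delta_t``; reflection at the bounds adds the first mirror image about
    each boundary (higher-order images are negligible for step sizes small
    compared to the interval).
    """
    if t_to < params.t_min or t_to > params.t_max:
        return 0.0
    mu, sd = params.drift_mean(t_from), params.step_sd
    d = norm.pdf(t_to, loc=mu, scale=sd)
    d += norm.pdf(2.0 * params.t_min - t_to, loc=mu, scale=sd)
    d += norm.pdf(2.0 * params.t_max - t_to, loc=mu, scale=sd)
    return float(d)


def p0_density(t: float, params: SweepParams) -> float:
    """Equilibrium sweep-time law: N(t0, 1/k) truncated to [t_min, t_max]."""
    sd = math.sqrt(1.0 / params.k)
    a = (params.t_min - params.t0) / sd
    b = (params.t_max - params.t0) / sd
    return float(truncnorm.pdf(t, a, b, loc=params.t0, scale=sd))


def _log_or_neginf(x: float) -> float:
    return math.log(x) if x > 0.0 else -math.inf


@dataclass
class ChainState:
    """Current chain position: a valid path, its action, and the sweep time."""

    path: CGPath
    t_sweep: float

    @property
    def action(self) -> float:
        return self.path.action


def log_acceptance(
    current: ChainState,
    candidate: ChainState,
    profile: ResponseProfile,
    params: SweepParams,
) -> float:
    """Log of the Metropolis ratio (before capping at 0)."""
    t, tp = current.t_sweep, candidate.t_sweep
    s, sp = current.action, candidate.action
    lr = _log_or_neginf(p0_density(tp, params)) - _log_or_neginf(p0_density(t, params))
    lr += _log_or_neginf(tsweep_transition_density(t, tp, params))
    lr -= _log_or_neginf(tsweep_transition_density(tp, t, params))
    lr += profile.log_density(s, t) - profile.log_density(sp, tp)
    lr += s - sp
    return lr


def acceptance_probability(
    current: ChainState,
    candidate: ChainState,
    profile: ResponseProfile,
    params: SweepParams,
) -> float:
    lr = log_acceptance(current, candidate, profile, params)
    if math.isnan(lr):
        log.warning("zero proposal density in acceptance ratio; rejecting")
        return 0.0
    return min(1.0, math.exp(min(lr, 0.0)))


@dataclass
class ChainRecord:
    """Per-step trace of the chain plus summary rates."""

    rows: list[dict] = field(default_factory=list)
    states: list[ChainState] = field(default_factory=list)
    seed: int | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    @property
    def acceptance_rate(self) -> float:
        n = [r for r in self.rows if r["step"] > 0]
        return sum(r["accepted"] for r in n) / len(n) if n else math.nan

    @property
    def invalid_rate(self) -> float:
        n = [r for r in self.rows if r["step"] > 0]
        return sum(not r["valid"] for r in n) / len(n) if n else math.nan

    def ensemble(self, burn_in: float = 0.1) -> list[CGPath]:
        """Post-burn-in sequence of chain states' paths (chain order kept)."""
        k = int(len(self.states) * burn_in)
        return [st.path for st in self.states[k:]]

    def tsweep_series(self, burn_in: float = 0.1) -> np.ndarray:
        k = int(len(self.states) * burn_in)
        return np.asarray([st.t_sweep for st in self.states[k:]])


def find_initial_state(
    problem: PathProblem,
    sampler,
    params: SweepParams,
    rng: np.random.Generator,
    budget: int = 200,
) -> ChainState:
    """Anneal at t0 until a valid topology appears."""
    for _ in range(budget):
        seed = int(rng.integers(2**31))
        res = sampler(params.t0, seed)
        if res.valid_topology:
            return ChainState(path=res.decoded, t_sweep=params.t0)
    raise RuntimeError(
        f"no valid initial path found in {budget} anneals at t_sweep={params.t0}"
    )


def run_chain(
    problem: PathProblem,
    sampler,
    profile: ResponseProfile,
    params: SweepParams,
    n_steps: int,
    seed: int,
    initial: ChainState | None = None,
    init_budget: int = 200,
) -> ChainRecord:
    """Run the hybrid Metropolis chain; bit-reproducible from ``seed``.

    ``sampler(t_sweep, seed) -> AnnealResult`` supplies fresh path proposals.
    Step 0 of the record is the initial state; each subsequent step proposes a
    sweep time, anneals at it, and accepts or rejects.
    """
    rng = np.random.default_rng(seed)
    state = initial if initial is not None else find_initial_state(
        problem, sampler, params, rng, budget=init_budget
    )
    rec = ChainRecord(seed=seed)
    rec.states.append(state)
    rec.rows.append({
        "step": 0, "t_sweep": state.t_sweep, "t_proposed": state.t_sweep,
        "S": state.action, "S_proposed": state.action,
        "accepted": True, "valid": True, "seed": seed,
    })
    for step in range(1, n_steps + 1):
        t_prop = propose_tsweep(state.t_sweep, params, rng)
        anneal_seed = int(rng.integers(2**31))
        res = sampler(t_prop, anneal_seed)
        accepted = False
        s_prop = math.nan
        if res.valid_topology:
            cand = ChainState(path=res.decoded, t_sweep=t_prop)
            s_prop = cand.action
            a = acceptance_probability(state, cand, profile, params)
            if rng.random() < a:
                state = cand
                accepted = True
        rec.states.append(state)
        rec.rows.append({
            "step": step, "t_sweep": state.t_sweep, "t_proposed": t_prop,
            "S": state.action, "S_proposed": s_prop,
            "accepted": accepted, "valid": bool(res.valid_topology),
            "seed": anneal_seed,
        })
    return rec
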