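"""Annealer-response model: the energy distribution P(E | t_sweep).

The Metropolis chain needs the probability that one anneal of duration
``t_sweep`` returns a given path; identifying paths with their (non-degenerate)
energies, this is the annealer's energy response ``P(E | t_sweep)``.  It is
estimated empirically — many anneals per sweep time on a grid — and
approximated at lowest cumulant order by a Gaussian,

.. math::  P(E | t) \\simeq \\frac{1}{\\sqrt{2\\pi}\\,\\Delta(t)}
           \\exp\\!\\left(-\\frac{(E - \\bar E(t))^2}{2\\Delta(t)^2}\\right),

with the mean and standard deviation interpolated linearly between grid
points.  Only anneals decoding to a valid path topology enter the statistics
(the response is a distribution over paths); the invalid fraction is recorded
alongside.  The standard deviation uses the population convention
(divide by n) and is clamped below by ``floor`` to keep degenerate samplers
evaluable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ResponseProfile", "calibrate", "density"]

log = logging.getLogger(__name__)


@dataclass
class ResponseProfile:
    """Calibrated (mean, spread) of the annealer energy per sweep time."""

    t_grid: np.ndarray
    E_bar: np.ndarray
    Delta: np.ndarray
    n: np.ndarray
    valid_fraction: np.ndarray
    floor: float = 1e-6

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.E_bar = np.asarray(self.E_bar, dtype=float)
        self.Delta = np.asarray(self.Delta, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.valid_fraction = np.asarray(self.valid_fraction, dtype=float)
        if np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        if np.any(self.n < 2):
            raise ValueError("each grid entry needs at least 2 samples")
        self.Delta = np.maximum(self.Delta, self.floor)

    def interpolate(self, t_sweep: float) -> tuple[float, float]:
        """(E_bar, Delta) at ``t_sweep``; nearest-value hold beyond the grid."""
        if t_sweep < self.t_grid[0] or t_sweep > self.t_grid[-1]:
            log.warning("t_sweep=%g outside calibration grid [%g, %g]; extrapolating",
                        t_sweep, self.t_grid[0], self.t_grid[-1])
        eb = float(np.interp(t_sweep, self.t_grid, self.E_bar))
        dl = float(np.interp(t_sweep, self.t_grid, self.Delta))
        return eb, max(dl, self.floor)

    def log_density(self, E: float, t_sweep: float) -> float:
        eb, dl = self.interpolate(t_sweep)
        return -0.5 * math.log(2.0 * math.pi) - math.log(dl) - (E - eb) ** 2 / (2.0 * dl**2)


def density(E: float, t_sweep: float, profile: ResponseProfile) -> float:
    """Gaussian (lowest-cumulant) response density ``P(E | t_sweep)``."""
    return math.exp(profile.log_density(E, t_sweep))


def calibrate(
    sampler,
    t_grid,
    n_reps: int,
    seed: int,
    floor: float = 1e-6,
) -> ResponseProfile:
    """Estimate the response profile by repeated annealing on a sweep-time grid.

    ``sampler(t_sweep, seed) -> AnnealResult``.  For every grid time,
    ``n_reps`` anneals are run with independent seeds spawned from ``seed``;
    the mean and population standard deviation of the valid-topology energies
    are recorded, along with the fraction of valid results.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    t_grid = np.asarray(sorted(float(t) for t in t_grid))
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(t_grid) * n_reps)]
    E_bar, Delta, n_valid, frac = [], [], [], []
    for k, t in enumerate(t_grid):
        energies = []
        n_ok = 0
        for r in range(n_reps):
            res = sampler(float(t), child_seeds[k * n_reps + r])
            if res.valid_topology:
                energies.append(res.energy)
                n_ok += 1
        if n_ok < 2:
            raise ValueError(
                f"calibration failed at t_sweep={t}: only {n_ok} valid-topology "
                f"results out of {n_reps}"
            )
        e = np.asarray(energies)
        E_bar.append(float(e.mean()))
        Delta.append(max(float(e.std(ddof=0)), floor))
        n_valid.append(n_ok)
        frac.append(n_ok / n_reps)
    return ResponseProfile(
        t_grid=t_grid,
        E_bar=np.asarray(E_bar),
        Delta=np.asarray(Delta),
        n=np.asarray(n_valid),
        valid_fraction=np.asarray(frac),
        floor=floor,
    )
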