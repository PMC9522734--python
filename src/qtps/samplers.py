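"""Low-energy samplers for the assembled path Hamiltonian.

Two samplers share one request/result contract: an exhaustive brute-force
solver (the test oracle, limited to small instances) and a classical
simulated annealer that stands in for a quantum annealing backend.  The
annealer's effort is controlled by an abstract sweep time ``t_sweep`` in
seconds, mapped to an integer number of Metropolis passes via
``n_sweeps = max(1, round(sweeps_per_second * t_sweep))``: the Markov chain
above needs a real-valued knob, the classical sampler an integer one.

Each anneal starts from unbiased random bits (every bit on with probability
one half, mirroring a transverse-field start in which each qubit begins in an
equal superposition) and performs single-bit-flip Metropolis passes while the
inverse temperature rises geometrically from ``beta_start`` to ``beta_end``.
All randomness derives from the request seed; identical requests give
bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cg_graph import CGPath
from .qubo import BinaryConfiguration, Invalid, PathProblem, QuadraticModel, decode

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "AnnealConfig",
    "AnnealRequest",
    "AnnealResult",
    "exact_ground_state",
    "simulated_anneal",
    "SimulatedAnnealer",
    "validate_result",
]


@dataclass(frozen=True)
class AnnealConfig:
    """Schedule parameters of the classical annealer."""

    beta_start: float = 0.1
    beta_end: float = 10.0
    sweeps_per_second: float = 10.0

    def n_sweeps(self, t_sweep: float) -> int:
        return max(1, int(round(self.sweeps_per_second * t_sweep)))

    def betas(self, t_sweep: float) -> np.ndarray:
        return np.geomspace(self.beta_start, self.beta_end, self.n_sweeps(t_sweep))


@dataclass(frozen=True)
class AnnealRequest:
    """One anneal: a model, an abstract sweep time (s), and a seed."""

    model: QuadraticModel
    t_sweep: float
    seed: int
    config: AnnealConfig = AnnealConfig()

    def __post_init__(self) -> None:
        if not self.t_sweep > 0:
            raise ValueError("t_sweep must be positive")


@dataclass(frozen=True)
class AnnealResult:
    """Sampler output: the final configuration, its energy, and its decode."""

    configuration: BinaryConfiguration
    energy: float
    valid_topology: bool
    decoded: "CGPath | Invalid"
    t_sweep: float | None = None
    seed: int | None = None


def validate_result(result: AnnealResult, model: QuadraticModel, atol: float = 1e-9) -> None:
    """Backend contract: the reported energy must match the model's evaluation.

    Any sampler backend (including external annealing hardware) must return
    results passing this check; a violation raises rather than being patched.
    """
    e = model.energy(result.configuration)
    if abs(e - result.energy) > atol * max(1.0, abs(e)):
        raise ValueError(
            f"backend contract violation: reported energy {result.energy!r} "
            f"!= model energy {e!r}"
        )


def _enumerate_energies(model: QuadraticModel, chunk_bits: int = 18):
    """Yield (X, E) chunks over all binary configurations, lexicographic order."""
    n = len(model.variables)
    total = 1 << n
    step = 1 << min(chunk_bits, n)
    for start in range(0, total, step):
        codes = np.arange(start, min(start + step, total), dtype=np.int64)
        # bit 0 of the variable order is the most significant digit, so that
        # increasing code order is lexicographic order of the bit tuples
        X = (codes[:, None] >> (n - 1 - np.arange(n))) & 1
        yield X, model.energies(X)


def exact_ground_state(
    model: QuadraticModel, problem: PathProblem | None = None, max_bits: int = 24
) -> AnnealResult:
    """Exhaustive minimisation; ties broken by lexicographic configuration.

    Oracle only: refuses instances above ``max_bits`` variables.
    """
    n = len(model.variables)
    if n > max_bits:
        raise ValueError(f"instance too large for exhaustive search ({n} > {max_bits} bits)")
    best_e = np.inf
    best_x = None
    for X, E in _enumerate_energies(model):
        k = int(np.argmin(E))  # first occurrence = lexicographic tie-break
        if E[k] < best_e:
            best_e = float(E[k])
            best_x = X[k].copy()
    conf = BinaryConfiguration.from_vector(model.variables, best_x)
    decoded = decode(problem, conf) if problem is not None else None
    return AnnealResult(
        configuration=conf,
        energy=best_e,
        valid_topology=decoded is not None and not isinstance(decoded, Invalid),
        decoded=decoded,
    )


def _anneal_python(x, h, indptr, indices, data, betas, u):
    n = x.shape[0]
    f = h.copy()  # local field: dE of turning bit i on from 0
    for i in range(n):
        if x[i] != 0.0:
            for p in range(indptr[i], indptr[i + 1]):
                f[indices[p]] += data[p]
    for s in range(betas.shape[0]):
        beta = betas[s]
        for i in range(n):
            dE = (1.0 - 2.0 * x[i]) * f[i]
            if dE <= 0.0 or u[s, i] < np.exp(-beta * dE):
                delta = 1.0 - 2.0 * x[i]
                x[i] += delta
                for p in range(indptr[i], indptr[i + 1]):
                    f[indices[p]] += data[p] * delta
    return x


if _HAVE_NUMBA:
    _kernel = njit(cache=False)(_anneal_python)
else:  # pragma: no cover
    _kernel = _anneal_python


def _model_csr(model: QuadraticModel):
    """Cached sparse-coupling view of a model: (h, indptr, indices, data)."""
    cached = getattr(model, "_csr_cache", None)
    if cached is not None:
        return cached
    from scipy.sparse import csr_matrix

    h, Q, _ = model.to_arrays()
    S = csr_matrix(Q)
    out = (h, S.indptr.astype(np.int64), S.indices.astype(np.int64), S.data)
    model._csr_cache = out
    return out


def simulated_anneal(request: AnnealRequest, problem: PathProblem | None = None) -> AnnealResult:
    """Single-bit-flip Metropolis annealing of a quadratic binary model.

    Sweeps pass over the bits in index order; the geometric inverse-temperature
    ladder has one rung per sweep.  Returns the final configuration (not the
    best-seen one: the sampler emulates an annealer whose output *is* its
    final state).
    """
    model = request.model
    h, indptr, indices, data = _model_csr(model)
    n = len(model.variables)
    rng = np.random.default_rng(request.seed)
    x = (rng.random(n) < 0.5).astype(np.float64)
    betas = request.config.betas(request.t_sweep)
    u = rng.random((betas.shape[0], n))
    x = _kernel(x, h, indptr, indices, data, betas, u)
    conf = BinaryConfiguration.from_vector(model.variables, x.astype(np.int8))
    energy = model.energy(conf)
    decoded: CGPath | Invalid | None = None
    valid = False
    if problem is not None:
        decoded = decode(problem, conf)
        valid = not isinstance(decoded, Invalid)
    return AnnealResult(
        configuration=conf,
        energy=energy,
        valid_topology=valid,
        decoded=decoded,
        t_sweep=request.t_sweep,
        seed=request.seed,
    )


class SimulatedAnnealer:
    """Callable sampler bound to a problem; the form the Markov chain consumes.

    ``sampler(t_sweep, seed) -> AnnealResult`` with the assembled model of
    ``problem`` and a fixed :class:`AnnealConfig`.
    """

    def __init__(self, problem: PathProblem, config: AnnealConfig | None = None,
                 model: QuadraticModel | None = None):
        from .qubo import assemble

        self.problem = problem
        self.config = config or AnnealConfig()
        self.model = model if model is not None else assemble(problem)

    def __call__(self, t_sweep: float, seed: int) -> AnnealResult:
        req = AnnealRequest(model=self.model, t_sweep=t_sweep, seed=seed, config=self.config)
        return simulated_anneal(req, problem=self.problem)
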