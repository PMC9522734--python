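# Methods

This note records the model, the estimators, the tunable parameters and the
design choices behind `qtps`, and what its tests do and do not demonstrate.

## Coarse-grained theory on the configuration graph

The starting object is a sparse set of configurations {Q_i} assumed to lie on
the intrinsic manifold of the system, each carrying a count n_i of raw
samples assigned to its cell.  The coarse-grained theory has four
parameters, all in reduced units:

| parameter | meaning | default |
|---|---|---|
| m | mass | 1 |
| kBT | thermal energy | 1 |
| σ | spatial resolution: mean distance between adjacent configurations | estimated |
| Δt | coarse time step | 1 (or diffusive, see below) |

D_cg = σ²/(2Δt) is derived, never free.  The directed step weight is

w_ij = [ m|Q_i−Q_j|²/(2Δt) + V_cg(Q_i)Δt ] / (2 m D_cg),

whose kinetic part reduces to |Q_i−Q_j|²/(2σ²).

**Effective potential.**  V_cg(Q_i) = −kBT·ln(n_i/Σn), shifted so its
minimum is zero.  This is the Boltzmann inversion of the equilibrium cell
occupancy; the shift keeps all weights non-negative.  Add-one smoothing is
applied when any count is zero.  More elaborate estimators (e.g. kinetic
ones) can be substituted per node without touching the rest of the package.

**Adjacency.**  Mutual k-nearest neighbours (default k = 6) with a distance
cutoff of 3σ.  Kinetic closeness (transition counts between cells) is *not*
enforced — only structural proximity — which is a known divergence from what
a transition-count-based rule would give on poorly sampled data.

**Symmetrisation.**  w_ij uses V_cg at the departure node only, so directed
weights differ; the undirected encoding needs one number per edge.  Both
directed weights are stored and w̄_ij = (w_ij + w_ji)/2 is used everywhere a
single weight is required (action, QUBO target, Dijkstra).  Path actions are
then reversal-symmetric; totals differ from the directed sum only by
endpoint terms.

**Diffusive time step.**  With Δt = 1 and σ < 1 the potential term
V_cg·Δt/(2mD_cg) = V_cg·Δt²·(…)/σ² can dwarf the kinetic term and produce
weights of order tens.  Passing `dt=None` to `build_graph` selects
Δt = σ²/(2·kBT): the mean time an overdamped walker with D = kBT (mobility
1) needs to diffuse across one resolution cell.  This makes D_cg = D and
keeps weights order one — the regime in which path probabilities on the
graph are comparable.  The synthetic pipeline uses this choice.

**Distances** are plain Euclidean on flattened coordinate vectors, no
rotational/translational superposition (σ then equals δ_RMSD·√N_atoms for
all-atom coordinates).  Superposition, if wanted, is a pre-processing step.

## QUBO / Ising encoding

Bits: Γ⁽¹⁾_i per node, Γ⁽²⁾_ij per undirected edge.  The constraint part is

H_s = −Γ⁽¹⁾_s + (Γ⁽¹⁾_s − Σ_i Γ⁽²⁾_si)²   (H_t analogous),
H_r = Σ_{j≠s,t} (2Γ⁽¹⁾_j − Σ_i Γ⁽²⁾_ji)²,
H_C = H_s + H_t + H_r + 2.

The constant +2 is deliberate: without it a valid path evaluates to −2
(each anchor term contributes −1), which contradicts the requirement that
the constraint be a positive-semidefinite function vanishing exactly on
path-like configurations.  The offset changes no minimiser.  Exhaustive
enumeration (tested) confirms: min H_C = 0, attained exactly on s–t
flux-conserving edge subgraphs — a simple s–t path possibly accompanied by
disjoint cycles.

**Subtours.**  Disjoint cycles cost zero constraint energy but positive
target energy, so they never occur in the ground state; excited-state
samples may contain them.  `decode` classifies every configuration as a
valid simple path or `INVALID` with reason `node_edge_mismatch`,
`broken_flux`, `subtour_present`, or `not_simple`; invalid proposals count
against the valid-topology fraction exactly as hardware sweeps without
correct path topology would.

**Penalty strength.**  Default α = Σ w̄_ij (all edges).  This guarantees a
clean separation between path-like and violating states for exhaustive or
powerful solvers, and is the default used by the encoding and the exact
solver.  Its interaction with the *local* annealer is discussed below.

The Ising form follows from σᶻ = 2Γ − 1 exactly (tested exhaustively).
Variable order is nodes by id then edges by sorted pair, making model files
reproducible.  The qubit count of an instance is #nodes + #edges.

## Samplers

`exact_ground_state` enumerates all configurations (≤ 24 bits), breaking
ties lexicographically; it is the oracle against which everything else is
checked.

`simulated_anneal` is a classical stand-in for an annealing backend:
single-bit-flip Metropolis over the bits in index order, with a geometric
inverse-temperature ladder β: `beta_start` → `beta_end` (defaults 0.1 → 10,
in model-energy units) and one rung per sweep.  The initial state sets each
bit with probability ½, mirroring an equal-superposition start.  The number
of sweeps is `max(1, round(c · t_sweep))` with c = 10 sweeps per abstract
second by default — the chain needs a real-valued effort knob, the classical
sampler an integer one; c is a free proportionality with no hardware
meaning.  Results are bit-reproducible from the request seed, and any
backend must return results whose energy re-evaluates exactly
(`validate_result`); hardware integration is an interface contract only.

## Annealer response model

P(I|t_sweep) is identified with the energy response P(E|t_sweep) (distinct
paths have distinct actions in generic graphs; see the four-channel caveat
below) and approximated at lowest cumulant order by a Gaussian with mean
Ē(t) and standard deviation Δ(t) estimated from `n_reps` anneals per grid
sweep time.  Choices:

- only valid-topology energies enter (the response is a distribution over
  paths); the invalid fraction is recorded per grid point;
- population standard deviation (divide by n), clamped below by
  `floor = 1e-6`;
- piecewise-linear interpolation of Ē and Δ in t; nearest-value hold beyond
  the grid, with a logged warning;
- calibration noise matters: the acceptance ratio is exponential in
  (E−Ē)/Δ², so Ē errors of order Δ/√n_reps tilt acceptance multiplicatively.
  The fixture experiments use n_reps = 1600 to keep this tilt at the
  per-cent level.

## The hybrid chain

Sweep-time dynamics: t' = t − δt·k·(t−t₀) + √(2δt)·ξ with defaults
t₀ = 150 s, k = 2×10⁻⁴ s⁻¹, δt = 50 s, reflected into [t₀/10, 2t₀].  The
equilibrium sweep-time law p₀ is left arbitrary by the theory; we take the
stationary density of the drift itself, N(t₀, 1/k), truncated to the bounds,
so the sweep-time factors in the acceptance ratio nearly cancel.  The
transition density used in the ratio includes the first mirror image about
each bound, making the Metropolis correction exact to that order (verified
by quadrature and by the Kolmogorov–Smirnov test on the marginal).

Acceptance is computed in log space.  Invalid-topology proposals are
rejected outright and the sweep time is not updated.  Default burn-in is 10%
of the chain; no thinning (the point of annealed proposals is one-shot
decorrelation).

**Exactness caveat.**  Detailed balance holds for the modified target
ρ̂ ∝ p₀·e^(−S)·q(I|t)/P̂(I|t), where q is the annealer's true outcome
distribution and P̂ the calibrated Gaussian.  The chain is unbiased exactly
insofar as P̂ tracks q.  Two consequences shaped the experiment defaults:

1. *Warm proposals.*  A cold annealer on a tiny problem is nearly
   deterministic; a Gaussian fitted to an almost-point distribution
   misstates density ratios badly.  The fixture chain experiments therefore
   run the annealer with `beta_end = 0.9` and raise α to twice the
   sum-of-weights heuristic (stiffer constraints keep essentially all warm
   samples path-like).  These are proposal-efficiency parameters; they do
   not alter the target ensemble.
2. *Two energy levels.*  A Gaussian's log-density is quadratic in E, so its
   ratios can reproduce a monotone (Boltzmann-like) response exactly only
   when the valid spectrum has two distinct levels.  With more well-separated
   levels the lowest-order cumulant approximation is structurally biased —
   precisely the situation the systematic higher-order improvement is for,
   which this package deliberately does not implement.  The four-path test
   fixture therefore carries two action-degenerate pairs (1, 1, 2, 2);
   equal degeneracies cancel exactly in the acceptance ratio.  On dense
   spectra (realistic problem sizes) the Gaussian histogram approximation is
   the natural regime; on sparse non-degenerate spectra it should be used
   with care.

## Synthetic data

The generator emulates what exploratory sampling of a two-state molecular
system provides: a sparse configuration set on a low-dimensional manifold
with two basins and a saddle.  The landscape is the symmetric double well
V = h(x²−1)² + (ω/2)y², h = 3 kBT, ω = 2 — chosen over asymmetric
alternatives because minima (±1, 0) and saddle (0, 0) are analytic, making
"crosses the barrier at its lowest point" an exact check.  Euler–Maruyama
integration (step 0.01, stability bound enforced), 2×10⁵ steps by default;
positions binned on a grid of spacing 0.35 ≈ σ; cells with fewer than 5
samples are dropped (their density estimate is meaningless); the run is
lengthened and re-seeded until both basins are visited.

What it does *not* emulate: high-dimensional geometry, manifold curvature,
kinetic anisotropy, and the exploration process itself.  Tests passing on
these data show the machinery is correct under the model's own assumptions,
not that the adjacency rule or potential estimator is adequate for real
molecular data.

**Single-flip annealing at scale.**  On the pipeline graphs (~150 nodes,
~500 qubits) the sum-of-weights α heuristic is unusable with a local
annealer: constraint stiffness then exceeds typical weights by the edge
count, so the topology freezes while the anneal is still blind to the
action, and the final states are flux-conserving subgraphs laced with
cycles.  A single-bit-flip sampler needs the constraint and action scales to
freeze together, i.e. α only a few times the typical weight.  The pipeline
uses α = 2.5 × median(w̄), β: 0.05 → 6, 60 sweeps/s, and a sweep-time window
of [75, 300] s (shorter anneals rarely yield valid topologies).  Valid
fractions are then ~10–40% — the proposal stream remains usable, as with
hardware runs where only a fraction of sweeps return correct topologies.
Powerful non-local solvers would tolerate the large-α heuristic.

## Numerical choices and degenerate inputs

- Dijkstra ties break toward the lexicographically smallest node sequence;
  the exhaustive solver breaks energy ties toward the lexicographically
  smallest bit string.
- Coincident adjacent configurations (σ = 0) raise; all-zero counts raise;
  an empty adjacency raises; start/end in different components raises at
  problem construction.
- Autocorrelation G(N) is defined over node-indicator vectors x_n:
  G(N) = (1/(L−N)) Σ (x_n−x̄)·(x_{n+N}−x̄).  An ensemble of identical paths
  has G(0) = 0 and the normalised form is flagged undefined.  Other inner
  products (edge indicators, actions) can be substituted.
- Writers emit floats at 17 significant digits with fixed key order;
  identical inputs give byte-identical files.

## Problem sizes used in the shipped experiments

Fixture chains: 2 600 steps (two-channel) and 5 200 steps thinned by two
(four-channel), calibration 7 × 1600 anneals; sweep-time marginal: 20 000
steps of the stub chain, thinned by 25; double-well pipeline: 2×10⁵ Langevin
steps, ~500-qubit encoding, 4 × 80 calibration anneals, 200 chain steps.
These sizes give per-test statistical resolution (3 binomial standard errors
at ~2 300 samples is ±0.028 on a probability) appropriate to the tolerances
asserted in the test suite.

## Known limitations

- The Gaussian response model's structural bias on sparse non-degenerate
  spectra (above) is the main accuracy limit of the chain; higher cumulants
  are the documented, unimplemented fix.
- V_cg from raw counts is a density estimator with no kinetic information;
  edges encode structural proximity only.
- The annealer is classical; nothing is claimed about quantum dynamics, and
  the abstract sweep time has no hardware calibration.
- No committor estimation, rate constants, or free-energy reconstruction;
  no minor-embedding or hardware topology handling; no replica exchange or
  adaptive α.
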