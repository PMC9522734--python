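# qtps — transition-path sampling with annealed path proposals

`qtps` samples the **transition path ensemble** of a system with two
metastable states — the set of reactive trajectories connecting them,
weighted by their dynamical probability — using a hybrid Monte Carlo scheme
in which trial paths are generated by an annealer acting on a
quadratic-binary (QUBO/Ising) encoding of the path space.  It is aimed at
molecular-simulation practitioners who have a sparse set of configurations
covering the intrinsic manifold of their system (e.g. from exploratory
sampling) and want reactive pathways and their statistical weights without
collective variables or biasing forces.

## The method

**Coarse-grained action.**  Each configuration Q&#8342; becomes a node of a
graph; structurally close nodes are joined by edges.  Discretised overdamped
Langevin dynamics at resolution σ (the mean distance between neighbouring
configurations) and coarse time step Δt assigns every step i→j a weight

    w_ij = [ m|Q_i − Q_j|² / (2Δt) + V_cg(Q_i)·Δt ] / (2 m D_cg),
    D_cg = σ² / (2Δt),

where V_cg is the effective potential estimated from the local sample
density.  A path I = (i₁,…,i_N) has action S(I) = Σ_k w̄_{i_k i_{k+1}}
(symmetrised weights) and probability P(I) ∝ e^(−S(I)).

**QUBO encoding.**  One bit per node (visited or not) and one bit per edge
(traversed or not).  The Hamiltonian H = α·H_C + H_T combines a constraint
part H_C (anchoring the path at the start node s and the end node t and
conserving flux at every other node; offset so its minimum is exactly 0) with
the target function H_T = Σ w̄_ij·Γ⁽²⁾_ij, whose value on any valid path
equals S(I).  The ground state is therefore the least-action (most probable)
path, and the low-energy spectrum enumerates the path ensemble.

**Hybrid Metropolis chain.**  A simulated annealer (stand-in for quantum
annealing hardware, with an abstract sweep time t_sweep controlling its
effort) proposes fresh, independent paths.  The sweep time itself performs
Brownian dynamics with a harmonic drift toward a target t₀ (the update
t' = t − δt·k·(t − t₀) + √(2δt)·ξ).  Proposals are accepted with

    min[1, (p₀(t')P(t|t'))/(p₀(t)P(t'|t)) · P(I|t)/P(I'|t') · e^(S(I)−S(I'))],

where the annealer response P(I|t) ≈ P(E|t) is a Gaussian calibrated from
repeated anneals (lowest-order cumulant approximation).  The chain then
samples ρ(t_sweep, I) = p₀(t_sweep)·e^(−S(I)) exactly insofar as the
calibrated response describes the annealer, and each accepted path is a
one-shot decorrelated sample.

## Worked example

```sh
python examples/02_sample_path_ensemble.py
```

runs the chain on a four-node fixture with exactly two start-to-end channels
of action 1.0 and 2.0 and prints:

```
chain: 2600 steps, acceptance 0.93, invalid-topology rate 0.001

path ensemble frequencies vs exact e^{-S}/Z:
  path (0, 1, 3) (S=1.0): sampled 0.7275, exact 0.7311
  path (0, 2, 3) (S=2.0): sampled 0.2725, exact 0.2689

path autocorrelation G(N)/G(0) (fresh-anneal proposals decorrelate fast):
  N=0: +1.000  N=1: +0.083  N=2: +0.003  N=3: -0.051  N=4: +0.000  N=5: -0.015
```

The sampled channel frequencies match the analytic Boltzmann weights
e^(−S)/Z of the two paths, and the lag-1 autocorrelation of the sampled
paths is already near zero — every Monte Carlo step draws an independent
anneal, so correlation survives only through rejections.

`examples/01_encode_and_solve.py` shows the encoding and the exhaustive /
annealed solvers on a triangle graph; `examples/03_double_well_pipeline.py`
runs the full pipeline — Langevin sampling of a 2-D double well, graph
construction, QUBO encoding, chain — and reports how close the sampled
transition paths come to the saddle point.

A thin CLI mirrors the library pipeline
(`qtps synth | build-graph | encode | solve | calibrate | mc | analyze`);
run `qtps --help`.

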