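import math

import numpy as np
import pytest
from scipy.integrate import quad

from qtps.cg_graph import CGPath
from qtps.mc import (
    ChainState,
    SweepParams,
    acceptance_probability,
    p0_density,
    propose_tsweep,
    run_chain,
    tsweep_transition_density,
)
from qtps.qubo import PathProblem
from qtps.response import ResponseProfile
from qtps.samplers import AnnealResult
from qtps.synthetic import fixture


def flat_profile(E_bar=0.0, Delta=100.0):
    return ResponseProfile(
        t_grid=np.array([1.0, 400.0]),
        E_bar=np.array([E_bar, E_bar]),
        Delta=np.array([Delta, Delta]),
        n=np.array([10, 10]),
        valid_fraction=np.array([1.0, 1.0]),
    )


def centered_profile(center):
    """Response whose mean sits midway: response factors cancel pairwise."""
    return flat_profile(E_bar=center, Delta=3.0)


class TestSweepParams:
    def test_default_bounds(self):
        p = SweepParams()
        assert p.t_min == pytest.approx(15.0)
        assert p.t_max == pytest.approx(300.0)

    def test_unstable_drift_rejected(self):
        with pytest.raises(ValueError):
            SweepParams(t0=150.0, k=0.5, delta_t=10.0)


class TestProposal:
    def test_t0_is_drift_fixed_point(self):
        p = SweepParams()
        assert p.drift_mean(p.t0) == p.t0

    def test_drift_magnitude(self):
        # delta_t * k = 0.1 * 2e-4: displacement from t0+100 is 100 * 2e-5
        p = SweepParams(t0=150.0, k=2e-4, delta_t=0.1)
        assert p.drift_mean(250.0) == pytest.approx(250.0 - 0.1 * 2e-4 * 100.0)

    def test_deterministic_given_seed(self):
        p = SweepParams()
        a = propose_tsweep(200.0, p, np.random.default_rng(9))
        b = propose_tsweep(200.0, p, np.random.default_rng(9))
        assert a == b

    def test_stays_in_bounds(self):
        p = SweepParams(delta_t=400.0)
        rng = np.random.default_rng(0)
        for _ in range(500):
            t = propose_tsweep(16.0, p, rng)
            assert p.t_min <= t <= p.t_max


class TestTransitionDensity:
    def test_peak_value_far_from_bounds(self):
        p = SweepParams(t0=150.0, k=2e-4, delta_t=1.0)
        mu = p.drift_mean(150.0)
        assert tsweep_transition_density(mu, 150.0, p) == pytest.approx(
            1.0 / math.sqrt(4 * math.pi * p.delta_t), rel=1e-6
        )

    def test_nearly_symmetric_for_tiny_drift(self):
        p = SweepParams(t0=150.0, k=1e-9, delta_t=25.0)
        a = tsweep_transition_density(170.0, 150.0, p)
        b = tsweep_transition_density(150.0, 170.0, p)
        assert a == pytest.approx(b, rel=1e-5)

    def test_integrates_to_one_including_reflection(self):
        p = SweepParams(delta_t=200.0)
        for t_from in (20.0, 150.0, 290.0):
            total, _ = quad(
                lambda t: tsweep_transition_density(t, t_from, p),
                p.t_min, p.t_max, limit=200,
            )
            assert total == pytest.approx(1.0, abs=1e-4)


class TestP0:
    def test_peak_at_t0(self):
        p = SweepParams()
        ts = np.linspace(p.t_min, p.t_max, 401)
        vals = [p0_density(t, p) for t in ts]
        assert ts[int(np.argmax(vals))] == pytest.approx(p.t0, abs=1.0)

    def test_standard_deviation_is_inverse_sqrt_k(self):
        # 1/sqrt(2e-4) ~ 70.7: the density at t0 +/- 70.7 is e^{-1/2} of peak
        p = SweepParams(t_min=1.0, t_max=1000.0)
        sd = math.sqrt(1.0 / p.k)
        assert sd == pytest.approx(70.7, abs=0.1)
        ratio = p0_density(p.t0 + sd, p) / p0_density(p.t0, p)
        assert ratio == pytest.approx(math.exp(-0.5), rel=1e-9)

    def test_integrates_to_one_on_bounds(self):
        p = SweepParams()
        total, _ = quad(lambda t: p0_density(t, p), p.t_min, p.t_max)
        assert total == pytest.approx(1.0, abs=1e-8)


class TestAcceptance:
    def _states(self, s_cur, s_cand, t=150.0):
        cur = ChainState(path=CGPath(nodes=(0, 1), action=s_cur), t_sweep=t)
        cand = ChainState(path=CGPath(nodes=(0, 2), action=s_cand), t_sweep=t)
        return cur, cand

    def test_identity_move_accepted(self):
        cur, _ = self._states(1.0, 1.0)
        p = SweepParams()
        assert acceptance_probability(cur, cur, flat_profile(), p) == 1.0

    def test_uphill_unit_action_is_exp_minus_one(self):
        cur, cand = self._states(1.0, 2.0)
        prof = centered_profile(center=1.5)  # response factors cancel
        a = acceptance_probability(cur, cand, prof, SweepParams())
        assert a == pytest.approx(math.exp(-1.0), rel=1e-9)

    def test_downhill_capped_at_one(self):
        cur, cand = self._states(2.0, 1.0)
        prof = centered_profile(center=1.5)
        assert acceptance_probability(cur, cand, prof, SweepParams()) == 1.0

    def test_invariance_under_constant_action_shift(self):
        prof = flat_profile(E_bar=0.0, Delta=1e6)
        p = SweepParams()
        a1 = acceptance_probability(*self._states(1.0, 2.3), profile=prof, params=p)
        a2 = acceptance_probability(*self._states(11.0, 12.3), profile=prof, params=p)
        assert a1 == pytest.approx(a2, rel=1e-6)


def constant_path_sampler(problem):
    """Stub backend: always proposes the unique line-graph path."""
    from qtps.cg_graph import path_action

    nodes = (0, 1, 2)
    path = CGPath(nodes=nodes, action=path_action(problem.graph, nodes))

    def sampler(t_sweep, seed):
        return AnnealResult(configuration=None, energy=path.action,
                            valid_topology=True, decoded=path)

    return sampler


class TestRunChain:
    def test_zero_steps_returns_initial_state_only(self):
        g, s, t = fixture("line3")
        prob = PathProblem(graph=g, s=s, t=t)
        sampler = constant_path_sampler(prob)
        from qtps.response import calibrate

        prof = calibrate(sampler, [15.0, 300.0], n_reps=4, seed=0)
        rec = run_chain(prob, sampler, prof, SweepParams(), n_steps=0, seed=1)
        assert len(rec.states) == 1
        assert rec.rows[0]["step"] == 0

    def test_bit_reproducible_from_seed(self):
        from qtps.experiments import fixture_chain

        _, _, a = fixture_chain("two_channel", n_steps=40, seed=11, calibration_reps=20)
        _, _, b = fixture_chain("two_channel", n_steps=40, seed=11, calibration_reps=20)
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_frozen_time_flat_action_accepts_everything(self):
        """With constant action and a frozen sweep time the ratio is 1."""
        g, s, t = fixture("line3")
        prob = PathProblem(graph=g, s=s, t=t)
        sampler = constant_path_sampler(prob)
        from qtps.response import calibrate

        prof = calibrate(sampler, [15.0, 300.0], n_reps=4, seed=0)
        params = SweepParams(delta_t=1e-9)  # effectively frozen t
        rec = run_chain(prob, sampler, prof, params, n_steps=200, seed=2)
        assert rec.acceptance_rate == 1.0

    def test_no_valid_initial_path_raises(self):
        g, s, t = fixture("line3")
        prob = PathProblem(graph=g, s=s, t=t)

        def never_valid(t_sweep, seed):
            return AnnealResult(configuration=None, energy=0.0,
                                valid_topology=False, decoded=None)

        prof = flat_profile()
        with pytest.raises(RuntimeError, match="no valid initial path"):
            run_chain(prob, never_valid, prof, SweepParams(), n_steps=1, seed=0,
                      init_budget=10)

    def test_sweep_time_marginal_matches_p0_for_constant_action(self):
        """KS test against the truncated-normal stationary law of the
        drift-diffusion sweep-time dynamics, using a constant-action stub."""
        from scipy.stats import kstest, truncnorm

        g, s, t = fixture("line3")
        prob = PathProblem(graph=g, s=s, t=t)
        sampler = constant_path_sampler(prob)
        from qtps.response import calibrate

        prof = calibrate(sampler, [15.0, 300.0], n_reps=4, seed=0)
        params = SweepParams(delta_t=500.0)
        rec = run_chain(prob, sampler, prof, params, n_steps=20_000, seed=3)
        ts = rec.tsweep_series(burn_in=0.1)[::25]
        sd = math.sqrt(1.0 / params.k)
        a = (params.t_min - params.t0) / sd
        b = (params.t_max - params.t0) / sd
        stat = kstest(ts, truncnorm(a, b, loc=params.t0, scale=sd).cdf)
        assert stat.pvalue > 0.01
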