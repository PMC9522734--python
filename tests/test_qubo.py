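import itertools

import numpy as np
import pytest

from qtps.analysis import dijkstra_path, enumerate_simple_paths
from qtps.cg_graph import path_action
from qtps.qubo import (
    BinaryConfiguration,
    Invalid,
    PathProblem,
    QuadraticModel,
    assemble,
    build_constraint,
    build_target,
    decode,
    encode_path,
    node_var,
    to_ising,
)
from qtps.synthetic import fixture

from helpers import random_connected_graph


def all_configurations(model):
    n = len(model.variables)
    for bits in itertools.product((0, 1), repeat=n):
        yield np.asarray(bits)


def problem(name, **kw):
    g, s, t = fixture(name)
    return PathProblem(graph=g, s=s, t=t, **kw)


class TestConstraint:
    def test_valid_path_sits_at_offset_zero(self):
        p = problem("line3")
        hc = build_constraint(p)
        assert hc.energy(encode_path(p, (0, 1, 2))) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_configuration_costs_two(self):
        p = problem("line3")
        hc = build_constraint(p)
        assert hc.energy(np.zeros(len(hc.variables))) == pytest.approx(2.0)

    def test_isolated_start_bit_costs_two(self):
        # Gamma1[s]=1 with no incident edge: H_s = -1 + 1 = 0, offset 2
        p = problem("line3")
        hc = build_constraint(p)
        conf = BinaryConfiguration(
            gamma1={0: 1, 1: 0, 2: 0}, gamma2={(0, 1): 0, (1, 2): 0}
        )
        assert hc.energy(conf) == pytest.approx(2.0)

    @pytest.mark.parametrize("name", ["line3", "triangle", "two_channel", "subtour5"])
    def test_floor_is_zero_exactly_on_flux_conserving_subgraphs(self, name):
        """Exhaustive: min H_C = 0, attained iff degrees match an s-t flux."""
        p = problem(name)
        hc = build_constraint(p)
        g = p.graph
        edge_keys = g.edge_keys()
        min_e = np.inf
        for x in all_configurations(hc):
            e = hc.energy(x)
            min_e = min(min_e, e)
            conf = BinaryConfiguration.from_vector(hc.variables, x)
            deg = {i: 0 for i in g.node_ids}
            for (i, j), b in conf.gamma2.items():
                deg[i] += b
                deg[j] += b
            flux_ok = all(
                (deg[i] == 1 and conf.gamma1[i] == 1)
                if i in (p.s, p.t)
                else deg[i] == 2 * conf.gamma1[i]
                for i in g.node_ids
            )
            assert (abs(e) < 1e-12) == flux_ok
        assert min_e == pytest.approx(0.0, abs=1e-12)

    def test_subtour_attains_floor_but_decode_rejects(self):
        p = problem("subtour5")
        hc = build_constraint(p)
        conf = BinaryConfiguration(
            gamma1={i: 1 for i in range(5)},
            gamma2={(0, 1): 1, (2, 3): 1, (2, 4): 1, (3, 4): 1},
        )
        assert hc.energy(conf) == pytest.approx(0.0, abs=1e-12)
        d = decode(p, conf)
        assert isinstance(d, Invalid) and d.reason == "subtour_present"


class TestTarget:
    def test_empty_configuration_is_zero(self):
        p = problem("line3")
        ht = build_target(p)
        assert ht.energy(np.zeros(len(ht.variables))) == 0.0

    def test_path_energy_equals_action(self):
        p = problem("line3")
        ht = build_target(p)
        conf = encode_path(p, (0, 1, 2))
        assert ht.energy(conf) == pytest.approx(path_action(p.graph, (0, 1, 2)))

    def test_linearity_in_edge_bits(self):
        p = problem("two_channel")
        ht = build_target(p)
        base = encode_path(p, (0, 1, 3))
        extra = BinaryConfiguration(
            gamma1=dict(base.gamma1), gamma2=dict(base.gamma2)
        )
        extra.gamma2[(0, 2)] = 1
        w = p.graph.edge(0, 2).w_sym
        assert ht.energy(extra) - ht.energy(base) == pytest.approx(w)


class TestAssemble:
    @pytest.mark.parametrize("name", ["line3", "triangle", "two_channel", "ladder8"])
    def test_energy_identity_on_all_simple_paths(self, name):
        g, s, t = fixture(name)
        p = PathProblem(graph=g, s=s, t=t)
        model = assemble(p)
        for path in enumerate_simple_paths(g, s, t):
            e = model.energy(encode_path(p, path.nodes))
            assert e == pytest.approx(path.action, rel=1e-12, abs=1e-12)

    def test_all_zero_costs_two_alpha(self):
        p = problem("line3", alpha=4.0)
        model = assemble(p)
        assert model.energy(np.zeros(len(model.variables))) == pytest.approx(8.0)

    def test_constraint_gap_linear_in_alpha(self):
        bad = BinaryConfiguration(
            gamma1={0: 1, 1: 0, 2: 0}, gamma2={(0, 1): 0, (1, 2): 0}
        )
        gaps = []
        for alpha in (1.0, 2.0):
            p = problem("line3", alpha=alpha)
            model, ht = assemble(p), build_target(p)
            good = encode_path(p, (0, 1, 2))
            # constraint part = full energy minus the target part
            c_bad = model.energy(bad) - ht.energy(bad)
            c_good = model.energy(good) - ht.energy(good)
            gaps.append(c_bad - c_good)
        assert gaps[1] == pytest.approx(2.0 * gaps[0])

    def test_default_alpha_is_total_weight(self):
        p = problem("two_channel")
        assert p.alpha_value == pytest.approx(3.0)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            problem("line3", alpha=-1.0)

    def test_qubit_count_is_nodes_plus_edges(self):
        p = problem("ladder8")
        assert p.n_qubits == 8 + 10


class TestIsing:
    def test_single_linear_term(self):
        m = QuadraticModel(variables=[node_var(0)])
        m.add_linear(node_var(0), 3.0)
        ising = to_ising(m)
        assert ising.h[node_var(0)] == pytest.approx(1.5)
        assert ising.offset == pytest.approx(1.5)

    def test_zero_model_maps_to_zero(self):
        m = QuadraticModel(variables=[node_var(0), node_var(1)])
        ising = to_ising(m)
        assert not ising.h and not ising.J and ising.offset == 0.0

    def test_exhaustive_equivalence_random_8bit(self):
        rng = np.random.default_rng(42)
        variables = [node_var(i) for i in range(8)]
        m = QuadraticModel(variables=variables)
        for v in variables:
            m.add_linear(v, float(rng.normal()))
        for u, v in itertools.combinations(variables, 2):
            if rng.random() < 0.5:
                m.add_quadratic(u, v, float(rng.normal()))
        m.offset = float(rng.normal())
        ising = to_ising(m)
        for x in all_configurations(m):
            assert ising.energy(2 * x - 1) == pytest.approx(m.energy(x), rel=1e-12, abs=1e-12)


class TestEncodeDecode:
    def test_line_graph_bits(self):
        p = problem("line3")
        conf = encode_path(p, (0, 1, 2))
        assert conf.gamma1 == {0: 1, 1: 1, 2: 1}
        assert conf.gamma2 == {(0, 1): 1, (1, 2): 1}

    def test_direct_edge_in_triangle(self):
        p = problem("triangle")
        conf = encode_path(p, (0, 2))
        assert conf.gamma1[1] == 0
        assert conf.gamma2 == {(0, 1): 0, (0, 2): 1, (1, 2): 0}

    @pytest.mark.parametrize("name", ["line3", "triangle", "two_channel", "ladder8"])
    def test_round_trip_identity(self, name):
        g, s, t = fixture(name)
        p = PathProblem(graph=g, s=s, t=t)
        for path in enumerate_simple_paths(g, s, t):
            out = decode(p, encode_path(p, path.nodes))
            assert out.nodes == path.nodes

    def test_encode_rejects_wrong_endpoints(self):
        p = problem("two_channel")
        with pytest.raises(ValueError):
            encode_path(p, (1, 3))

    def test_node_bit_without_edges_is_mismatch(self):
        p = problem("triangle")
        conf = encode_path(p, (0, 2))
        conf.gamma1[1] = 1
        d = decode(p, conf)
        assert isinstance(d, Invalid) and d.reason == "node_edge_mismatch"

    def test_missing_endpoint_degree_is_broken_flux(self):
        p = problem("line3")
        conf = BinaryConfiguration(
            gamma1={0: 1, 1: 1, 2: 0}, gamma2={(0, 1): 1, (1, 2): 1}
        )
        d = decode(p, conf)
        assert isinstance(d, Invalid) and d.reason == "node_edge_mismatch"

    def test_dangling_interior_is_broken_flux(self):
        p = problem("line3")
        conf = BinaryConfiguration(
            gamma1={0: 1, 1: 1, 2: 0}, gamma2={(0, 1): 1, (1, 2): 0}
        )
        d = decode(p, conf)
        assert isinstance(d, Invalid) and d.reason == "broken_flux"


class TestGroundStateOracle:
    def test_ground_state_matches_dijkstra_on_random_graphs(self):
        from qtps.samplers import exact_ground_state

        rng = np.random.default_rng(7)
        for trial in range(8):
            n = int(rng.integers(4, 8))
            g = random_connected_graph(rng, n)
            p = PathProblem(graph=g, s=0, t=n - 1)
            res = exact_ground_state(assemble(p), p)
            assert res.valid_topology
            best = dijkstra_path(g, 0, n - 1)
            assert res.decoded.action == pytest.approx(best.action, rel=1e-9)
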