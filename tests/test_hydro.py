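"""Kirchhoff flow, the fluctuating-sink ensemble, and dissipation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import venanet as vn


class TestSinkEnsemble:
    def test_full_fluctuation_concentrates_the_sink(self):
        # sigma = 1: s_k = -1 and every other sink entry vanishes,
        # independent of the drainage areas
        ens = vn.SinkEnsemble(areas=np.array([1.0, 5.0, 2.0, 3.0]), source=0, sigma=1.0)
        s = ens.member(2)
        assert s[2] == pytest.approx(-1.0)
        assert s[0] == 1.0
        assert s[1] == pytest.approx(0.0) and s[3] == pytest.approx(0.0)

    def test_no_fluctuation_equal_areas_is_uniform(self):
        ens = vn.SinkEnsemble(areas=np.ones(5), source=0, sigma=0.0)
        s = ens.member(3)
        np.testing.assert_allclose(s[1:], -0.25)

    def test_hand_computed_member(self):
        # source + sinks with areas (1, 2, 3), sigma = 1/2, moving sink on
        # the area-2 node: s_avg = 1/6, C(k) = 1/2
        ens = vn.SinkEnsemble(
            areas=np.array([1.0, 1.0, 2.0, 3.0]), source=0, sigma=0.5
        )
        s = ens.member(2)
        np.testing.assert_allclose(s, [1.0, -1 / 12, -2 / 3, -1 / 4])
        assert s.sum() == pytest.approx(0.0, abs=1e-15)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 40),
        sigma=st.floats(0.0, 1.0),
        seed=st.integers(0, 10_000),
    )
    def test_every_member_is_balanced(self, n, sigma, seed):
        rng = np.random.default_rng(seed)
        areas = rng.uniform(0.1, 10.0, n)
        source = int(rng.integers(0, n))
        ens = vn.SinkEnsemble(areas=areas, source=source, sigma=sigma)
        S = ens.matrix()
        assert np.abs(S.sum(axis=0)).max() < 1e-12
        assert np.all(S[source] == 1.0)
        sinks = np.delete(np.arange(n), source)
        assert np.all(S[sinks] <= 0)

    def test_member_matches_matrix_column(self):
        ens = vn.SinkEnsemble(areas=np.array([1.0, 2.0, 3.0, 4.0]), source=1, sigma=0.3)
        S = ens.matrix()
        for j, k in enumerate(ens.sinks):
            np.testing.assert_allclose(ens.member(int(k)), S[:, j])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            vn.SinkEnsemble(areas=np.ones(3), source=0, sigma=1.5)
        ens = vn.SinkEnsemble(areas=np.ones(3), source=0, sigma=0.5)
        with pytest.raises(ValueError, match="source"):
            ens.member(0)


class TestSolveFlow:
    def test_single_resistor(self, two_node):
        sol = vn.solve_flow(two_node, np.array([2.0]), np.array([1.0, -1.0]))
        assert sol.fluxes[0] == pytest.approx(1.0)
        dp = sol.pressures[0] - sol.pressures[1]
        assert dp == pytest.approx(0.5)  # f = c_eff * dp with c_eff = 2

    def test_symmetric_y_splits_evenly(self, star4):
        c = np.ones(3)
        s = np.array([1.0, -0.5, -0.25, -0.25])
        sol = vn.solve_flow(star4, c, s)
        assert sol.fluxes[1] == pytest.approx(sol.fluxes[2])

    def test_matches_dense_pseudo_inverse(self, grid5):
        g = grid5
        s = np.full(g.n_nodes, -1.0 / (g.n_nodes - 1))
        s[g.source] = 1.0
        sol = vn.solve_flow(g, g.conductivities, s)
        B = g.incidence().toarray()
        c_eff = g.conductivities / g.lengths
        A = B @ np.diag(c_eff) @ B.T
        f_oracle = np.diag(c_eff) @ B.T @ np.linalg.pinv(A) @ s
        np.testing.assert_allclose(sol.fluxes, f_oracle, atol=1e-8)

    def test_conservation_contract(self, grid5):
        g = grid5
        rng = np.random.default_rng(3)
        s = rng.normal(size=g.n_nodes)
        s -= s.mean()
        sol = vn.solve_flow(g, g.conductivities, s)
        B = g.incidence()
        assert np.abs(B @ sol.fluxes - s).max() <= 1e-9 * np.abs(s).max()

    def test_gauge_invariance_of_fluxes(self, grid5):
        g = grid5
        s = np.zeros(g.n_nodes)
        s[0], s[-1] = 1.0, -1.0
        solver = vn.FlowSolver(g, g.conductivities)
        p = solver.pressures(s)
        f = solver.fluxes(s)
        f_shifted = solver.c_eff * (solver.B.T @ (p + 42.0))
        np.testing.assert_allclose(f, f_shifted, atol=1e-12)

    def test_linearity_in_the_load(self, grid5):
        g = grid5
        s = np.zeros(g.n_nodes)
        s[0], s[-1] = 1.0, -1.0
        solver = vn.FlowSolver(g, g.conductivities)
        np.testing.assert_allclose(
            solver.fluxes(3.5 * s), 3.5 * solver.fluxes(s), rtol=1e-12
        )

    def test_unbalanced_load_rejected(self, two_node):
        with pytest.raises(ValueError, match="balanced"):
            vn.solve_flow(two_node, np.array([1.0]), np.array([1.0, -0.5]))

    def test_disconnected_positive_conductance_rejected(self, make_graph):
        g = make_graph([[0, 0], [1, 0], [2, 0]], [[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            vn.solve_flow(g, np.array([1.0, 0.0]), np.array([1.0, 0.0, -1.0]))


class TestEnsembleSecondMoment:
    def test_sigma0_degenerate_ensemble(self, star4):
        c = np.ones(3)
        ens = vn.SinkEnsemble.from_graph(star4, 0.0)
        f2 = vn.ensemble_second_moment(star4, c, ens)
        s = ens.member(int(ens.sinks[0]))
        sol = vn.solve_flow(star4, c, s, floor=1e-18)
        np.testing.assert_allclose(f2, sol.fluxes**2, rtol=1e-10)

    def test_sigma1_star_member_enumeration(self, star4):
        # sigma = 1 on a star: member k sends the full unit flux down
        # spoke k only, so <f^2> = 1/3 on every spoke
        c = np.ones(3)
        ens = vn.SinkEnsemble.from_graph(star4, 1.0)
        f2 = vn.ensemble_second_moment(star4, c, ens)
        np.testing.assert_allclose(f2, 1.0 / 3.0, rtol=1e-10)

    def test_equals_explicit_member_loop(self, grid5):
        g = grid5
        ens = vn.SinkEnsemble.from_graph(g, 0.4)
        f2 = vn.ensemble_second_moment(g, g.conductivities, ens)
        acc = np.zeros(g.n_edges)
        for k in ens.sinks:
            sol = vn.solve_flow(g, g.conductivities, ens.member(int(k)), floor=1e-18)
            acc += sol.fluxes**2
        np.testing.assert_allclose(f2, acc / len(ens.sinks), rtol=1e-9)

    def test_direction_fractions_bounded(self, grid5):
        g = grid5
        ens = vn.SinkEnsemble.from_graph(g, 0.8)
        _, frac = vn.ensemble_second_moment(
            g, g.conductivities, ens, return_direction_fractions=True
        )
        assert np.all((frac >= 0) & (frac <= 1))


class TestDissipatedPower:
    def test_single_edge(self):
        assert vn.dissipated_power(np.array([2.0]), np.array([1.0])) == pytest.approx(0.5)

    def test_series_additivity(self):
        p1 = vn.dissipated_power(np.array([1.0]), np.array([1.0]))
        p2 = vn.dissipated_power(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert p2 == pytest.approx(2 * p1)

    def test_parallel_split_halves_dissipation(self):
        # unit current through one branch vs split over two equal branches
        single = vn.dissipated_power(np.array([1.0]), np.array([1.0]))
        split = vn.dissipated_power(np.array([1.0, 1.0]), np.array([0.5, 0.5]))
        assert split == pytest.approx(single / 2)

    def test_flux_on_dead_edge_rejected(self):
        with pytest.raises(ValueError, match="zero-conductance"):
            vn.dissipated_power(np.array([1.0, 0.0]), np.array([1.0, 0.5]))

    def test_dead_edge_contributes_nothing(self):
        assert vn.dissipated_power(
            np.array([1.0, 0.0]), np.array([1.0, 0.0])
        ) == pytest.approx(1.0)
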