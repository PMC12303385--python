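"""Reticulate Murray's law: direction-resolved sums, α fitting, residuals."""

import numpy as np
import pytest

import venanet as vn
from venanet.murray import _parabolic_vertex, gaussian_smoothed_residuals


@pytest.fixture
def leak_free_y(make_graph):
    """Y-junction obeying the classical law by construction.

    Daughters of width 1 each carrying half the flux; parent width 2^(1/3)
    so that w_p³ = w_d1³ + w_d2³.  The junction's own sink is made
    negligible, so the flow is effectively leak-free.
    """
    wp = 2.0 ** (1.0 / 3.0)
    g = make_graph(
        [[0, 0], [1, 0], [2, 1], [2, -1]],
        [[0, 1], [1, 2], [1, 3]],
        widths=[wp, 1.0, 1.0],
        source=0,
        areas=[1.0, 1e-9, 1.0, 1.0],
    )
    return g


class TestMurraySums:
    def test_leak_free_y_balances_at_alpha_3(self, leak_free_y):
        ma = vn.MurrayAnalysis(leak_free_y, leak_free_y.widths, sigma=0.0)
        t = ma.sums(3.0)
        assert len(t.branch_nodes) == 1
        assert t.r_in[0] == pytest.approx(t.r_out[0], abs=1e-8)
        assert ma.loss(3.0) <= 1e-15

    def test_leak_free_y_fits_alpha_3(self, leak_free_y):
        fit = vn.fit_alpha(leak_free_y, leak_free_y.widths, sigma=0.0)
        assert not fit.bracket_failure
        assert fit.alpha_star == pytest.approx(3.0, abs=1e-3)

    def test_homogeneity_in_width_scale(self, leak_free_y):
        ma1 = vn.MurrayAnalysis(leak_free_y, leak_free_y.widths, sigma=0.0)
        ma2 = vn.MurrayAnalysis(leak_free_y, 2 * leak_free_y.widths, sigma=0.0)
        a = 2.7
        t1, t2 = ma1.sums(a), ma2.sums(a)
        np.testing.assert_allclose(t2.r_in, 2**a * t1.r_in, rtol=1e-12)
        np.testing.assert_allclose(t2.r_out, 2**a * t1.r_out, rtol=1e-12)

    def test_radii_versus_widths_scales_loss_exactly(self, leak_free_y):
        # evaluating with widths instead of radii multiplies both sums by
        # 2^alpha and the loss by 2^(2 alpha) at every alpha
        g = leak_free_y
        ma_r = vn.MurrayAnalysis(g, g.widths, sigma=0.0, use_radii=True)
        ma_w = vn.MurrayAnalysis(g, g.widths, sigma=0.0, use_radii=False)
        alphas = np.array([2.0, 2.5, 3.0, 3.5])
        np.testing.assert_allclose(
            ma_w.loss_curve(alphas),
            4.0**alphas * ma_r.loss_curve(alphas),
            rtol=1e-9,
        )


class TestDirectionIndicators:
    def test_tree_flow_never_reverses(self, star4):
        # on a tree every edge either carries flow away from the source
        # or nothing at all, whatever the moving-sink position: the "in"
        # class at the source hub stays empty across all members
        g = star4
        ma = vn.MurrayAnalysis(g, np.ones(3), sigma=1.0, conductivities=np.ones(3))
        inc, I_in, I_out = ma.direction_indicators(0)
        assert I_in.shape == (3, 3)
        assert not I_in.any()
        # member k uses spoke k only; the other spokes are flux-free
        assert np.all(I_out.sum(axis=0) == 1)

    def test_cycle_edge_flips_direction_across_members(self, loop_with_stubs):
        # moving the concentrated sink between D and E reverses the flow
        # on the cycle edge B-D at branch node B
        g = loop_with_stubs
        ma = vn.MurrayAnalysis(
            g, np.ones(g.n_edges), sigma=1.0, conductivities=np.ones(g.n_edges)
        )
        b = 2  # node B
        inc, I_in, I_out = ma.direction_indicators(b)
        edge_bd = int(np.flatnonzero(inc == 3)[0])  # edge index 3 is B-D
        assert I_in[edge_bd].any() and I_out[edge_bd].any()

    def test_member_out_term_counts_can_differ(self, loop_with_stubs):
        # the number of outgoing terms varies with the sink position
        g = loop_with_stubs
        ma = vn.MurrayAnalysis(
            g, np.ones(g.n_edges), sigma=1.0, conductivities=np.ones(g.n_edges)
        )
        _, _, I_out = ma.direction_indicators(2)
        n_out = I_out.sum(axis=0)
        assert n_out.min() != n_out.max()

    def test_non_branch_node_rejected(self, loop_with_stubs):
        ma = vn.MurrayAnalysis(
            loop_with_stubs,
            np.ones(loop_with_stubs.n_edges),
            sigma=0.5,
            conductivities=np.ones(loop_with_stubs.n_edges),
        )
        with pytest.raises(ValueError, match="branch"):
            ma.direction_indicators(4)


class TestConvergedTreeResiduals:
    def test_residuals_all_negative_at_alpha_3(self, sigma0_murray):
        t = sigma0_murray.sums(3.0)
        assert np.all(t.residuals < 0)

    def test_sink_area_correction_cancels_residuals(self, sigma0_murray):
        # at the fixed point w³ ∝ |f| and conservation leaves exactly the
        # node's own sink: residual_b = −κ a_b with one global κ > 0
        corrected, kappa, table = sigma0_murray.sink_corrected_residuals(3.0)
        assert kappa > 0
        assert np.abs(corrected).max() <= 1e-6 * np.abs(table.residuals).mean()

    def test_loss_has_interior_minimum_near_3(self, sigma0_murray):
        fit = sigma0_murray.fit_alpha()
        assert not fit.bracket_failure
        assert 2.7 <= fit.alpha_star <= 3.2

    def test_alpha_invariant_under_relabeling(self, leaf_lattice, sigma0_run):
        g = leaf_lattice
        fit0 = vn.MurrayAnalysis(
            g, sigma0_run.widths, 0.0, conductivities=sigma0_run.conductivities
        ).fit_alpha()
        rng = np.random.default_rng(5)
        perm = rng.permutation(g.n_nodes)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(g.n_nodes)
        eperm = rng.permutation(g.n_edges)
        g2 = vn.VenationGraph(
            coords=g.coords[perm],
            edges=inv[g.edges[eperm]],
            lengths=g.lengths[eperm],
            widths=g.widths[eperm],
            source=int(inv[g.source]),
            areas=g.areas[perm],
        )
        fit2 = vn.MurrayAnalysis(
            g2,
            sigma0_run.widths[eperm],
            0.0,
            conductivities=sigma0_run.conductivities[eperm],
        ).fit_alpha()
        assert fit2.alpha_star == pytest.approx(fit0.alpha_star, abs=1e-9)


class TestLossProperties:
    def test_loss_nonnegative_and_smooth_on_grid(self, sigma0_murray):
        alphas = np.arange(2.0, 4.01, 0.05)
        L = sigma0_murray.loss_curve(alphas)
        assert np.all(L >= 0)
        # no wild jumps between adjacent grid points
        rel_jump = np.abs(np.diff(np.log(L + 1e-300)))
        assert rel_jump.max() < 1.0

    def test_parabolic_vertex_recovers_quadratic_minimum(self):
        x = np.array([1.0, 1.5, 2.0])
        y = (x - 1.37) ** 2 + 0.2
        assert _parabolic_vertex(x, y) == pytest.approx(1.37, abs=1e-12)

    def test_gaussian_smoothing_recovers_constant_residuals(self):
        w = np.logspace(-1, 1, 200)
        r = np.full(200, -0.3)
        grid, mean, sd = gaussian_smoothed_residuals(w, r)
        np.testing.assert_allclose(mean, -0.3, atol=1e-12)
        np.testing.assert_allclose(sd, 0.0, atol=1e-6)
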