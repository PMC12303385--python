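"""Shared fixtures: tiny hand-built graphs and session-scoped model runs.

The expensive optimizations (the ~500-node leaf lattice at σ = 0 and at
σ = 0.094) are computed once per session and shared by all tests that
examine their output.
"""

import numpy as np
import pytest

import venanet as vn


def _graph(coords, edges, widths=None, source=0, areas=None):
    coords = np.asarray(coords, float)
    edges = np.asarray(edges, int)
    lengths = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    if widths is None:
        widths = np.ones(len(edges))
    return vn.VenationGraph(
        coords=coords,
        edges=edges,
        lengths=lengths,
        widths=widths,
        source=source,
        areas=areas,
    )


@pytest.fixture
def make_graph():
    return _graph


@pytest.fixture
def two_node():
    return _graph([[0, 0], [1, 0]], [[0, 1]], areas=[1.0, 1.0])


@pytest.fixture
def triangle():
    return _graph([[0, 0], [1, 0], [0, 1]], [[0, 1], [1, 2], [2, 0]])


@pytest.fixture
def path9():
    """Path of 9 nodes, source at one end, equal drainage areas."""
    coords = [[i, 0] for i in range(9)]
    edges = [[i, i + 1] for i in range(8)]
    return _graph(coords, edges, source=0, areas=np.ones(9))


@pytest.fixture
def star4():
    """Source at the hub, three leaves with equal areas."""
    coords = [[0, 0], [1, 0], [-0.5, 0.9], [-0.5, -0.9]]
    edges = [[0, 1], [0, 2], [0, 3]]
    return _graph(coords, edges, source=0, areas=np.ones(4))


@pytest.fixture
def loop_with_stubs():
    """Source stub S-A, cycle A-B-D-C-A, sink stub B-E.

    At branch node B the cycle edge B-D reverses direction depending on
    whether the moving sink sits at D or at E.
    """
    coords = [[-1, 0], [0, 0], [1, 1], [1, -1], [2, 0], [0.9, 2]]
    #          S       A       B       C       D       E
    edges = [[0, 1], [1, 2], [1, 3], [2, 4], [3, 4], [2, 5]]
    return _graph(coords, edges, source=0, areas=np.ones(6))


@pytest.fixture
def grid5():
    """5x5 grid graph with random conductances (seed 0)."""
    n = 5
    coords = [[i, j] for j in range(n) for i in range(n)]
    edges = []
    for j in range(n):
        for i in range(n):
            k = j * n + i
            if i < n - 1:
                edges.append([k, k + 1])
            if j < n - 1:
                edges.append([k, k + n])
    g = _graph(coords, edges, source=0, areas=np.ones(n * n))
    rng = np.random.default_rng(0)
    g.conductivities = rng.uniform(0.5, 2.0, size=g.n_edges)
    return g


# -- session-scoped leaf-lattice model runs -----------------------------


@pytest.fixture(scope="session")
def leaf_lattice():
    """~500-node jittered triangular lattice on a 2x1 elliptical lamina."""
    shape = vn.LeafShape(length=2.0, width=1.0, spacing=0.06, jitter=0.2, seed=0)
    return vn.generate_leaf_lattice(shape)


@pytest.fixture(scope="session")
def sigma0_run(leaf_lattice):
    """Converged conductivity optimization at sigma=0, gamma=1/2."""
    return vn.optimize_conductivities(leaf_lattice, vn.OptimizerConfig(sigma=0.0))


@pytest.fixture(scope="session")
def sigma0_murray(leaf_lattice, sigma0_run):
    return vn.MurrayAnalysis(
        leaf_lattice,
        sigma0_run.widths,
        0.0,
        conductivities=sigma0_run.conductivities,
    )


@pytest.fixture(scope="session")
def sigma_fluct_run(leaf_lattice):
    """Converged optimization at a small realistic amplitude, sigma=0.094.

    Run at a tight tolerance so fixed-point identities can be checked to
    1e-6 on the converged state.
    """
    return vn.optimize_conductivities(
        leaf_lattice, vn.OptimizerConfig(sigma=0.094, tol=1e-9)
    )


@pytest.fixture(scope="session")
def small_lattice():
    """~230-node lattice for subsystem and recovery experiments."""
    shape = vn.LeafShape(length=2.0, width=1.0, spacing=0.09, jitter=0.2, seed=0)
    return vn.generate_leaf_lattice(shape)
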