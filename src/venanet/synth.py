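"""Synthetic leaf networks, pseudo-data, and rendered masks.

Real venation graphs come out of leaf images: irregular node placement,
heterogeneous drainage areas, a hierarchy of widths, and abundant loops.
This module emulates those features at desk scale so every stage of the
pipeline can be exercised against known ground truth:

* :func:`generate_leaf_lattice` — a jittered triangular lattice clipped
  to an elliptical lamina, with the petiole appended at the base.  A
  triangular (rather than square) lattice is used so the input is loopy
  and rich in degree > 2 branch nodes, like a reticulate leaf.
* :func:`make_pseudo_data` — "observed" widths manufactured by the model
  itself at a known σ*, optionally corrupted with multiplicative
  lognormal noise; used for parameter-recovery experiments.
* :func:`render_mask` — rasterize a graph back into a binary vein mask
  for extraction round-trips.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import shapely
from shapely.geometry import Polygon
from scipy.spatial import Delaunay

from .extract import drainage_areas
from .graph import VenationGraph
from .optimize import OptimizerConfig, optimize_conductivities


@dataclass
class LeafShape:
    """Parametric lamina: an ellipse of length L and width W.

    spacing : target lattice constant h (same length units as L, W).
    jitter : positional jitter amplitude as a fraction of h (uniform in
        each coordinate); emulates the non-uniform node placement of
        image-extracted networks.
    seed : RNG seed for jitter and width perturbations.
    """

    length: float = 2.0
    width: float = 1.0
    spacing: float = 0.08
    jitter: float = 0.2
    seed: int = 0

    def boundary(self, n_vertices: int = 256) -> Polygon:
        t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        x = 0.5 * self.length * np.cos(t)
        y = 0.5 * self.width * np.sin(t)
        return Polygon(np.column_stack([x, y]))

    @property
    def petiole(self) -> tuple[float, float]:
        """Base of the leaf: the lamina attaches to the stalk at (−L/2, 0)."""
        return (-0.5 * self.length, 0.0)


def generate_leaf_lattice(
    shape: LeafShape,
    base_width: float = 1.0,
    width_perturbation: float = 0.01,
    fill_areas: bool = True,
) -> VenationGraph:
    """Loopy leaf-shaped lattice with near-uniform perturbed widths.

    Triangular lattice points inside the lamina are jittered by
    ``±jitter·h`` per coordinate (points jittered outside are dropped);
    edges come from the Delaunay triangulation, keeping only short links
    (< 1.7 h) so the lattice stays local.  The petiole node is placed at
    the leaf base and connected through its Delaunay neighbors.  Initial
    widths are ``base_width · (1 + ε u)`` with u ~ Uniform(−1, 1) — the
    small perturbations that select a local optimum.  Drainage areas are
    filled from the boundary-clipped Voronoi tessellation.
    """
    h = shape.spacing
    if h <= 0:
        raise ValueError("lattice spacing must be positive")
    rng = np.random.default_rng(shape.seed)
    a, b = 0.5 * shape.length, 0.5 * shape.width
    dy = h * np.sqrt(3) / 2
    ys = np.arange(-b, b + dy, dy)
    pts = []
    for row, y in enumerate(ys):
        off = 0.5 * h if row % 2 else 0.0
        xs = np.arange(-a - off, a + h, h) + off
        for x in xs:
            pts.append((x, y))
    pts = np.asarray(pts)
    jit = rng.uniform(-shape.jitter * h, shape.jitter * h, size=pts.shape)
    pts = pts + jit
    inside = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 < 1.0
    pts = pts[inside]
    if len(pts) < 20:
        raise ValueError("lattice spacing too coarse for this lamina")

    petiole = np.asarray(shape.petiole)
    coords = np.vstack([pts, petiole])
    source = len(coords) - 1

    tri = Delaunay(coords)
    edge_set = set()
    for simplex in tri.simplices:
        for i in range(3):
            u, v = int(simplex[i]), int(simplex[(i + 1) % 3])
            edge_set.add((min(u, v), max(u, v)))
    edges = np.array(sorted(edge_set), np.int64)
    lengths = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    keep = lengths < 1.7 * h
    # always keep the petiole connected through its shortest links
    pet_edges = (edges[:, 0] == source) | (edges[:, 1] == source)
    if not (keep & pet_edges).any():
        nearest = np.argsort(lengths + np.where(pet_edges, 0, np.inf))[:3]
        keep[nearest] = True
    edges, lengths = edges[keep], lengths[keep]

    u = rng.uniform(-1.0, 1.0, size=len(edges))
    widths = base_width * (1.0 + width_perturbation * u)

    g = VenationGraph(
        coords=coords, edges=edges, lengths=lengths, widths=widths, source=source
    )
    if not g.is_connected():
        # drop nodes not reachable from the petiole (stray boundary slivers)
        import scipy.sparse as sp

        adj = sp.coo_matrix(
            (np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
            shape=(len(coords), len(coords)),
        )
        _, comp = sp.csgraph.connected_components(adj, directed=False)
        keep_nodes = comp == comp[source]
        remap = -np.ones(len(coords), int)
        remap[keep_nodes] = np.arange(keep_nodes.sum())
        emask = keep_nodes[edges[:, 0]] & keep_nodes[edges[:, 1]]
        g = VenationGraph(
            coords=coords[keep_nodes],
            edges=remap[edges[emask]],
            lengths=lengths[emask],
            widths=widths[emask],
            source=int(remap[source]),
        )
    if fill_areas:
        drainage_areas(g, boundary=shape.boundary())
        # the Voronoi cell of a node can degenerate to zero area only if
        # it falls outside the lamina; guard the sink-ensemble invariant
        g.areas = np.maximum(g.areas, 1e-12 * g.areas.max())
    return g


def make_pseudo_data(
    shape: LeafShape,
    sigma_star: float,
    gamma: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    config: OptimizerConfig | None = None,
    width_floor_factor: float = 1e-3,
) -> VenationGraph:
    """Model-generated "observed" widths at a known σ*, for recovery tests.

    The optimizer runs at (σ*, γ) from the perturbed-uniform lattice
    initialization; the output widths receive optional multiplicative
    lognormal noise (sd ``noise_sd`` in log space) and are floored at a
    small positive value — real extracted data contains no zero-width
    edges — then stored as the graph's data widths.
    """
    g = generate_leaf_lattice(shape)
    config = config or OptimizerConfig()
    from dataclasses import replace

    config = replace(config, sigma=float(sigma_star), gamma=float(gamma))
    result = optimize_conductivities(g, config)
    w = result.raw_widths.copy()
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        w = w * rng.lognormal(mean=0.0, sigma=noise_sd, size=len(w))
    floor = width_floor_factor * w.mean()
    w = np.maximum(w, floor)
    out = g.copy()
    out.widths = w
    return out


def render_mask(
    graph: VenationGraph, px_per_unit: float = 50.0, pad: float | None = None
) -> np.ndarray:
    """Rasterize a graph into a binary vein mask.

    Each positive-width edge is drawn as a stroke of its width (round
    caps), then sampled on the pixel grid; the raster uses the (row, col)
    = (y, x) convention of the extraction module.
    """
    w = graph.widths
    if np.all(w <= 0):
        raise ValueError("render_mask needs positive widths")
    if np.any((w > 0) & (w * px_per_unit < 2)):
        warnings.warn(
            "some strokes are thinner than 2 px at this resolution; "
            "extraction round-trips will be unreliable",
            stacklevel=2,
        )
    if pad is None:
        pad = w.max() / 2 + 2.0 / px_per_unit
    strokes = []
    for i, (t, h) in enumerate(graph.edges):
        if w[i] <= 0:
            continue
        line = shapely.LineString([graph.coords[t], graph.coords[h]])
        strokes.append(line.buffer(w[i] / 2.0, cap_style="round"))
    union = shapely.union_all(strokes)
    x0, y0 = graph.coords.min(axis=0) - pad
    x1, y1 = graph.coords.max(axis=0) + pad
    n_cols = int(np.ceil((x1 - x0) * px_per_unit)) + 1
    n_rows = int(np.ceil((y1 - y0) * px_per_unit)) + 1
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    xs = x0 + cols / px_per_unit
    ys = y0 + rows / px_per_unit
    mask = shapely.intersects_xy(union, xs.ravel(), ys.ravel()).reshape(n_rows, n_cols)
    return mask
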