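"""Binary vein mask → venation graph, and Voronoi drainage areas.

Pipeline: the mask is skeletonized with a medial-axis transform (which
also yields the local vein width as twice the distance to background);
endpoints and branch points are detected from 8-neighbor counts;
the graph is traced by walking the skeleton between node pixels while
averaging the width raster; finally nearby nodes are merged and all
degree-2 nodes contracted.

Drainage areas: each node drains the part of the lamina nearest to it —
the Voronoi cell clipped to the leaf boundary (an alpha shape of the node
cloud when no boundary is supplied).  The clipped cells partition the
boundary polygon, so the areas sum exactly to the lamina area.

Raster convention: images are indexed (row, col), graphs use
(x = col, y = row).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import shapely
from shapely.geometry import MultiPoint, Polygon
from shapely.strtree import STRtree
from scipy.spatial import cKDTree
from skimage.morphology import medial_axis

from .graph import VenationGraph

#: default node-merge radius in pixels ("very close" nodes after tracing)
DEFAULT_MERGE_RADIUS = 3.0


@dataclass
class SkeletonImage:
    """Medial-axis skeleton plus the aligned local-width raster.

    ``widths[r, c]`` is the full local vein width (2 × the distance from
    the centerline pixel to the background) wherever ``skeleton`` is True.
    """

    skeleton: np.ndarray
    widths: np.ndarray


def skeletonize_with_widths(mask: np.ndarray) -> SkeletonImage:
    """Medial-axis skeleton of a binary mask with per-pixel widths."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("mask has empty foreground")
    skel, dist = medial_axis(mask, return_distance=True)
    # the EDT measures center-to-center: the vein boundary lies half a
    # pixel inside the nearest background pixel, so the full width is
    # 2d − 1 (a 5-px bar has d = 3 at its centerline)
    widths = np.where(skel, 2.0 * dist - 1.0, 0.0)
    return SkeletonImage(skeleton=skel, widths=widths)


_NEIGH = np.ones((3, 3), dtype=int)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    s = skel.astype(int)
    return ndi.convolve(s, _NEIGH, mode="constant") * skel - skel


def detect_skeleton_nodes(skel: SkeletonImage | np.ndarray):
    """Endpoints and (cluster-merged) branch points of a skeleton.

    Endpoints have exactly one 8-connected skeleton neighbor; branch
    points have three or more.  Adjacent branch-point pixels are merged
    into one node at their centroid.  Returns
    ``(endpoint (row, col) array, branchpoint centroid array,
    branch label image)``.
    """
    s = skel.skeleton if isinstance(skel, SkeletonImage) else np.asarray(skel, bool)
    counts = _neighbor_counts(s)
    endpoints = np.argwhere(s & (counts == 1))
    branch_mask = s & (counts >= 3)
    labels, n_lab = ndi.label(branch_mask, structure=_NEIGH)
    centroids = (
        np.array(ndi.center_of_mass(branch_mask, labels, range(1, n_lab + 1)))
        if n_lab
        else np.zeros((0, 2))
    )
    return endpoints, centroids, labels


_STEPS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _step(p, q) -> float:
    """Pixel step cost: 1 for axial moves, √2 for diagonal ones."""
    return 1.0 if (p[0] == q[0] or p[1] == q[1]) else float(np.sqrt(2.0))


def _polyline_length(pixels: list, window: int = 5) -> float:
    """Path length along a smoothed polyline through the pixel centers.

    Raw step-cost sums overestimate the length of near-axial paths whose
    skeleton zigzags between adjacent rows/columns (each zigzag pair
    costs √2+1 instead of 2); a short moving average over the pixel
    coordinates removes the staircase while preserving genuine curvature
    at the scale of the window.
    """
    arr = np.asarray(pixels, float)
    if len(arr) < 3:
        return float(np.sum(np.linalg.norm(np.diff(arr, axis=0), axis=1)))
    w = min(window, len(arr))
    kernel = np.ones(w) / w
    sm = np.column_stack(
        [np.convolve(np.pad(arr[:, j], w // 2, mode="edge"), kernel, "valid")
         for j in (0, 1)]
    )
    sm[0], sm[-1] = arr[0], arr[-1]  # endpoints stay anchored on the nodes
    return float(np.sum(np.linalg.norm(np.diff(sm, axis=0), axis=1)))


def trace_graph(skel: SkeletonImage) -> VenationGraph:
    """Walk the skeleton between node pixels and build the raw graph.

    One edge per skeleton path between node points; path length uses
    step cost 1 for axial moves and √2 for diagonal ones; edge width is
    the mean of the width raster along the path.  Skeleton cycles with no
    branch points are anchored at two synthetic nodes (a self-loop would
    be degenerate).
    """
    s = skel.skeleton
    endpoints, centroids, branch_labels = detect_skeleton_nodes(skel)

    # node id per skeleton pixel: endpoints get their own id, each branch
    # cluster one shared id
    node_of_pixel: dict[tuple[int, int], int] = {}
    node_coords: list[tuple[float, float]] = []
    for r, c in endpoints:
        node_of_pixel[(int(r), int(c))] = len(node_coords)
        node_coords.append((float(c), float(r)))
    n_end = len(node_coords)
    for lab in range(1, branch_labels.max() + 1):
        node_coords.append((float(centroids[lab - 1][1]), float(centroids[lab - 1][0])))
    for r, c in np.argwhere(branch_labels > 0):
        node_of_pixel[(int(r), int(c))] = n_end + branch_labels[r, c] - 1

    H, W = s.shape

    def neighbors(p):
        r, c = p
        for dr, dc in _STEPS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and s[rr, cc]:
                yield (rr, cc)

    visited_px: set = set()
    edges, lengths, widths = [], [], []

    def walk(start_px, first_px):
        """Follow the path from a node pixel into first_px until a node.

        Terminates at the first node pixel reached (preferring node
        pixels over plain continuation at every step).
        """
        wsum = skel.widths[first_px]
        cnt = 1
        prev, cur = start_px, first_px
        path = [first_px]
        path_set = {first_px}
        while cur not in node_of_pixel:
            cand = [q for q in neighbors(cur) if q != prev and q not in path_set]
            node_cand = [q for q in cand if q in node_of_pixel]
            plain = [q for q in cand if q not in node_of_pixel and q not in visited_px]
            if node_cand:
                q = node_cand[0]
            elif plain:
                q = plain[0]
            else:
                return None  # dead end without a node marker
            wsum += skel.widths[q]
            cnt += 1
            path.append(q)
            path_set.add(q)
            prev, cur = cur, q
        length = _polyline_length([start_px] + path)
        return cur, length, wsum, cnt, path

    adjacent_pairs: set = set()
    for px, nid in list(node_of_pixel.items()):
        for nb in neighbors(px):
            if nb in node_of_pixel:
                other = node_of_pixel[nb]
                # direct node-node adjacency: one minimal edge per pair
                if other <= nid or (nid, other) in adjacent_pairs:
                    continue
                adjacent_pairs.add((nid, other))
                edges.append((nid, other))
                lengths.append(_step(px, nb))
                widths.append((skel.widths[px] + skel.widths[nb]) / 2.0)
                continue
            if nb in visited_px:
                continue
            out = walk(px, nb)
            if out is None:
                continue
            end_px, length, wsum, cnt, path = out
            visited_px.update(path[:-1] if path[-1] in node_of_pixel else path)
            edges.append((nid, node_of_pixel[end_px]))
            lengths.append(length)
            widths.append(wsum / cnt)

    # isolated cycles: skeleton pixels neither visited nor node pixels
    remaining = (
        {(int(r), int(c)) for r, c in np.argwhere(s)}
        - visited_px
        - set(node_of_pixel)
    )
    while remaining:
        seed = min(remaining)
        ring = [seed]
        ring_set = {seed}
        cur, prev = seed, None
        while True:
            nxt = [
                q for q in neighbors(cur) if q in remaining and q not in ring_set
            ]
            if not nxt:
                break
            q = nxt[0]
            ring.append(q)
            ring_set.add(q)
            prev, cur = cur, q
        remaining -= ring_set
        if len(ring) < 4:
            continue  # too short to form a meaningful cycle
        a_px, b_px = ring[0], ring[len(ring) // 2]
        a_id = len(node_coords)
        node_coords.append((float(a_px[1]), float(a_px[0])))
        b_id = len(node_coords)
        node_coords.append((float(b_px[1]), float(b_px[0])))
        node_of_pixel[a_px] = a_id
        node_of_pixel[b_px] = b_id
        closed = ring + [ring[0]]
        half = len(ring) // 2
        for seg in (closed[: half + 1], closed[half:]):
            L = _polyline_length(seg)
            Wm = float(np.mean([skel.widths[p] for p in seg]))
            edges.append((node_of_pixel[seg[0]], node_of_pixel[seg[-1]]))
            lengths.append(L)
            widths.append(Wm)

    coords = np.array(node_coords, float).reshape(-1, 2)
    edges_arr = np.array(edges, np.int64).reshape(-1, 2)
    if len(edges_arr):
        keep = edges_arr[:, 0] != edges_arr[:, 1]
        edges_arr = edges_arr[keep]
        lengths = np.array(lengths)[keep]
        widths = np.array(widths)[keep]
    return VenationGraph(
        coords=coords,
        edges=edges_arr,
        lengths=np.asarray(lengths, float),
        widths=np.asarray(widths, float),
        source=0,
    )


def prune_graph(
    graph: VenationGraph, merge_radius: float = DEFAULT_MERGE_RADIUS
) -> VenationGraph:
    """Merge nearby nodes and contract all degree-2 nodes.

    Node pairs closer than ``merge_radius`` collapse to their mean
    position (transitively, via union–find).  Chains through degree-2
    nodes become single edges with summed length and length-weighted mean
    width.  Self-loops created by merging are dropped.  Idempotent.
    """
    g = graph
    # --- union-find merge of close nodes
    parent = np.arange(g.n_nodes)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if g.n_nodes > 1 and merge_radius > 0:
        tree = cKDTree(g.coords)
        for i, j in tree.query_pairs(merge_radius):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(g.n_nodes)])
    uniq, new_idx = np.unique(roots, return_inverse=True)
    coords = np.zeros((len(uniq), 2))
    counts = np.bincount(new_idx)
    np.add.at(coords, new_idx, g.coords)
    coords /= counts[:, None]
    edges = new_idx[g.edges]
    keep = edges[:, 0] != edges[:, 1]
    edges, lengths, widths = edges[keep], g.lengths[keep].copy(), g.widths[keep].copy()
    source = int(new_idx[g.source])

    # --- contract degree-2 nodes (repeat until stable)
    changed = True
    while changed:
        changed = False
        deg = np.bincount(edges.ravel(), minlength=len(coords))
        for v in np.flatnonzero(deg == 2):
            if v == source:
                continue
            inc = np.flatnonzero((edges[:, 0] == v) | (edges[:, 1] == v))
            if len(inc) != 2:
                continue  # double edge to same neighbor (loop through v)
            e1, e2 = inc
            a = edges[e1, 1] if edges[e1, 0] == v else edges[e1, 0]
            b = edges[e2, 1] if edges[e2, 0] == v else edges[e2, 0]
            if a == b and a == v:
                continue
            L = lengths[e1] + lengths[e2]
            Wm = (lengths[e1] * widths[e1] + lengths[e2] * widths[e2]) / L
            edges[e1] = (a, b)
            lengths[e1], widths[e1] = L, Wm
            mask = np.ones(len(edges), bool)
            mask[e2] = False
            edges, lengths, widths = edges[mask], lengths[mask], widths[mask]
            if a == b:  # contracted a loop into a self-loop: drop it
                mask = np.ones(len(edges), bool)
                mask[e1 if e1 < e2 else e1 - 1] = False
                edges, lengths, widths = edges[mask], lengths[mask], widths[mask]
            changed = True
            break

    # drop nodes that lost all their edges
    used = np.zeros(len(coords), bool)
    if len(edges):
        used[np.unique(edges.ravel())] = True
    used[source] = True
    remap = -np.ones(len(coords), int)
    remap[used] = np.arange(used.sum())
    return VenationGraph(
        coords=coords[used],
        edges=remap[edges] if len(edges) else edges,
        lengths=lengths,
        widths=widths,
        source=int(remap[source]),
    )


def extract_graph(
    mask: np.ndarray,
    petiole: tuple[float, float] | None = None,
    merge_radius: float = DEFAULT_MERGE_RADIUS,
) -> VenationGraph:
    """Full mask → pruned graph pipeline; source = node nearest the petiole.

    ``petiole`` is an (x, y) position in graph coordinates; when omitted
    the source stays at node 0.
    """
    skel = skeletonize_with_widths(mask)
    g = trace_graph(skel)
    g = prune_graph(g, merge_radius=merge_radius)
    if petiole is not None and g.n_nodes:
        d = np.linalg.norm(g.coords - np.asarray(petiole, float), axis=1)
        g.source = int(np.argmin(d))
    return g


# ----------------------------------------------------------------------
# Drainage areas
# ----------------------------------------------------------------------


def alpha_shape_boundary(coords: np.ndarray, coverage: float = 0.99) -> Polygon:
    """Alpha-shape (concave hull) of the node cloud delimiting the lamina.

    The tightest single simple polygon containing at least ``coverage``
    of the nodes is chosen automatically; falls back to the convex hull.
    """
    pts = MultiPoint([tuple(p) for p in coords])
    best = None
    for ratio in np.linspace(0.05, 1.0, 20):
        hull = shapely.concave_hull(pts, ratio=float(ratio))
        if not isinstance(hull, Polygon) or not hull.is_valid or hull.is_empty:
            continue
        # boundary points count as covered
        frac = shapely.intersects_xy(hull, coords[:, 0], coords[:, 1]).mean()
        if frac >= coverage:
            best = hull
            break
    if best is None:
        best = pts.convex_hull
        if not isinstance(best, Polygon):
            raise ValueError("degenerate node geometry: no polygonal hull")
    return best


def drainage_areas(
    graph: VenationGraph, boundary: Polygon | None = None
) -> VenationGraph:
    """Fill per-node drainage areas: boundary-clipped Voronoi cell areas.

    Mutates and returns ``graph``.  The cells partition the boundary, so
    Σ_j a_j equals the boundary polygon area to numerical precision.
    """
    coords = graph.coords
    if graph.n_nodes < 3:
        raise ValueError("need at least 3 nodes for a Voronoi tessellation")
    if boundary is None:
        boundary = alpha_shape_boundary(coords)
    if not boundary.is_valid or boundary.area <= 0:
        raise ValueError("invalid boundary polygon")
    pts = MultiPoint([tuple(p) for p in coords])
    bx0, by0, bx1, by1 = boundary.bounds
    px0, py0 = coords.min(axis=0)
    px1, py1 = coords.max(axis=0)
    x0, y0 = min(bx0, px0), min(by0, py0)
    x1, y1 = max(bx1, px1), max(by1, py1)
    pad = max(x1 - x0, y1 - y0, 1.0)
    env = shapely.box(x0 - pad, y0 - pad, x1 + pad, y1 + pad)
    cells = shapely.voronoi_polygons(pts, extend_to=env)
    # voronoi_polygons does not preserve input order: match cell -> node
    areas = np.zeros(graph.n_nodes)
    tree = cKDTree(coords)
    for cell in cells.geoms:
        clipped = cell.intersection(boundary)
        if clipped.is_empty:
            continue
        probe = cell.representative_point()
        _, j = tree.query([probe.x, probe.y])
        areas[j] += clipped.area
    graph.areas = areas
    return graph
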