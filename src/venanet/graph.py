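"""Venation-graph data model, validation, incidence construction and file I/O.

A leaf venation network is represented as a directed planar graph: ``n_n``
nodes with coordinates (and, once computed, drainage areas), and ``n_e``
edges each carrying a length, a width and optionally a conductivity.  A
single node — the petiole, where the leaf attaches to the stem — acts as
the fluid source; every other node is a sink.

The edge direction is a bookkeeping convention only: the signed incidence
matrix ``B`` has +1 at an edge's tail and −1 at its head, so a positive
flux means flow from tail to head.  All physical quantities downstream
depend on ``|f|`` or on the sign of ``f`` relative to a node, never on the
orientation itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import networkx as nx
import pandas as pd
import scipy.sparse as sp


class GraphFormatError(ValueError):
    """Raised for malformed or inconsistent graph files."""


@dataclass
class VenationGraph:
    """Directed planar graph of a leaf venation network.

    Parameters
    ----------
    coords : (n_n, 2) float array
        Node positions, arbitrary length units (pixels for extracted graphs).
    edges : (n_e, 2) int array
        Tail and head node indices (dense, 0-based).
    lengths : (n_e,) float array
        Edge lengths, strictly positive.
    widths : (n_e,) float array
        Edge widths, non-negative.  Input data widths are strictly positive;
        model output may contain zeros.
    source : int
        Index of the petiole (source) node.
    areas : (n_n,) float array, optional
        Drainage area of each node (area of its boundary-clipped Voronoi
        cell); ``None`` until computed.
    conductivities : (n_e,) float array, optional
        Per-edge conductivity ``c`` (``c ∝ w⁴``); ``None`` until set.
    node_ids, edge_ids : sequence, optional
        External labels preserved through file round-trips.
    """

    coords: np.ndarray
    edges: np.ndarray
    lengths: np.ndarray
    widths: np.ndarray
    source: int = 0
    areas: np.ndarray | None = None
    conductivities: np.ndarray | None = None
    node_ids: list | None = None
    edge_ids: list | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.lengths = np.asarray(self.lengths, dtype=float).ravel()
        self.widths = np.asarray(self.widths, dtype=float).ravel()
        if self.areas is not None:
            self.areas = np.asarray(self.areas, dtype=float).ravel()
        if self.conductivities is not None:
            self.conductivities = np.asarray(self.conductivities, dtype=float).ravel()

    # -- basic shape ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def sinks(self) -> np.ndarray:
        """Indices of all non-source nodes."""
        return np.delete(np.arange(self.n_nodes), self.source)

    def copy(self) -> "VenationGraph":
        return replace(
            self,
            coords=self.coords.copy(),
            edges=self.edges.copy(),
            lengths=self.lengths.copy(),
            widths=self.widths.copy(),
            areas=None if self.areas is None else self.areas.copy(),
            conductivities=None
            if self.conductivities is None
            else self.conductivities.copy(),
            node_ids=None if self.node_ids is None else list(self.node_ids),
            edge_ids=None if self.edge_ids is None else list(self.edge_ids),
        )

    def degrees(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Node degrees, optionally restricted to a boolean edge mask."""
        e = self.edges if mask is None else self.edges[np.asarray(mask, bool)]
        return np.bincount(e.ravel(), minlength=self.n_nodes)

    def cycle_rank(self, mask: np.ndarray | None = None) -> int:
        """Number of independent loops E − N + C of the (masked) subgraph.

        N counts only nodes touched by at least one retained edge.
        """
        e = self.edges if mask is None else self.edges[np.asarray(mask, bool)]
        if len(e) == 0:
            return 0
        nodes = np.unique(e.ravel())
        remap = {n: i for i, n in enumerate(nodes)}
        rows = np.array([remap[t] for t in e[:, 0]])
        cols = np.array([remap[h] for h in e[:, 1]])
        adj = sp.coo_matrix(
            (np.ones(len(e)), (rows, cols)), shape=(len(nodes), len(nodes))
        )
        n_comp = sp.csgraph.connected_components(adj, directed=False)[0]
        return int(len(e) - len(nodes) + n_comp)

    # -- matrices -------------------------------------------------------
    def incidence(self) -> sp.csr_matrix:
        """Signed node–edge incidence matrix B (n_n × n_e).

        Column i has +1 at the tail node of edge i and −1 at its head, so
        f_i > 0 means flow tail→head.  Independent of coordinates.
        """
        n_e = self.n_edges
        rows = self.edges.T.ravel()  # tails then heads
        cols = np.tile(np.arange(n_e), 2)
        data = np.concatenate([np.ones(n_e), -np.ones(n_e)])
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n_nodes, n_e))

    def is_connected(self, mask: np.ndarray | None = None) -> bool:
        """Whether all n_n nodes are connected through the (masked) edges."""
        e = self.edges if mask is None else self.edges[np.asarray(mask, bool)]
        if self.n_nodes <= 1:
            return True
        if len(e) == 0:
            return False
        adj = sp.coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])),
            shape=(self.n_nodes, self.n_nodes),
        )
        return sp.csgraph.connected_components(adj, directed=False)[0] == 1

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for j in range(self.n_nodes):
            attrs = {"x": float(self.coords[j, 0]), "y": float(self.coords[j, 1])}
            if self.areas is not None:
                attrs["area"] = float(self.areas[j])
            g.add_node(j, **attrs)
        for i, (t, h) in enumerate(self.edges):
            attrs = {
                "length": float(self.lengths[i]),
                "width": float(self.widths[i]),
                "eid": i,
            }
            if self.conductivities is not None:
                attrs["conductivity"] = float(self.conductivities[i])
            g.add_edge(int(t), int(h), **attrs)
        g.graph["source"] = int(self.source)
        return g


@dataclass
class ValidationReport:
    ok: bool
    violations: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_graph(graph: VenationGraph) -> ValidationReport:
    """Check the structural invariants of a venation graph.

    Returns a report rather than raising, so callers can surface all
    problems at once.  Checked: positive lengths, non-negative widths,
    valid endpoints, no self-loops, a valid source index, and connectivity
    of the positive-width subgraph (input data has no zero-width edges, so
    on input this is connectivity of the whole network).
    """
    v: list[str] = []
    g = graph
    if g.n_nodes == 0:
        v.append("empty graph: no nodes")
    if not (0 <= g.source < max(g.n_nodes, 1)):
        v.append(f"source index {g.source} out of range")
    if g.n_edges:
        if g.edges.min() < 0 or g.edges.max() >= g.n_nodes:
            v.append("edge endpoint references a non-existent node")
        if np.any(g.edges[:, 0] == g.edges[:, 1]):
            v.append("self-loop edge present")
        if np.any(~(g.lengths > 0)):
            v.append("non-positive length")
        if np.any(g.widths < 0):
            v.append("negative width")
    if len(g.lengths) != g.n_edges or len(g.widths) != g.n_edges:
        v.append("length/width arrays do not match edge count")
    if g.node_ids is not None and len(set(g.node_ids)) != g.n_nodes:
        v.append("duplicate node id")
    if not v and g.n_nodes > 1:
        if not g.is_connected(mask=g.widths > 0):
            v.append("disconnected: positive-width subgraph does not span all nodes")
    return ValidationReport(ok=not v, violations=v)


def build_incidence(graph: VenationGraph) -> sp.csr_matrix:
    """Validated incidence-matrix construction (see ``VenationGraph.incidence``)."""
    report = validate_graph(graph)
    if not report.ok:
        raise ValueError("invalid graph: " + "; ".join(report.violations))
    return graph.incidence()


# ----------------------------------------------------------------------
# File I/O.  Three dialects: csv-pair (nodes.csv + edges.csv), a single
# JSON file, and GraphML.  External ids may be arbitrary strings; they are
# mapped onto dense 0-based integers with the mapping preserved.
# ----------------------------------------------------------------------

_FORMATS = ("csv-pair", "json", "graphml")


def _infer_format(path: Path) -> str:
    s = str(path)
    if s.endswith(".json"):
        return "json"
    if s.endswith(".graphml"):
        return "graphml"
    return "csv-pair"


def save_graph(graph: VenationGraph, path: str | Path, format: str | None = None) -> None:
    """Write a graph to disk.

    ``csv-pair`` writes ``<path>.nodes.csv`` and ``<path>.edges.csv`` (or
    ``nodes.csv``/``edges.csv`` inside ``path`` if it is a directory).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise GraphFormatError(f"unknown format {fmt!r}; choose from {_FORMATS}")
    g = graph
    node_ids = g.node_ids if g.node_ids is not None else list(range(g.n_nodes))
    edge_ids = g.edge_ids if g.edge_ids is not None else list(range(g.n_edges))

    if fmt == "json":
        payload = {
            "source": int(g.source),
            "nodes": [
                {
                    "id": node_ids[j],
                    "x": float(g.coords[j, 0]),
                    "y": float(g.coords[j, 1]),
                    **({"area": float(g.areas[j])} if g.areas is not None else {}),
                }
                for j in range(g.n_nodes)
            ],
            "edges": [
                {
                    "id": edge_ids[i],
                    "tail": node_ids[g.edges[i, 0]],
                    "head": node_ids[g.edges[i, 1]],
                    "length": float(g.lengths[i]),
                    "width": float(g.widths[i]),
                    **(
                        {"conductivity": float(g.conductivities[i])}
                        if g.conductivities is not None
                        else {}
                    ),
                }
                for i in range(g.n_edges)
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    elif fmt == "csv-pair":
        if path.is_dir() or path.suffix == "":
            path.mkdir(parents=True, exist_ok=True)
            npath, epath = path / "nodes.csv", path / "edges.csv"
        else:
            base = str(path)
            npath, epath = Path(base + ".nodes.csv"), Path(base + ".edges.csv")
        ndf = pd.DataFrame(
            {"id": node_ids, "x": g.coords[:, 0], "y": g.coords[:, 1]}
        )
        if g.areas is not None:
            ndf["area"] = g.areas
        ndf["is_source"] = np.arange(g.n_nodes) == g.source
        edf = pd.DataFrame(
            {
                "id": edge_ids,
                "tail": [node_ids[t] for t in g.edges[:, 0]],
                "head": [node_ids[h] for h in g.edges[:, 1]],
                "length": g.lengths,
                "width": g.widths,
            }
        )
        if g.conductivities is not None:
            edf["conductivity"] = g.conductivities
        ndf.to_csv(npath, index=False)
        edf.to_csv(epath, index=False)
    else:  # graphml
        nx.write_graphml(graph.to_networkx(), path)


def load_graph(path: str | Path, format: str | None = None) -> VenationGraph:
    """Read a graph written by :func:`save_graph`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise GraphFormatError(f"unknown format {fmt!r}; choose from {_FORMATS}")

    if fmt == "json":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise GraphFormatError(f"malformed JSON in {path}: {exc}") from exc
        node_recs, edge_recs = payload.get("nodes", []), payload.get("edges", [])
        node_ids = [r["id"] for r in node_recs]
        if len(set(map(str, node_ids))) != len(node_ids):
            raise GraphFormatError("duplicate node id in JSON graph")
        index = {nid: j for j, nid in enumerate(node_ids)}
        coords = np.array([[r["x"], r["y"]] for r in node_recs], float).reshape(-1, 2)
        areas = (
            np.array([r["area"] for r in node_recs], float)
            if node_recs and all("area" in r for r in node_recs)
            else None
        )
        try:
            edges = np.array(
                [[index[r["tail"]], index[r["head"]]] for r in edge_recs], np.int64
            ).reshape(-1, 2)
            lengths = np.array([r["length"] for r in edge_recs], float)
            widths = np.array([r["width"] for r in edge_recs], float)
        except KeyError as exc:
            raise GraphFormatError(f"edge record missing field {exc}") from exc
        cond = (
            np.array([r["conductivity"] for r in edge_recs], float)
            if edge_recs and all("conductivity" in r for r in edge_recs)
            else None
        )
        return VenationGraph(
            coords=coords,
            edges=edges,
            lengths=lengths,
            widths=widths,
            source=int(payload.get("source", 0)),
            areas=areas,
            conductivities=cond,
            node_ids=node_ids,
            edge_ids=[r["id"] for r in edge_recs],
        )

    if fmt == "csv-pair":
        if path.is_dir():
            npath, epath = path / "nodes.csv", path / "edges.csv"
        else:
            base = str(path)
            npath, epath = Path(base + ".nodes.csv"), Path(base + ".edges.csv")
        ndf = pd.read_csv(npath)
        edf = pd.read_csv(epath)
        for col in ("id", "x", "y"):
            if col not in ndf.columns:
                raise GraphFormatError(f"{npath}: missing node column {col!r}")
        for col in ("tail", "head", "length", "width"):
            if col not in edf.columns:
                raise GraphFormatError(f"{epath}: missing edge column {col!r}")
        node_ids = ndf["id"].tolist()
        if len(set(map(str, node_ids))) != len(node_ids):
            raise GraphFormatError(f"{npath}: duplicate node id")
        index = {nid: j for j, nid in enumerate(node_ids)}
        try:
            edges = np.array(
                [[index[t], index[h]] for t, h in zip(edf["tail"], edf["head"])],
                np.int64,
            ).reshape(-1, 2)
        except KeyError as exc:
            raise GraphFormatError(f"{epath}: edge references unknown node {exc}")
        source = 0
        if "is_source" in ndf.columns:
            src = np.flatnonzero(ndf["is_source"].astype(bool).to_numpy())
            if len(src) != 1:
                raise GraphFormatError(f"{npath}: expected exactly one source node")
            source = int(src[0])
        return VenationGraph(
            coords=ndf[["x", "y"]].to_numpy(float),
            edges=edges,
            lengths=edf["length"].to_numpy(float),
            widths=edf["width"].to_numpy(float),
            source=source,
            areas=ndf["area"].to_numpy(float) if "area" in ndf.columns else None,
            conductivities=edf["conductivity"].to_numpy(float)
            if "conductivity" in edf.columns
            else None,
            node_ids=node_ids,
            edge_ids=edf["id"].tolist(),
        )

    # graphml
    g = nx.read_graphml(path, node_type=str)
    node_ids = list(g.nodes)
    index = {nid: j for j, nid in enumerate(node_ids)}
    coords = np.array([[g.nodes[n]["x"], g.nodes[n]["y"]] for n in node_ids], float)
    areas = (
        np.array([g.nodes[n]["area"] for n in node_ids], float)
        if node_ids and all("area" in g.nodes[n] for n in node_ids)
        else None
    )
    if g.is_multigraph():
        raw = [(t, h, d) for t, h, _, d in g.edges(keys=True, data=True)]
    else:
        raw = [(t, h, d) for t, h, d in g.edges(data=True)]
    erecs = sorted(raw, key=lambda e: e[2].get("eid", 0))
    edges = np.array([[index[t], index[h]] for t, h, _ in erecs], np.int64).reshape(
        -1, 2
    )
    lengths = np.array([d["length"] for *_, d in erecs], float)
    widths = np.array([d["width"] for *_, d in erecs], float)
    cond = (
        np.array([d["conductivity"] for *_, d in erecs], float)
        if erecs and all("conductivity" in d for *_, d in erecs)
        else None
    )
    return VenationGraph(
        coords=coords,
        edges=edges,
        lengths=lengths,
        widths=widths,
        source=int(g.graph.get("source", 0)),
        areas=areas,
        conductivities=cond,
        node_ids=node_ids,
    )
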