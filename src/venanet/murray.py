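"""Murray's law for reticulate venation networks.

Classical Murray's law states that at a branch point of a leak-free,
tree-like vascular network the parent radius obeys
``r_p^α = Σ_i r_{d,i}^α`` with α = 3 for laminar flow.  In a network
with loops the very notion of "parent" and "daughter" breaks down: the
direction of flow through an edge depends on where in the leaf the
drainage is currently concentrated.  The extension implemented here
resolves directions per ensemble member and averages:

    R_b^{in/out}(α) = ⟨ Σ_i I_b,i^{in/out}(k) · r_{b,i}^α ⟩_k

for every branch node b (degree > 2), where the indicator I selects the
edges whose flow enters (leaves) b under the moving-sink position k.
The law reads R_b^in(α) = R_b^out(α), and the branching exponent is
estimated by minimizing the mean squared residual

    L(α) = ⟨ (R_b^out(α) − R_b^in(α))² ⟩_b.

Because the model drains fluid *at* the branch nodes, the out-sum misses
exactly the node's own sink; on a σ = 0 tree at the optimizer's fixed
point (w³ ∝ |f|) the residual is −κ·a_b with a single global κ > 0.
Fitting that sink-area correction and adding κ·a_b back recenters the
residuals at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import VenationGraph
from .hydro import CONDUCTIVITY_FLOOR, FlowSolver, SinkEnsemble, conductivity_from_width

#: relative flux threshold below which an incident edge is excluded from
#: both the in- and the out-sum (ties / numerically dead edges)
FLUX_TIE_RTOL = 1e-12


@dataclass
class MurrayTable:
    """Per-branch-node Murray sums at a single exponent α."""

    branch_nodes: np.ndarray
    r_in: np.ndarray
    r_out: np.ndarray
    areas: np.ndarray | None
    alpha: float

    @property
    def residuals(self) -> np.ndarray:
        return self.r_out - self.r_in


class MurrayAnalysis:
    """Direction-resolved Murray sums for one model-output network.

    Parameters
    ----------
    graph : VenationGraph
    widths : (n_e,) array
        Model-output widths ŵ (zeros allowed on pruned edges).
    sigma : float
        Sink-fluctuation amplitude used to build the direction ensemble.
    conductivities : optional
        Conductivities defining the flow field; defaults to ŵ⁴, which
        reproduces the converged model's flow directions.
    use_radii : bool
        Evaluate the sums with r = w/2 (default) or with widths directly;
        both sides scale by 2^α, so losses shift but the fitted exponent
        is identical.
    """

    def __init__(
        self,
        graph: VenationGraph,
        widths: np.ndarray,
        sigma: float,
        conductivities: np.ndarray | None = None,
        use_radii: bool = True,
        floor: float = CONDUCTIVITY_FLOOR,
    ):
        self.graph = graph
        self.widths = np.asarray(widths, float)
        self.sigma = sigma
        if conductivities is None:
            conductivities = conductivity_from_width(self.widths)
        self.ensemble = SinkEnsemble.from_graph(graph, sigma)
        solver = FlowSolver(graph, conductivities, floor=floor)
        S, weights = self.ensemble.unique_members()
        self._F = solver.fluxes(S)  # (n_e, K)
        self._weights = weights
        self.radii = self.widths / 2.0 if use_radii else self.widths.copy()

        deg = graph.degrees()
        branch = np.flatnonzero(deg > 2)
        # the petiole injects the whole load and has no incoming vein; it
        # is a boundary condition, not a branch point, and its spurious
        # residual (≈ the full unit inflow) would swamp the loss
        branch = branch[branch != graph.source]
        # branch nodes whose every incident edge has zero width carry no
        # information and are dropped from the loss
        incident_w = np.zeros(graph.n_nodes)
        np.add.at(incident_w, graph.edges[:, 0], self.widths)
        np.add.at(incident_w, graph.edges[:, 1], self.widths)
        self.branch_nodes = branch[incident_w[branch] > 0]
        self._build_direction_counts()

    def _build_direction_counts(self):
        """Ensemble-averaged in/out weight of each (branch node, edge) pair."""
        g, F, w = self.graph, self._F, self._weights
        thresh = FLUX_TIE_RTOL * np.abs(F).max()
        self._frac_in = {}  # b -> (incident edge idx, avg in-weight, avg out-weight)
        tails, heads = g.edges[:, 0], g.edges[:, 1]
        for b in self.branch_nodes:
            inc = np.flatnonzero((tails == b) | (heads == b))
            sign = np.where(tails[inc] == b, 1.0, -1.0)  # + = f>0 leaves b
            Fb = F[inc] * sign[:, None]  # >0 means outgoing at b
            w_out = ((Fb > thresh).astype(float) @ w)
            w_in = ((Fb < -thresh).astype(float) @ w)
            self._frac_in[b] = (inc, w_in, w_out)

    def direction_indicators(self, b: int):
        """Per-member in/out classification of node b's incident edges.

        Returns ``(incident edge indices, I_in, I_out)`` with boolean
        arrays of shape (n_incident, n_members); near-zero fluxes are in
        neither class.
        """
        g, F = self.graph, self._F
        if g.degrees()[b] <= 2:
            raise ValueError(f"node {b} is not a branch node (degree <= 2)")
        thresh = FLUX_TIE_RTOL * np.abs(F).max()
        tails, heads = g.edges[:, 0], g.edges[:, 1]
        inc = np.flatnonzero((tails == b) | (heads == b))
        sign = np.where(tails[inc] == b, 1.0, -1.0)
        Fb = F[inc] * sign[:, None]
        return inc, Fb < -thresh, Fb > thresh

    def sums(self, alpha: float) -> MurrayTable:
        """R_b^in(α) and R_b^out(α) for every branch node."""
        r = self.radii
        r_in = np.empty(len(self.branch_nodes))
        r_out = np.empty(len(self.branch_nodes))
        for i, b in enumerate(self.branch_nodes):
            inc, w_in, w_out = self._frac_in[b]
            ra = r[inc] ** alpha
            r_in[i] = np.dot(w_in, ra)
            r_out[i] = np.dot(w_out, ra)
        areas = None if self.graph.areas is None else self.graph.areas[self.branch_nodes]
        return MurrayTable(
            branch_nodes=self.branch_nodes.copy(),
            r_in=r_in,
            r_out=r_out,
            areas=areas,
            alpha=alpha,
        )

    def loss(self, alpha: float) -> float:
        """L(α): mean squared residual over branch nodes."""
        if len(self.branch_nodes) == 0:
            raise ValueError("network has no branch nodes (degree > 2)")
        t = self.sums(alpha)
        return float(np.mean(t.residuals**2))

    def loss_curve(self, alphas: np.ndarray) -> np.ndarray:
        """Vectorized L(α) over a grid (counts are computed once)."""
        alphas = np.asarray(alphas, float)
        r = self.radii
        losses = np.empty(len(alphas))
        # Precompute per-branch incident radii and direction weights
        packed = [self._frac_in[b] for b in self.branch_nodes]
        for j, a in enumerate(alphas):
            acc = 0.0
            for inc, w_in, w_out in packed:
                ra = r[inc] ** a
                d = np.dot(w_out - w_in, ra)
                acc += d * d
            losses[j] = acc / len(packed)
        return losses

    def fit_alpha(
        self, alphas: np.ndarray | None = None
    ) -> "MurrayFitResult":
        """Grid minimization of L(α) with parabolic refinement.

        The default grid is [2, 4] in steps of 0.01; a minimum on the
        grid boundary is flagged as a bracket failure.
        """
        if alphas is None:
            alphas = np.arange(2.0, 4.0 + 1e-12, 0.01)
        alphas = np.asarray(alphas, float)
        losses = self.loss_curve(alphas)
        i = int(np.argmin(losses))
        boundary = i == 0 or i == len(alphas) - 1
        if boundary:
            alpha_star = float(alphas[i])
        else:
            alpha_star = _parabolic_vertex(alphas[i - 1 : i + 2], losses[i - 1 : i + 2])
        return MurrayFitResult(
            alpha_star=alpha_star,
            alphas=alphas,
            losses=losses,
            bracket_failure=boundary,
            analysis=self,
        )

    def sink_corrected_residuals(self, alpha: float):
        """Least-squares sink-area correction of the Murray residuals.

        Finds the single κ minimizing Σ_b (residual_b + κ a_b)² — in
        closed form κ = −Σ residual_b a_b / Σ a_b² — and returns
        ``(corrected residuals, κ, table)``.
        """
        table = self.sums(alpha)
        if table.areas is None or np.all(table.areas == 0):
            raise ValueError("drainage areas required for the sink correction")
        res, a = table.residuals, table.areas
        kappa = -float(np.dot(res, a) / np.dot(a, a))
        return res + kappa * a, kappa, table


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex of the parabola through three bracketing points."""
    x0, x1, x2 = map(float, x)
    y0, y1, y2 = map(float, y)
    num = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
    den = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if den == 0:
        return x1
    return x1 - 0.5 * num / den


@dataclass
class MurrayFitResult:
    alpha_star: float
    alphas: np.ndarray
    losses: np.ndarray
    bracket_failure: bool
    analysis: MurrayAnalysis


def murray_loss(
    graph: VenationGraph,
    widths: np.ndarray,
    sigma: float,
    alpha: float,
    conductivities: np.ndarray | None = None,
) -> float:
    """Functional one-shot L(α) (see :class:`MurrayAnalysis`)."""
    return MurrayAnalysis(graph, widths, sigma, conductivities).loss(alpha)


def fit_alpha(
    graph: VenationGraph,
    widths: np.ndarray,
    sigma: float,
    alphas: np.ndarray | None = None,
    conductivities: np.ndarray | None = None,
) -> MurrayFitResult:
    """Functional one-shot α fit (see :meth:`MurrayAnalysis.fit_alpha`)."""
    return MurrayAnalysis(graph, widths, sigma, conductivities).fit_alpha(alphas)


def gaussian_smoothed_residuals(
    parent_widths: np.ndarray,
    residuals: np.ndarray,
    bandwidth: float = 0.2,
    n_points: int = 100,
):
    """Gaussian-kernel mean and SD of residuals versus parent-vein width.

    The kernel acts in log10 of the width (bandwidth in decades), the
    scale on which vein hierarchies are naturally spaced.  Returns
    ``(width grid, smoothed mean, smoothed SD)``.
    """
    w = np.asarray(parent_widths, float)
    r = np.asarray(residuals, float)
    keep = w > 0
    w, r = w[keep], r[keep]
    lw = np.log10(w)
    grid = np.linspace(lw.min(), lw.max(), n_points)
    K = np.exp(-0.5 * ((grid[:, None] - lw[None, :]) / bandwidth) ** 2)
    Ksum = K.sum(axis=1)
    mean = (K @ r) / Ksum
    var = (K @ r**2) / Ksum - mean**2
    return 10.0**grid, mean, np.sqrt(np.maximum(var, 0.0))
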