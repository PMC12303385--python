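"""Model/Results interface over the venation pipeline.

`VenationFlowModel` is built from a :class:`~venanet.graph.VenationGraph`
(or directly from a binary mask); its :meth:`fit` runs the fixed-point
conductivity optimization and returns a :class:`VenationFlowResults`
carrying the optimized widths, convergence diagnostics, and downstream
analyses (Murray exponent fitting, width comparison).  σ estimation is a
separate model, :class:`SigmaFluctuationModel`, whose fit scans the σ
grid with one full optimization per point.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import extract, hydro, murray as murray_mod, optimize as opt, sigma as sigma_mod
from .graph import VenationGraph, validate_graph


class VenationFlowModel:
    """Hydrodynamic venation model for one leaf network.

    Parameters
    ----------
    graph : VenationGraph
        Input network with strictly positive data widths; drainage areas
        are computed on construction if missing.
    sigma : float
        Sink-fluctuation amplitude σ ∈ [0, 1].
    gamma : float
        Material-cost exponent (default 1/2: fixed-volume budget).
    **config
        Remaining :class:`~venanet.optimize.OptimizerConfig` fields.
    """

    def __init__(self, graph: VenationGraph, sigma: float = 0.0, gamma: float = 0.5, **config):
        report = validate_graph(graph)
        if not report.ok:
            raise ValueError("invalid graph: " + "; ".join(report.violations))
        if graph.areas is None:
            graph = extract.drainage_areas(graph.copy())
        self.graph = graph
        self.config = opt.OptimizerConfig(sigma=sigma, gamma=gamma, **config)

    @classmethod
    def from_mask(
        cls,
        mask: np.ndarray,
        petiole: tuple[float, float],
        sigma: float = 0.0,
        gamma: float = 0.5,
        merge_radius: float = extract.DEFAULT_MERGE_RADIUS,
        **config,
    ) -> "VenationFlowModel":
        """Extract the graph from a binary vein mask and build the model."""
        g = extract.extract_graph(mask, petiole=petiole, merge_radius=merge_radius)
        return cls(g, sigma=sigma, gamma=gamma, **config)

    @property
    def ensemble(self) -> hydro.SinkEnsemble:
        return hydro.SinkEnsemble.from_graph(self.graph, self.config.sigma)

    def flow(self, k: int | None = None) -> hydro.FlowSolution:
        """Kirchhoff flow at the *data* conductivities (w_data⁴).

        With ``k`` given, solves the single moving-sink member; otherwise
        the σ = 0 static area-weighted load.
        """
        c = hydro.conductivity_from_width(self.graph.widths)
        ens = self.ensemble if k is not None else hydro.SinkEnsemble.from_graph(self.graph, 0.0)
        s = ens.member(k if k is not None else int(ens.sinks[0]))
        return hydro.solve_flow(self.graph, c, s, floor=self.config.floor)

    def fit(self, method: str = "monolithic") -> "VenationFlowResults":
        """Optimize conductivities; ``method`` ∈ {monolithic, subsystems}."""
        if method == "monolithic":
            res = opt.optimize_conductivities(self.graph, self.config)
        elif method == "subsystems":
            res = opt.optimize_full_leaf(self.graph, self.config)
        else:
            raise ValueError(f"unknown method {method!r}")
        return VenationFlowResults(self, res, method)


class VenationFlowResults:
    """Converged model network and its diagnostics."""

    def __init__(self, model: VenationFlowModel, result: opt.OptimizeResult, method: str):
        self.model = model
        self._result = result
        self.method = method

    # -- estimates ------------------------------------------------------
    @property
    def widths(self) -> np.ndarray:
        """Normalized model widths ŵ (exact zeros below the threshold)."""
        return self._result.widths

    @property
    def raw_widths(self) -> np.ndarray:
        return self._result.raw_widths

    @property
    def conductivities(self) -> np.ndarray:
        return self._result.conductivities

    @property
    def zero_width_count(self) -> int:
        return int(self._result.zero_mask.sum())

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def n_iter(self) -> int:
        return self._result.n_iter

    @property
    def dissipation_trace(self) -> np.ndarray:
        """Ensemble dissipation at fixed material cost, per iteration."""
        return self._result.power

    def cycle_rank(self) -> int:
        """Independent loops among the nonzero-width model edges."""
        return self.model.graph.cycle_rank(mask=self.widths > 0)

    def width_loss(self) -> float:
        """Edge-to-edge width loss L(σ) of this fit against the data."""
        return sigma_mod.width_loss(self.model.graph.widths, self.widths)

    # -- downstream analyses -------------------------------------------
    def murray(self, alphas: np.ndarray | None = None) -> murray_mod.MurrayFitResult:
        """Fit the reticulate Murray exponent on the model output."""
        analysis = murray_mod.MurrayAnalysis(
            self.model.graph,
            self.widths,
            self.model.config.sigma,
            conductivities=self.conductivities,
        )
        return analysis.fit_alpha(alphas)

    def murray_analysis(self) -> murray_mod.MurrayAnalysis:
        return murray_mod.MurrayAnalysis(
            self.model.graph,
            self.widths,
            self.model.config.sigma,
            conductivities=self.conductivities,
        )

    def summary(self) -> str:
        g = self.model.graph
        cfg = self.model.config
        lines = [
            "Venation flow model fit",
            "=" * 47,
            f"{'nodes':<28}{g.n_nodes:>19}",
            f"{'edges':<28}{g.n_edges:>19}",
            f"{'sigma (sink fluctuation)':<28}{cfg.sigma:>19.4g}",
            f"{'gamma (material exponent)':<28}{cfg.gamma:>19.4g}",
            f"{'method':<28}{self.method:>19}",
            f"{'converged':<28}{str(self.converged):>19}",
            f"{'iterations':<28}{self.n_iter:>19}",
            f"{'zero-width model edges':<28}{self.zero_width_count:>19}",
            f"{'cycle rank (model output)':<28}{self.cycle_rank():>19}",
            f"{'width loss L(sigma)':<28}{self.width_loss():>19.6g}",
            "=" * 47,
        ]
        return "\n".join(lines)

    def plot_widths(self, ax=None):
        """Model vs. data widths, edge by edge (zeros highlighted)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        wd, wm = self.model.graph.widths, self.widths
        zero = self._result.zero_mask
        ax.scatter(wd[~zero], wm[~zero], s=6, alpha=0.5, label="model edges")
        if zero.any():
            ax.scatter(wd[zero], np.zeros(zero.sum()), s=6, c="k", label="zero-width")
        lim = max(wd.max(), wm.max())
        ax.plot([0, lim], [0, lim], "r--", lw=1, label="equality")
        ax.set_xlabel("data width")
        ax.set_ylabel("model width")
        ax.legend()
        return ax


class SigmaFluctuationModel:
    """Grid estimator for the sink-fluctuation amplitude σ."""

    def __init__(self, graph: VenationGraph, gamma: float = 0.5, **config):
        if graph.areas is None:
            graph = extract.drainage_areas(graph.copy())
        self.graph = graph
        self.config = opt.OptimizerConfig(gamma=gamma, **config)

    def fit(self, grid: np.ndarray | None = None) -> "SigmaFluctuationResults":
        res = sigma_mod.fit_sigma(self.graph, self.config, grid)
        return SigmaFluctuationResults(self, res)


class SigmaFluctuationResults:
    def __init__(self, model: SigmaFluctuationModel, result: sigma_mod.SigmaFitResult):
        self.model = model
        self._result = result

    @property
    def sigma_star(self) -> float:
        return self._result.sigma_star

    @property
    def grid(self) -> np.ndarray:
        return self._result.grid

    @property
    def losses(self) -> np.ndarray:
        return self._result.losses

    @property
    def boundary_minimum(self) -> bool:
        return self._result.boundary_minimum

    @property
    def scatter_table(self):
        return self._result.scatter_table

    def summary(self) -> str:
        r = self._result
        lines = [
            "Sink-fluctuation amplitude fit",
            "=" * 47,
            f"{'sigma*':<28}{r.sigma_star:>19.4f}",
            f"{'grid points':<28}{len(r.grid):>19}",
            f"{'min grid loss':<28}{r.losses.min():>19.6g}",
            f"{'boundary minimum':<28}{str(r.boundary_minimum):>19}",
            f"{'zero-width edges at fit':<28}{r.zero_width_count:>19}",
            "=" * 47,
        ]
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.losses, "o-")
        ax.axvline(self.sigma_star, color="r", ls="--", lw=1)
        ax.set_xlabel(r"sink fluctuation $\sigma$")
        ax.set_ylabel(r"width loss $L(\sigma)$")
        return ax
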