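"""Model / Results interface for generalized modularity detection.

`GeneralizedModularity` binds a graph to one generalized modularity
model (NG, RB, or AFG) and a resolution-parameter source.  `fit()` runs
one hierarchical agglomeration and returns `AgglomerationResults`;
`fit_ensemble()` runs many stochastic replicas and returns
`EnsembleResults` with replica statistics and stability diagnostics.
Both results objects expose `summary()`.
"""

from __future__ import annotations

import numpy as np

from .agglomeration import Hierarchy, run_agglomeration
from .experiments import ExperimentSummary, SigmaSampler, run_experiment, report
from .graph import Graph, Partition, check_connected, degree_vector, largest_component, read_graph
from .metrics import nvi
from .modularity import make_params, newman_girvan_q, spectral_bipartition

__all__ = ["GeneralizedModularity", "AgglomerationResults", "EnsembleResults"]


class GeneralizedModularity:
    """Generalized-modularity community detection model on a graph.

    Parameters
    ----------
    graph : Graph
        Undirected weighted graph; must be connected unless
        ``allow_disconnected`` is set (then the largest component is
        analyzed, matching the connectivity assumption of the
        modularity null model).
    variant : {"ng", "rb", "afg"}
        Null-model family.  NG is the parameter-free standard model; RB
        rescales the null term by ``sigma / 2m``; AFG adds ``sigma`` to
        every self-loop and shifts the degree vector accordingly.
    sigma : float or SigmaSampler, default SigmaSampler.uniform(0.5, 1.5)
        Resolution parameter: a number for deterministic runs, or a
        sampler for the stochastic algorithm (redrawn each coarsening
        level by default).
    """

    def __init__(self, graph: Graph, variant: str = "rb",
                 sigma: float | SigmaSampler = SigmaSampler.uniform(0.5, 1.5),
                 sigma_per: str = "level", allow_disconnected: bool = False,
                 name: str = "graph"):
        if not check_connected(graph):
            if not allow_disconnected:
                raise ValueError(
                    "graph is disconnected; modularity assumes a connected "
                    "graph (pass allow_disconnected=True to analyze the "
                    "largest component)"
                )
            graph = largest_component(graph)
        self.graph = graph
        self.variant = variant.lower()
        self.sigma = (SigmaSampler.fixed(sigma)
                      if isinstance(sigma, (int, float)) else sigma)
        self.sigma_per = sigma_per
        self.name = name
        self.deg = degree_vector(graph)

    @classmethod
    def from_file(cls, path, fmt: str = "auto", **kw) -> "GeneralizedModularity":
        g = read_graph(path, fmt)
        kw.setdefault("name", str(path))
        return cls(g, **kw)

    def _run(self, rng) -> Hierarchy:
        if self.sigma.mode == "fixed":
            return run_agglomeration(self.graph, self.variant,
                                     sigma=self.sigma.value, rng=rng)
        return run_agglomeration(
            self.graph, self.variant,
            sigma_interval=(self.sigma.low, self.sigma.high),
            rng=rng, sigma_per=self.sigma_per,
        )

    def fit(self, seed: int | None = None) -> "AgglomerationResults":
        """One agglomeration run (deterministic given the seed)."""
        h = self._run(np.random.default_rng(seed))
        return AgglomerationResults(self, h, seed)

    def fit_ensemble(self, runs: int = 100,
                     seed: int | None = None) -> "EnsembleResults":
        """``runs`` independent stochastic replicas with replica stats."""
        summary = run_experiment(
            self.graph, self.variant, self.sigma, runs, seed=seed,
            sigma_per=self.sigma_per, dataset=self.name,
        )
        return EnsembleResults(self, summary)

    def spectral_split(self, sigma: float = 1.0):
        """Leading-eigenvector two-way split (small-graph validation)."""
        params = make_params(self.graph, self.variant, sigma, deg=self.deg)
        return spectral_bipartition(self.graph, params)


class AgglomerationResults:
    """Result of a single agglomeration run."""

    def __init__(self, model: GeneralizedModularity, hierarchy: Hierarchy,
                 seed):
        self.model = model
        self.hierarchy = hierarchy
        self.seed = seed
        self.partition: Partition = hierarchy.final_partition
        self.q_ng: float = hierarchy.q_ng
        self.n_communities: int = hierarchy.n_communities
        self.sigma_trace = hierarchy.sigma_trace

    def score(self, other: Partition | None = None) -> float:
        """Newman-Girvan modularity of this (or a supplied) partition."""
        p = self.partition if other is None else other
        return newman_girvan_q(self.model.graph, p, self.model.deg)

    def compare(self, other: Partition) -> float:
        """NVI distance to another partition of the same graph."""
        return nvi(self.partition, other)

    def summary(self) -> str:
        h = self.hierarchy
        lines = [
            "Generalized modularity agglomeration",
            "=" * 44,
            f"dataset:            {self.model.name}",
            f"variant:            {self.model.variant.upper()}",
            f"nodes, edge mass:   {self.model.graph.n}, "
            f"{self.model.deg.two_m / 2:g}",
            f"communities:        {self.n_communities}",
            f"Q (Newman-Girvan):  {self.q_ng:.4f}",
            f"coarsening levels:  {len(h.levels)}",
            f"sigma trace:        "
            + ", ".join(f"{s:.3f}" for s in self.sigma_trace),
        ]
        return "\n".join(lines)


class EnsembleResults:
    """Replica statistics of a stochastic ensemble."""

    def __init__(self, model: GeneralizedModularity,
                 summary: ExperimentSummary):
        self.model = model
        self.experiment = summary
        self.q_mean = summary.q_mean
        self.q_sd = summary.q_sd
        self.partitions = summary.partitions

    def nvi_quadruplet(self):
        s = self.experiment
        return (s.nvi_mean, s.nvi_var, s.nvi_min, s.nvi_max)

    def summary(self) -> str:
        s = self.experiment
        lines = [
            "Stochastic generalized modularity ensemble",
            "=" * 44,
            f"dataset:          {s.dataset}",
            f"variant:          {s.variant.upper()}  ({s.runs} runs)",
            f"sigma:            {s.sigma}",
            f"Q mean (min,max): {s.q_mean:.4f}  "
            f"({s.q_min:.4f}, {s.q_max:.4f})",
            f"Q sd:             {s.q_sd:.4f}",
            f"communities:      mean {s.communities_mean:.2f}, "
            f"range ({s.communities_min}, {s.communities_max}), "
            f"modal {s.communities_modal}",
            f"NVI quadruplet:   ({s.nvi_mean:.4f}, {s.nvi_var:.4f}, "
            f"{s.nvi_min:.4f}, {s.nvi_max:.4f})",
            f"total runtime:    {s.total_runtime:.2f} s",
        ]
        return "\n".join(lines)

    def plot_histogram(self, path):
        report(self.experiment, fmt="json", hist=path)

    def to_report(self, fmt: str = "json", path=None) -> str:
        return report(self.experiment, fmt=fmt, path=path)
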