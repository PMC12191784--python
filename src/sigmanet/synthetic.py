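"""Seedable fixture graphs: planted partitions and small named graphs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import Graph, Partition, largest_component
from scipy.sparse.csgraph import connected_components

__all__ = ["PlantedSpec", "planted_partition", "named_graph", "NAMED_GRAPHS"]


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted-partition (equal-block SBM) graph.

    Within-community pairs are edges with probability ``p_in``,
    cross-community pairs with ``p_out < p_in``.
    """

    n_communities: int = 4
    community_size: int = 25
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int | None = None

    def __post_init__(self):
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.community_size < 2:
            raise ValueError("community_size must be >= 2")


def planted_partition(spec: PlantedSpec, keep_largest: bool = True):
    """Sample a planted-partition graph and its ground-truth labels.

    Returns ``(Graph, Partition)``.  If the sample is disconnected and
    ``keep_largest`` is set, the largest component is returned with the
    planted labels restricted to it; otherwise the full (possibly
    disconnected) graph is returned.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_communities * spec.community_size
    blocks = np.repeat(np.arange(spec.n_communities), spec.community_size)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(blocks[iu] == blocks[ju], spec.p_in, spec.p_out)
    mask = rng.random(len(p)) < p
    if not mask.any():
        raise ValueError("sampled graph has no edges; increase p_in")
    g = Graph.from_edges(iu[mask], ju[mask], n=n)
    labels = blocks
    if keep_largest:
        ncomp, comp = connected_components(g.adjacency, directed=False)
        if ncomp > 1:
            g2 = largest_component(g)
            keep = np.isin(np.arange(n), g2.node_ids.astype(np.int64))
            labels = blocks[keep]
            g = g2
    return g, Partition(labels)


def _from_pairs(pairs):
    u, v = zip(*pairs)
    return Graph.from_edges(np.asarray(u), np.asarray(v))


def _barbell6():
    # two triangles {0,1,2} and {3,4,5} joined by the bridge 2-3
    return _from_pairs([(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (3, 5), (4, 5)])


def _two_k4_bridge():
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    pairs += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
    pairs.append((3, 4))
    return _from_pairs(pairs)


NAMED_GRAPHS = {
    "triangle": lambda: _from_pairs([(0, 1), (0, 2), (1, 2)]),
    "k2": lambda: _from_pairs([(0, 1)]),
    "barbell6": _barbell6,
    "two_k4_bridge": _two_k4_bridge,
}


def named_graph(name: str) -> Graph:
    """Small worked-example graphs used throughout the test suite."""
    try:
        return NAMED_GRAPHS[name]()
    except KeyError:
        raise ValueError(
            f"unknown graph {name!r}; choose from {sorted(NAMED_GRAPHS)}"
        ) from None
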