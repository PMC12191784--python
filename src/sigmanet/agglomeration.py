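"""Hierarchical agglomeration by mutual-pointer pair merging.

One coarsening round on the current (super)graph:

1. build the generalized modularity parameters for the chosen variant,
   drawing a fresh resolution parameter sigma in stochastic mode;
2. compute the merge-gain matrix dQ with entries 2(e_ij - a_i a_j);
3. pointer vector: each supernode points at the neighbour with the
   largest positive gain (lowest index on ties), or -1 if none;
4. merge exactly the pairs that point at each other;
5. coarsen: A^c = R A R^T, k^c = R k, where R is the 0/1 grouping matrix.

Rounds repeat until no positive gain remains (or a single supernode is
left).  For the resolution-free part of the measure only adjacency-based
gains can be positive (non-adjacent pairs have dQ = -2 a_i a_j <= 0), so
the pointer search touches edges only and a round is near-linear in the
edge count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import DegreeVector, Graph, Partition, degree_vector
from .modularity import (
    delta_q_matrix,
    init_aggregates,
    make_params,
    newman_girvan_q,
)

__all__ = [
    "PointerVector",
    "CoarseningMatrix",
    "Hierarchy",
    "pointer_vector",
    "mutual_pairs",
    "coarsen",
    "restrict_dq",
    "run_agglomeration",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PointerVector:
    """Per-supernode preferred merge partner; -1 means no positive gain."""

    p: np.ndarray


@dataclass(frozen=True)
class CoarseningMatrix:
    """One round's grouping of supernodes into merged pairs / singletons.

    ``groups[i]`` lists the member indices of coarse node ``i`` (size 1
    or 2); groups are ordered by ascending minimum member index.  ``R``
    is the equivalent 0/1 matrix with one row per coarse node.
    """

    groups: tuple[tuple[int, ...], ...]

    @property
    def n_coarse(self) -> int:
        return len(self.groups)

    @property
    def n_fine(self) -> int:
        return sum(len(g) for g in self.groups)

    def matrix(self) -> sp.csr_array:
        rows = np.repeat(np.arange(self.n_coarse),
                         [len(g) for g in self.groups])
        cols = np.concatenate([np.asarray(g) for g in self.groups])
        return sp.csr_array(
            (np.ones(len(cols)), (rows, cols)), shape=(self.n_coarse, self.n_fine)
        )

    def fine_to_coarse(self) -> np.ndarray:
        out = np.empty(self.n_fine, dtype=np.int64)
        for i, g in enumerate(self.groups):
            for j in g:
                out[j] = i
        return out


@dataclass(frozen=True)
class LevelRecord:
    """Bookkeeping for one coarsening round."""

    sigma: float
    n_before: int
    n_after: int
    n_merges: int
    coarse_q: float  # Q_gen of the singleton partition of the coarse graph
    coarsening: CoarseningMatrix


@dataclass
class Hierarchy:
    """Full output of one agglomeration run."""

    levels: list[LevelRecord]
    final_partition: Partition
    variant: str
    sigma_trace: list[float]
    q_ng: float

    @property
    def n_communities(self) -> int:
        return self.final_partition.n_communities

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "sigma_trace": self.sigma_trace,
            "n_communities": int(self.n_communities),
            "q_ng": self.q_ng,
            "levels": [
                {
                    "sigma": lv.sigma,
                    "n_before": lv.n_before,
                    "n_after": lv.n_after,
                    "n_merges": lv.n_merges,
                    "coarse_q": lv.coarse_q,
                }
                for lv in self.levels
            ],
            "labels": self.final_partition.labels.tolist(),
        }


def pointer_vector(dq: np.ndarray) -> PointerVector:
    """Row-wise argmax of positive merge gains, lowest index on ties.

    Each row is independent (the computation parallelizes trivially);
    rows whose off-diagonal gains are all nonpositive point to -1.
    """
    c = dq.shape[0]
    masked = dq.copy()
    np.fill_diagonal(masked, -np.inf)
    best = np.argmax(masked, axis=1)  # np.argmax takes the first maximum
    p = np.where(masked[np.arange(c), best] > 0, best, -1)
    return PointerVector(p.astype(np.int64))


def _sparse_pointer(e_off: sp.csr_array, a: np.ndarray) -> np.ndarray:
    """Pointer vector touching only adjacency-support pairs.

    Exact for diagonal W: a non-adjacent pair has dQ = -2 a_i a_j <= 0,
    so the positive maximum (if any) is attained on an edge.
    """
    c = e_off.shape[0]
    p = np.full(c, -1, dtype=np.int64)
    indptr, indices, data = e_off.indptr, e_off.indices, e_off.data
    for i in range(c):
        lo, hi = indptr[i], indptr[i + 1]
        if lo == hi:
            continue
        cols = indices[lo:hi]
        keep = cols != i
        cols = cols[keep]
        if not len(cols):
            continue
        gains = 2.0 * (data[lo:hi][keep] - a[i] * a[cols])
        jbest = int(np.argmax(gains))
        # argmax returns the first maximum; csr columns are sorted, so
        # this is already the lowest-index tie-break
        if gains[jbest] > 0:
            p[i] = cols[jbest]
    return p


def mutual_pairs(p: PointerVector | np.ndarray) -> CoarseningMatrix:
    """Group supernodes: pairs that point at each other merge, rest stay."""
    vec = p.p if isinstance(p, PointerVector) else np.asarray(p)
    c = len(vec)
    taken = np.zeros(c, dtype=bool)
    groups: list[tuple[int, ...]] = []
    for i in range(c):
        if taken[i]:
            continue
        j = vec[i]
        if j >= 0 and not taken[j] and vec[j] == i:
            groups.append((i, int(j)) if i < j else (int(j), i))
            taken[i] = taken[j] = True
        else:
            groups.append((i,))
            taken[i] = True
    return CoarseningMatrix(tuple(groups))


def coarsen(g: Graph, deg: DegreeVector, r: CoarseningMatrix):
    """A^c = R A R^T and k^c = R k; total mass is conserved."""
    R = r.matrix()
    ac = sp.csr_array(R @ g.adjacency @ R.T)
    ac.sum_duplicates()
    kc = R @ deg.k
    gc = Graph(ac, np.arange(r.n_coarse))
    return gc, DegreeVector(k=np.asarray(kc).ravel(), two_m=deg.two_m)


def restrict_dq(dq: np.ndarray, r: CoarseningMatrix) -> np.ndarray:
    """Coarse merge-gain matrix R dQ R^T; valid for a fixed measure.

    Restriction of the fine gains equals the recomputed coarse gains
    only when the modularity parameters do not change across the round
    (fixed sigma, W = 0); stochastic and AFG runs recompute instead.
    """
    R = r.matrix()
    out = np.asarray((R @ sp.csr_array(dq) @ R.T).todense())
    np.fill_diagonal(out, 0.0)
    return out


def _compose(levels: list[LevelRecord], n: int) -> Partition:
    labels = np.arange(n)
    for lv in levels:
        labels = lv.coarsening.fine_to_coarse()[labels]
    return Partition(labels)


def run_agglomeration(
    g: Graph,
    variant: str = "ng",
    sigma: float | None = None,
    rng: np.random.Generator | int | None = None,
    sigma_interval: tuple[float, float] | None = None,
    sigma_per: str = "level",
    dq_mode: str = "recompute",
    max_rounds: int | None = None,
) -> Hierarchy:
    """Run the full hierarchical agglomeration on a graph.

    Parameters
    ----------
    variant : {"ng", "rb", "afg"}
        Which generalized modularity model to optimize.
    sigma : float, optional
        Fixed resolution parameter (deterministic run).  Exactly one of
        ``sigma`` and ``sigma_interval`` must be given for RB/AFG; NG
        ignores both.
    sigma_interval : (low, high), optional
        Stochastic mode: sigma ~ Uniform(low, high), redrawn per
        coarsening level (``sigma_per="level"``) or once per run
        (``sigma_per="run"``).
    rng : numpy Generator or seed
        Randomness source for stochastic mode.
    dq_mode : {"recompute", "restrict"}
        "recompute" rebuilds gains from the coarse graph each round
        (always correct).  "restrict" propagates the fine-level gain
        matrix through R dQ R^T; only permitted for fixed-sigma runs of
        the W = 0 variants (NG/RB), where the two are identical.

    Returns
    -------
    Hierarchy
        Levels, sigma trace, and the final partition of the original
        nodes, scored by normalized Newman-Girvan modularity.
    """
    variant = variant.lower()
    stochastic = sigma_interval is not None
    if variant == "ng":
        stochastic = False
        sigma = 1.0
    elif stochastic and sigma is not None:
        raise ValueError("give either sigma or sigma_interval, not both")
    elif not stochastic and sigma is None:
        raise ValueError(f"{variant} needs sigma or sigma_interval")
    if dq_mode not in ("recompute", "restrict"):
        raise ValueError(f"unknown dq_mode {dq_mode!r}")
    if dq_mode == "restrict" and (stochastic or variant == "afg"):
        raise ValueError("dq_mode='restrict' requires fixed sigma and W = 0 (NG/RB)")

    rng = np.random.default_rng(rng)
    if stochastic and sigma_per not in ("level", "run"):
        raise ValueError("sigma_per must be 'level' or 'run'")
    if stochastic and sigma_per == "run":
        sigma = float(rng.uniform(*sigma_interval))
        stochastic_levels = False
    else:
        stochastic_levels = stochastic

    gc, deg = g, degree_vector(g)
    levels: list[LevelRecord] = []
    trace: list[float] = []
    dq_dense: np.ndarray | None = None
    n_rounds = 0
    limit = max_rounds if max_rounds is not None else g.n + 1

    while gc.n > 1 and n_rounds < limit:
        n_rounds += 1
        sig = float(rng.uniform(*sigma_interval)) if stochastic_levels else float(sigma)
        params = make_params(gc, variant, sig, deg=deg)
        a = np.sqrt(params.sigma_gen) * params.k_tilde
        if dq_mode == "restrict" and dq_dense is not None:
            dq = dq_dense
            if not np.all(np.isfinite(dq)):
                raise FloatingPointError("non-finite merge gains")
            p = pointer_vector(dq).p
        else:
            # off-diagonal e equals the coarse adjacency for diagonal W
            p = _sparse_pointer(gc.adjacency, a)
        r = mutual_pairs(PointerVector(p))
        if r.n_coarse == gc.n:
            # no mutual pair: only possible through float asymmetry,
            # since the global max positive pair always points mutually
            pair = _global_best_pair(gc.adjacency, a)
            if pair is None:
                break  # no positive gain anywhere: done
            logger.warning("stall guard: merging single best pair %s", pair)
            groups = [(i,) for i in range(gc.n) if i not in pair]
            groups.append(tuple(sorted(pair)))
            groups.sort(key=min)
            r = CoarseningMatrix(tuple(tuple(x) for x in groups))
        if dq_mode == "restrict":
            if dq_dense is None:
                dq_dense = delta_q_matrix(init_aggregates(gc, params))
            dq_dense = restrict_dq(dq_dense, r)
        gc, deg = coarsen(gc, deg, r)
        params_c = make_params(gc, variant, sig, deg=deg)
        coarse_q = float(
            gc.adjacency.diagonal().sum()
            + params_c.w_diag.sum()
            - params_c.sigma_gen * float(params_c.k_tilde @ params_c.k_tilde)
        )
        levels.append(
            LevelRecord(sig, r.n_fine, r.n_coarse, r.n_fine - r.n_coarse,
                        coarse_q, r)
        )
        trace.append(sig)

    part = _compose(levels, g.n).relabel()
    return Hierarchy(
        levels=levels,
        final_partition=part,
        variant=variant,
        sigma_trace=trace,
        q_ng=newman_girvan_q(g, part),
    )


def _global_best_pair(adj: sp.csr_array, a: np.ndarray):
    """Lexicographically first pair attaining the global max positive gain."""
    coo = sp.coo_array(adj)
    mask = coo.row < coo.col
    if not mask.any():
        return None
    rows, cols, w = coo.row[mask], coo.col[mask], coo.data[mask]
    gains = 2.0 * (w - a[rows] * a[cols])
    best = gains.max()
    if best <= 0:
        return None
    cand = np.flatnonzero(gains == best)
    order = np.lexsort((cols[cand], rows[cand]))
    i = cand[order[0]]
    return int(rows[i]), int(cols[i])
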