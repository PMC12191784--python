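"""Generalized modularity matrices and merge-gain machinery.

A generalized modularity matrix is ``M = A + W - sigma * k~ k~^T`` with
``W`` diagonal, ``k~`` a nonzero nonnegative vector and ``sigma > 0``.
The associated (unnormalized) measure of a partition P is

    Q = sum_{u,v} (A_uv + W_uv - sigma k~_u k~_v) delta(c_u, c_v)
      = sum_{i in P} (e_ii - a_i^2),

where ``e_ij`` is the (A+W)-mass between communities i and j and
``a_i = sqrt(sigma) * sum_{u in i} k~_u``.  The square-root convention in
``a_i`` is what makes the two forms and all merge identities
(``e_(ij)(ij) = e_ii + e_jj + 2 e_ij``, ``a_(ij) = a_i + a_j``,
``dQ(ij) = 2(e_ij - a_i a_j)``) hold simultaneously.

Three standard instantiations are provided:

NG   Newman-Girvan: W = 0, k~ = k, sigma = 1/(2m).
RB   Reichardt-Bornholdt: W = 0, k~ = k, sigma = sigma_user/(2m).
AFG  Arenas-Fernandez-Gomez: W = sigma_user*I, k~ = k + sigma_user*1,
     sigma = 1/(sigma_user*n + 2m).

The user-facing resolution parameter sigma_user is recorded separately
from the generic ``sigma_gen`` of the canonical form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import DegreeVector, Graph, Partition, degree_vector

__all__ = [
    "ModularityParams",
    "CommunityAggregates",
    "make_params",
    "modularity_measure",
    "newman_girvan_q",
    "init_aggregates",
    "delta_q",
    "delta_q_matrix",
    "spectral_bipartition",
]

VARIANTS = ("ng", "rb", "afg")

_DENSE_EIG_LIMIT = 5000


@dataclass(frozen=True)
class ModularityParams:
    """One concrete generalized modularity matrix M = A + W - sigma k~ k~^T.

    Attributes
    ----------
    w_diag : numpy.ndarray
        Diagonal of W (length n).
    k_tilde : numpy.ndarray
        The null-model vector k~ (length n, nonnegative, not all zero).
    sigma_gen : float
        The positive scalar of the canonical form.
    variant : str
        "ng", "rb", "afg", or "custom".
    variant_sigma : float
        The user-facing resolution parameter that produced these params
        (recorded for provenance; 1.0 for NG).
    """

    w_diag: np.ndarray
    k_tilde: np.ndarray
    sigma_gen: float
    variant: str = "custom"
    variant_sigma: float = float("nan")

    def __post_init__(self):
        if not self.sigma_gen > 0:
            raise ValueError(f"sigma_gen must be positive, got {self.sigma_gen}")
        kt = np.asarray(self.k_tilde, dtype=float)
        if kt.min() < 0 or not kt.max() > 0:
            raise ValueError("k_tilde must be nonnegative with a positive entry")
        object.__setattr__(self, "k_tilde", kt)
        object.__setattr__(self, "w_diag", np.asarray(self.w_diag, dtype=float))
        if len(self.w_diag) != len(kt):
            raise ValueError("w_diag and k_tilde length mismatch")


@dataclass(frozen=True)
class CommunityAggregates:
    """Per-community mass matrix e and null vector a for a partition.

    ``e[i, j]`` is the total (A+W) weight between communities i and j;
    ``a[i] = sqrt(sigma_gen) * sum of k~ over community i``.
    """

    e: np.ndarray
    a: np.ndarray

    @property
    def n_communities(self) -> int:
        return len(self.a)

    def q(self) -> float:
        """Q = sum_i (e_ii - a_i^2)."""
        return float(np.trace(self.e) - self.a @ self.a)


def make_params(g: Graph, variant: str, sigma: float = 1.0,
                deg: DegreeVector | None = None) -> ModularityParams:
    """Instantiate NG / RB / AFG parameters on a graph.

    ``sigma`` is the resolution parameter of the RB and AFG models; it is
    ignored for NG (the NG matrix has no free parameter).
    """
    variant = variant.lower()
    deg = deg or degree_vector(g)
    k, two_m = deg.k, deg.two_m
    if two_m <= 0:
        raise ValueError("graph has no edge mass (2m = 0)")
    n = g.n
    if variant == "ng":
        return ModularityParams(np.zeros(n), k, 1.0 / two_m, "ng", 1.0)
    if variant == "rb":
        if sigma <= 0:
            raise ValueError("RB requires sigma > 0")
        return ModularityParams(np.zeros(n), k, sigma / two_m, "rb", sigma)
    if variant == "afg":
        denom = sigma * n + two_m
        if denom <= 0:
            raise ValueError(f"AFG requires sigma*n + 2m > 0, got {denom}")
        return ModularityParams(
            np.full(n, float(sigma)), k + sigma, 1.0 / denom, "afg", sigma
        )
    raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")


def _indicator(p: Partition) -> sp.csr_array:
    """n x c one-hot community membership matrix."""
    labels = p.relabel().labels
    c = labels.max() + 1
    n = len(labels)
    return sp.csr_array(
        (np.ones(n), (np.arange(n), labels)), shape=(n, int(c))
    )


def modularity_measure(g: Graph, p: Partition, params: ModularityParams) -> float:
    """Unnormalized generalized modularity of a partition (double-sum form)."""
    if p.n != g.n or len(params.k_tilde) != g.n:
        raise ValueError("partition / params / graph dimension mismatch")
    s = _indicator(p)
    aw = s.T @ g.adjacency @ s
    within_aw = float(aw.diagonal().sum()) + float(
        np.bincount(p.relabel().labels, weights=params.w_diag).sum()
    )
    ksum = s.T @ params.k_tilde
    return within_aw - params.sigma_gen * float(ksum @ ksum)


def newman_girvan_q(g: Graph, p: Partition, deg: DegreeVector | None = None) -> float:
    """Standard Newman-Girvan modularity, normalized by 2m (in [-1, 1])."""
    deg = deg or degree_vector(g)
    if deg.two_m <= 0:
        raise ValueError("Newman-Girvan modularity undefined for 2m = 0")
    params = make_params(g, "ng", deg=deg)
    return modularity_measure(g, p, params) / deg.two_m


def init_aggregates(g: Graph, params: ModularityParams,
                    p: Partition | None = None) -> CommunityAggregates:
    """Community aggregates (e, a) for a partition (default: all singletons)."""
    if p is None:
        p = Partition(np.arange(g.n))
    s = _indicator(p)
    e = (s.T @ g.adjacency @ s).toarray()
    labels = p.relabel().labels
    e[np.diag_indices_from(e)] += np.bincount(labels, weights=params.w_diag)
    a = np.sqrt(params.sigma_gen) * (s.T @ params.k_tilde)
    return CommunityAggregates(e=e, a=np.asarray(a).ravel())


def delta_q(agg: CommunityAggregates, i: int, j: int) -> float:
    """Modularity gain from merging communities i and j: 2(e_ij - a_i a_j)."""
    if i == j:
        raise ValueError("cannot merge a community with itself")
    return 2.0 * (agg.e[i, j] - agg.a[i] * agg.a[j])


def delta_q_matrix(agg: CommunityAggregates) -> np.ndarray:
    """Symmetric matrix of pairwise merge gains; diagonal fixed at 0."""
    dq = 2.0 * (agg.e - np.outer(agg.a, agg.a))
    np.fill_diagonal(dq, 0.0)
    return dq


def dense_modularity_matrix(g: Graph, params: ModularityParams) -> np.ndarray:
    """Materialize M = A + W - sigma k~ k~^T (dense; validation use only)."""
    m = g.adjacency.toarray().astype(float)
    m[np.diag_indices_from(m)] += params.w_diag
    m -= params.sigma_gen * np.outer(params.k_tilde, params.k_tilde)
    return m


def spectral_bipartition(g: Graph, params: ModularityParams):
    """Leading-eigenvector two-way split of the generalized modularity matrix.

    Returns ``(s, lam, q_relaxed)``: the sign vector of the leading
    eigenvector (zero entries mapped to +1), the largest eigenvalue
    ``lam`` of M, and the relaxed optimum ``q_relaxed = n * lam / 2``.
    This is a validation tool for small graphs, not the production
    detection path.
    """
    if g.n < 2:
        raise ValueError("spectral bipartition needs n >= 2")
    if g.n > _DENSE_EIG_LIMIT:
        raise ValueError(f"dense eigenproblem limited to n <= {_DENSE_EIG_LIMIT}")
    m = dense_modularity_matrix(g, params)
    vals, vecs = np.linalg.eigh(m)
    lam = float(vals[-1])
    lead = vecs[:, -1]
    s = np.where(lead < 0, -1, 1).astype(np.int64)
    return s, lam, g.n * lam / 2.0
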