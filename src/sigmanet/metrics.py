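"""Partition comparison: normalized variation of information.

VI(P1, P2) = H(P1|P2) + H(P2|P1), computed from the contingency table
with natural logarithms and normalized by log n, so that identical
partitions score 0 and the extreme pair (all singletons vs one block)
scores exactly 1.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .graph import Partition

__all__ = ["contingency_table", "nvi", "nvi_quadruplet", "community_count"]


def contingency_table(p1: Partition, p2: Partition) -> np.ndarray:
    """c1 x c2 matrix of shared node counts between two partitions."""
    if p1.n != p2.n:
        raise ValueError("partitions cover different node sets")
    l1 = p1.relabel().labels
    l2 = p2.relabel().labels
    c1, c2 = l1.max() + 1, l2.max() + 1
    t = sp.coo_array(
        (np.ones(p1.n), (l1, l2)), shape=(int(c1), int(c2))
    ).todense()
    return np.asarray(t)


def nvi(p1: Partition, p2: Partition) -> float:
    """Normalized variation of information in [0, 1].

    0 iff the two partitions are identical up to label renaming; the
    all-singletons vs single-block pair attains 1.
    """
    n = p1.n
    if n <= 1:
        return 0.0
    t = contingency_table(p1, p2)
    pij = t / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    # VI = H(P1) + H(P2) - 2 I(P1; P2)
    h1 = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
    h2 = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
    mi = np.sum(pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz]))
    vi = max(h1 + h2 - 2.0 * mi, 0.0)
    return float(vi / np.log(n))


def nvi_quadruplet(partitions: list[Partition]):
    """(mean, variance, min, max) of NVI over all unordered pairs.

    Variance is the population variance of the pairwise values.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    vals = [
        nvi(partitions[i], partitions[j])
        for i in range(len(partitions))
        for j in range(i + 1, len(partitions))
    ]
    vals = np.asarray(vals)
    return (
        float(vals.mean()),
        float(vals.var()),
        float(vals.min()),
        float(vals.max()),
    )


def community_count(p: Partition) -> int:
    return p.n_communities
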