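"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own aggregate-based
code paths: modularity is evaluated as an explicit double sum over the
dense matrix, and optimal partitions come from exhaustive enumeration
of all set partitions (restricted-growth strings).
"""

import itertools

import numpy as np
import pytest

from sigmanet import (
    Graph,
    Partition,
    degree_vector,
    make_params,
    named_graph,
)


def brute_force_q(g, labels, params):
    """Q as the literal double sum over all node pairs."""
    a = g.adjacency.toarray().astype(float)
    m = a + np.diag(params.w_diag)
    m = m - params.sigma_gen * np.outer(params.k_tilde, params.k_tilde)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(m[same].sum())


def brute_force_q_ng(g, labels):
    d = degree_vector(g)
    params = make_params(g, "ng", deg=d)
    return brute_force_q(g, labels, params) / d.two_m


def all_set_partitions(n):
    """Every partition of range(n) as a label vector (Bell enumeration)."""
    def grow(prefix, k):
        if len(prefix) == n:
            yield np.array(prefix)
            return
        for c in range(k + 1):
            yield from grow(prefix + [c], max(k, c + 1))
    yield from grow([0], 1)


def exhaustive_best_q_ng(g):
    """Global optimum of Newman-Girvan modularity by enumeration."""
    best = -np.inf
    best_labels = None
    for labels in all_set_partitions(g.n):
        q = brute_force_q_ng(g, labels)
        if q > best:
            best, best_labels = q, labels
    return best, Partition(best_labels)


def random_connected_graph(rng, n, p=0.5, weighted=False):
    """Connected Erdos-Renyi graph; a random spanning tree guarantees
    connectivity, extra edges are added with probability p."""
    order = rng.permutation(n)
    edges = {(min(order[i], order[i - 1]), max(order[i], order[i - 1]))
             for i in range(1, n)}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((i, j))
    u, v = map(np.array, zip(*sorted(edges)))
    w = rng.uniform(0.5, 2.0, len(u)) if weighted else None
    return Graph.from_edges(u, v, w)


def random_partition(rng, n, c=None):
    c = c or rng.integers(1, n + 1)
    labels = rng.integers(0, c, n)
    labels[rng.integers(0, n)] = 0  # community 0 always nonempty
    return Partition(labels)


def random_params(rng, g):
    """A random valid generalized modularity parameter set."""
    choice = rng.integers(0, 4)
    if choice < 3:
        return make_params(g, ["ng", "rb", "afg"][choice],
                           sigma=float(rng.uniform(0.2, 2.5)))
    from sigmanet import ModularityParams
    return ModularityParams(
        w_diag=rng.uniform(0, 1, g.n),
        k_tilde=rng.uniform(0.1, 2, g.n),
        sigma_gen=float(rng.uniform(0.05, 1.0)),
    )


@pytest.fixture
def barbell6():
    return named_graph("barbell6")


@pytest.fixture
def triangle():
    return named_graph("triangle")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
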