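"""Generalized modularity: variants, measures, merge gains, spectra."""

import numpy as np
import pytest

import sigmanet as sn
from sigmanet import ModularityParams, Partition

from conftest import (
    brute_force_q,
    brute_force_q_ng,
    exhaustive_best_q_ng,
    random_connected_graph,
    random_params,
    random_partition,
)


class TestMakeParams:
    def test_rb_triangle(self, triangle):
        p = sn.make_params(triangle, "rb", 1.0)
        assert p.sigma_gen == pytest.approx(1 / 6)
        assert np.allclose(p.w_diag, 0)
        assert np.allclose(p.k_tilde, [2, 2, 2])

    def test_afg_triangle(self, triangle):
        p = sn.make_params(triangle, "afg", 1.0)
        assert np.allclose(p.w_diag, 1.0)
        assert np.allclose(p.k_tilde, [3, 3, 3])
        assert p.sigma_gen == pytest.approx(1 / 9)

    def test_afg_sigma_zero_is_ng(self, triangle):
        afg = sn.make_params(triangle, "afg", 0.0)
        ng = sn.make_params(triangle, "ng")
        assert np.allclose(afg.w_diag, ng.w_diag)
        assert np.allclose(afg.k_tilde, ng.k_tilde)
        assert afg.sigma_gen == pytest.approx(ng.sigma_gen)

    def test_afg_continuity_at_zero(self, barbell6):
        ng = sn.make_params(barbell6, "ng")
        for s in (1e-3, 1e-6):
            afg = sn.make_params(barbell6, "afg", s)
            assert np.allclose(afg.k_tilde, ng.k_tilde, atol=2 * s)
            assert afg.sigma_gen == pytest.approx(ng.sigma_gen, rel=1e-2)

    def test_invalid_sigma_rejected(self, triangle):
        with pytest.raises(ValueError):
            sn.make_params(triangle, "rb", -1.0)
        with pytest.raises(ValueError):
            sn.make_params(triangle, "afg", -3.0)  # sigma*n + 2m < 0

    def test_rb_sigma_one_is_ng(self, barbell6):
        rb = sn.make_params(barbell6, "rb", 1.0)
        ng = sn.make_params(barbell6, "ng")
        assert rb.sigma_gen == ng.sigma_gen
        assert np.allclose(rb.k_tilde, ng.k_tilde)


class TestModularityMeasure:
    def test_triangle_examples(self, triangle):
        ng = sn.make_params(triangle, "ng")
        assert sn.modularity_measure(triangle, Partition([0, 0, 0]), ng) == \
            pytest.approx(0.0)
        assert sn.modularity_measure(triangle, Partition([0, 1, 2]), ng) == \
            pytest.approx(-2.0)

    def test_barbell_two_triangles(self, barbell6):
        ng = sn.make_params(barbell6, "ng")
        p = Partition([0, 0, 0, 1, 1, 1])
        assert sn.modularity_measure(barbell6, p, ng) == pytest.approx(5.0)
        assert sn.newman_girvan_q(barbell6, p) == pytest.approx(5 / 14)

    def test_ng_examples(self, triangle):
        assert sn.newman_girvan_q(triangle, Partition([0, 0, 0])) == 0.0
        assert sn.newman_girvan_q(triangle, Partition([0, 1, 2])) == \
            pytest.approx(-1 / 3)

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(30):
            g = random_connected_graph(rng, int(rng.integers(3, 20)),
                                       weighted=bool(rng.integers(2)))
            params = random_params(rng, g)
            p = random_partition(rng, g.n)
            assert sn.modularity_measure(g, p, params) == pytest.approx(
                brute_force_q(g, p.labels, params), rel=1e-9, abs=1e-9
            )

    def test_ng_matches_textbook_formula(self, rng):
        # Q = sum_i (l_i/m - (d_i/2m)^2) on unweighted graphs
        for _ in range(10):
            g = random_connected_graph(rng, int(rng.integers(4, 15)))
            p = random_partition(rng, g.n)
            a = g.adjacency.toarray()
            k = a.sum(1)
            two_m = k.sum()
            q = 0.0
            for c in np.unique(p.labels):
                mask = p.labels == c
                q += a[np.ix_(mask, mask)].sum() / two_m - (k[mask].sum() / two_m) ** 2
            assert sn.newman_girvan_q(g, p) == pytest.approx(q, rel=1e-9)

    def test_dimension_mismatch(self, triangle):
        ng = sn.make_params(triangle, "ng")
        with pytest.raises(ValueError):
            sn.modularity_measure(triangle, Partition([0, 1]), ng)


class TestAggregatesAndGains:
    def test_singleton_aggregates_triangle(self, triangle):
        ng = sn.make_params(triangle, "ng")
        agg = sn.init_aggregates(triangle, ng)
        assert np.allclose(agg.e, [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        assert np.allclose(agg.a, np.array([2, 2, 2]) / np.sqrt(6))

    def test_singleton_aggregates_afg(self, triangle):
        afg = sn.make_params(triangle, "afg", 1.0)
        agg = sn.init_aggregates(triangle, afg)
        assert np.allclose(np.diag(agg.e), 1.0)
        assert np.allclose(agg.a, 1.0)

    def test_merged_diagonal_identity(self, triangle):
        # e_(12)(12) = e_11 + e_22 + 2 e_12
        ng = sn.make_params(triangle, "ng")
        singles = sn.init_aggregates(triangle, ng)
        merged = sn.init_aggregates(triangle, ng, Partition([0, 0, 1]))
        assert merged.e[0, 0] == pytest.approx(
            singles.e[0, 0] + singles.e[1, 1] + 2 * singles.e[0, 1]
        )
        assert merged.e[0, 0] == pytest.approx(2.0)

    def test_delta_q_examples(self, triangle, barbell6):
        ng = sn.make_params(triangle, "ng")
        agg = sn.init_aggregates(triangle, ng)
        assert sn.delta_q(agg, 0, 1) == pytest.approx(2 / 3)
        aggb = sn.init_aggregates(barbell6, sn.make_params(barbell6, "ng"))
        assert sn.delta_q(aggb, 2, 3) == pytest.approx(5 / 7)

    def test_delta_q_same_community_rejected(self, triangle):
        agg = sn.init_aggregates(triangle, sn.make_params(triangle, "ng"))
        with pytest.raises(ValueError):
            sn.delta_q(agg, 1, 1)

    def test_nonadjacent_gain_negative(self):
        g = sn.Graph.from_edges([0, 1, 2], [1, 2, 3])
        agg = sn.init_aggregates(g, sn.make_params(g, "ng"))
        assert sn.delta_q(agg, 0, 3) < 0

    def test_delta_q_matrix_barbell(self, barbell6):
        dq = sn.delta_q_matrix(
            sn.init_aggregates(barbell6, sn.make_params(barbell6, "ng"))
        )
        assert np.allclose(dq, dq.T)
        assert np.allclose(np.diag(dq), 0)
        assert dq[0, 1] == pytest.approx(10 / 7)   # deg2-deg2 in a triangle
        assert dq[0, 2] == pytest.approx(8 / 7)    # deg2-deg3
        assert dq[2, 3] == pytest.approx(5 / 7)    # bridge
        assert dq[0, 4] < 0                         # non-adjacent

    def test_delta_q_matrix_triangle_uniform(self, triangle):
        dq = sn.delta_q_matrix(
            sn.init_aggregates(triangle, sn.make_params(triangle, "ng"))
        )
        off = dq[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 2 / 3)

    def test_merge_identities_random(self, rng):
        # a_(ij) = a_i + a_j; e_i(jk) = e_ij + e_ik;
        # dQ(ij) = Q(merged) - Q(before); dQ(i,(jk)) = dQ(ij) + dQ(ik)
        for _ in range(25):
            g = random_connected_graph(rng, int(rng.integers(5, 25)),
                                       weighted=True)
            params = random_params(rng, g)
            labels = random_partition(rng, g.n, c=min(g.n, 5)).relabel().labels
            c = labels.max() + 1
            if c < 3:
                continue
            agg = sn.init_aggregates(g, params, Partition(labels))
            i, j, k = 0, 1, 2
            merged_jk = labels.copy()
            merged_jk[merged_jk == k] = j
            agg2 = sn.init_aggregates(g, params, Partition(merged_jk))
            # relabelling keeps community order of first appearance
            jj = sorted({0, 1}).index(j)
            assert agg2.a[jj] == pytest.approx(agg.a[j] + agg.a[k], abs=1e-12)
            assert agg2.e[i, jj] == pytest.approx(
                agg.e[i, j] + agg.e[i, k], abs=1e-12
            )
            q_before = sn.modularity_measure(g, Partition(labels), params)
            merged_ij = labels.copy()
            merged_ij[merged_ij == j] = i
            q_after = sn.modularity_measure(g, Partition(merged_ij), params)
            assert sn.delta_q(agg, i, j) == pytest.approx(
                q_after - q_before, rel=1e-9, abs=1e-9
            )
            assert sn.delta_q(agg2, i, jj) == pytest.approx(
                sn.delta_q(agg, i, j) + sn.delta_q(agg, i, k),
                rel=1e-9, abs=1e-9,
            )


class TestSpectral:
    def test_relaxed_q_is_n_lambda_over_2(self, barbell6):
        params = sn.make_params(barbell6, "ng")
        s, lam, q_rel = sn.spectral_bipartition(barbell6, params)
        assert q_rel == barbell6.n * lam / 2

    def test_barbell_split_separates_triangles(self, barbell6):
        params = sn.make_params(barbell6, "ng")
        s, _, _ = sn.spectral_bipartition(barbell6, params)
        assert len(set(s[:3])) == 1 and len(set(s[3:])) == 1
        assert s[0] != s[5]
        # and that split is the exhaustive two-block optimum
        best_q, best_p = exhaustive_best_q_ng(barbell6)
        labels = (np.asarray(s) > 0).astype(int)
        assert brute_force_q_ng(barbell6, labels) == pytest.approx(best_q)

    def test_sign_partition_bounded_by_relaxation(self, rng):
        # Q(sign partition) <= n * lambda / 2 in the centered convention
        for _ in range(20):
            g = random_connected_graph(rng, int(rng.integers(4, 13)))
            params = random_params(rng, g)
            s, lam, q_rel = sn.spectral_bipartition(g, params)
            labels = (np.asarray(s) > 0).astype(int)
            q_sign = brute_force_q(g, labels, params)
            m = g.adjacency.toarray() + np.diag(params.w_diag)
            m -= params.sigma_gen * np.outer(params.k_tilde, params.k_tilde)
            # centered: subtract the partition-independent constant term
            assert q_sign - m.sum() / 2 <= q_rel + 1e-9

    def test_too_small_graph_rejected(self):
        g = sn.Graph.from_edges([0], [0], [1.0])
        with pytest.raises(ValueError):
            sn.spectral_bipartition(g, sn.make_params(g, "ng"))


def test_custom_params_constructor_validation():
    with pytest.raises(ValueError):
        ModularityParams(np.zeros(3), np.zeros(3), 0.5)  # k~ all zero
    with pytest.raises(ValueError):
        ModularityParams(np.zeros(3), np.ones(3), -0.1)  # sigma <= 0
    p = ModularityParams(np.zeros(3), np.ones(3), 0.5)
    assert p.variant == "custom"
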