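"""Signed similarity, soft threshold, TOM and edge export against oracles."""

import numpy as np
import pandas as pd
import pytest

import salinet as sn
from salinet.wgcna_core import AdjacencyMatrix, SimilarityMatrix, _scale_free_fit

from conftest import random_expression


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop signed TOM, independent of the matrix-product path."""
    n = a.shape[0]
    k = [sum(a[u, i] for u in range(n) if u != i) for i in range(n)]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            denom = min(k[i], k[j]) + 1.0 - a[i, j]
            tom[i, j] = (a[i, j] + shared) / denom if denom > 1e-12 else 0.0
    return tom


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


class TestCorrelation:
    def test_duplicate_gene_r_one(self):
        data = pd.DataFrame(
            [[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4.0, 3, 2, 1]],
            index=["a", "b", "c"],
        )
        cor = sn.correlation_matrix(sn.ExpressionMatrix(data))
        assert cor.values[0, 1] == pytest.approx(1.0)
        assert cor.values[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_two_pass_oracle(self, rng):
        m = random_expression(rng, 10, 8)
        cor = sn.correlation_matrix(m)
        X = m.data.to_numpy()
        for i in range(10):
            for j in range(10):
                xi, xj = X[i], X[j]
                mi, mj = xi.mean(), xj.mean()
                cov = ((xi - mi) * (xj - mj)).sum()
                denom = np.sqrt(((xi - mi) ** 2).sum() * ((xj - mj) ** 2).sum())
                assert cor.values[i, j] == pytest.approx(cov / denom, abs=1e-12)

    def test_constant_gene_dropped_with_warning(self):
        data = pd.DataFrame([[1.0, 1, 1, 1], [1.0, 2, 3, 4]], index=["flat", "ok"])
        with pytest.warns(UserWarning, match="constant"):
            cor = sn.correlation_matrix(sn.ExpressionMatrix(data))
        assert cor.gene_ids == ["ok"]

    def test_too_few_samples_rejected(self):
        data = pd.DataFrame([[1.0, 2], [2.0, 1]])
        with pytest.raises(sn.ValidationError):
            sn.correlation_matrix(sn.ExpressionMatrix(data))

    def test_records_sample_count(self, rng):
        m = random_expression(rng, 5, 9)
        assert sn.correlation_matrix(m).n_samples == 9


class TestSignedSimilarity:
    @pytest.mark.parametrize("r,expected", [(0.0, 0.5), (1.0, 1.0), (-1.0, 0.0)])
    def test_analytic_points(self, r, expected):
        assert sn.signed_similarity(r) == pytest.approx(expected)

    def test_bounds_on_grid(self):
        grid = np.linspace(-1, 1, 201)
        s = sn.signed_similarity(grid)
        assert s.max() == pytest.approx(1.0) and s.min() == pytest.approx(0.0)
        assert ((s >= 0) & (s <= 1)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(sn.ValidationError):
            sn.signed_similarity(1.5)


class TestSoftAdjacency:
    def test_power_matches_repeated_multiplication(self):
        s = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        a = sn.soft_adjacency(s, 22)
        expected = 1.0
        for _ in range(22):
            expected *= 0.9
        assert a.values[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_identity_power(self):
        s = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        a = sn.soft_adjacency(s, 1)
        assert a.values[0, 1] == pytest.approx(0.5)
        assert a.values[0, 0] == 0.0  # diagonal zeroed

    def test_monotone_in_beta(self, rng):
        vals = rng.uniform(0, 1, size=(6, 6))
        vals = (vals + vals.T) / 2
        s = SimilarityMatrix(list("abcdef"), vals)
        prev = sn.soft_adjacency(s, 1).values
        for beta in range(2, 12):
            cur = sn.soft_adjacency(s, beta).values
            assert (cur <= prev + 1e-15).all()
            prev = cur


class TestPickSoftThreshold:
    def test_exact_power_law_degree_sequence_fits_well(self):
        # truncated-Pareto connectivities (density exactly k^-2.5 on
        # [1, 30], inverse-CDF on an even grid): near-perfect signed fit
        n, gamma, kmax = 2000, 2.5, 30.0
        u = (np.arange(n) + 0.5) / n
        a = gamma - 1.0
        k = (1.0 - u * (1.0 - kmax**-a)) ** (-1.0 / a)
        assert _scale_free_fit(k) >= 0.95

    def test_degenerate_equal_similarity_reports_zero(self):
        s = SimilarityMatrix(list("abcd"), np.full((4, 4), 0.7))
        with pytest.warns(UserWarning):
            rep = sn.pick_soft_threshold(s, candidates=(1, 2))
        assert all(r == 0.0 for r in rep.r_squared)

    def test_default_fixture_reaches_target(self, default_sim):
        cor = sn.correlation_matrix(sn.ExpressionMatrix(default_sim.expr_a))
        rep = sn.pick_soft_threshold(sn.signed_similarity(cor))
        idx = rep.betas.index(rep.selected_beta)
        assert rep.r_squared[idx] >= 0.5

    def test_selects_smallest_qualifying_beta(self, default_sim):
        cor = sn.correlation_matrix(sn.ExpressionMatrix(default_sim.expr_b))
        rep = sn.pick_soft_threshold(sn.signed_similarity(cor))
        assert rep.target_reached
        for beta, r2 in zip(rep.betas, rep.r_squared):
            if beta < rep.selected_beta:
                assert r2 < 0.5

    def test_default_grid_includes_22(self):
        assert 22 in sn.wgcna_core.DEFAULT_BETA_GRID


class TestSignedTom:
    def test_complete_unit_graph(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = sn.signed_tom(AdjacencyMatrix(list("abc"), a, 1))
        off = tom.values[np.triu_indices(3, k=1)]
        np.testing.assert_allclose(off, 1.0)

    def test_isolated_pair_zero(self):
        a = np.zeros((4, 4))
        a[2, 3] = a[3, 2] = 0.8  # unrelated edge elsewhere
        tom = sn.signed_tom(AdjacencyMatrix(list("abcd"), a, 1))
        assert tom.values[0, 1] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        a = random_adjacency(rng, n)
        tom = sn.signed_tom(AdjacencyMatrix([f"g{i}" for i in range(n)], a, 1))
        np.testing.assert_allclose(tom.values, tom_oracle(a), atol=1e-12)

    def test_bounds_and_symmetry(self, rng):
        for _ in range(10):
            a = random_adjacency(rng, 8)
            t = sn.signed_tom(AdjacencyMatrix([f"g{i}" for i in range(8)], a, 1)).values
            assert ((t >= 0) & (t <= 1)).all()
            np.testing.assert_array_equal(t, t.T)


class TestExportEdges:
    def _small(self, rng, n=6):
        genes = [f"g{i}" for i in range(n)]
        a = random_adjacency(rng, n)
        tom = sn.signed_tom(AdjacencyMatrix(genes, a, 1))
        r = rng.uniform(-1, 1, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        cor = sn.CorrelationMatrix(genes, r, 10)
        return tom, cor

    def test_zero_cutoff_complete_graph(self, rng):
        tom, cor = self._small(rng)
        net = sn.export_edges(tom, cor, cutoff=0.0)
        assert net.number_of_edges() == 6 * 5 // 2

    def test_cutoff_above_one_empty(self, rng):
        tom, cor = self._small(rng)
        net = sn.export_edges(tom, cor, cutoff=1.01)
        assert net.number_of_edges() == 0 and net.number_of_nodes() == 0

    def test_edge_count_matches_counting_oracle(self, rng):
        tom, cor = self._small(rng, n=8)
        cutoff = float(np.quantile(tom.values[np.triu_indices(8, k=1)], 0.6))
        expected = int((tom.values[np.triu_indices(8, k=1)] >= cutoff).sum())
        net = sn.export_edges(tom, cor, cutoff=cutoff)
        assert net.number_of_edges() == expected
        weights = [d["weight"] for _, _, d in net.edges(data=True)]
        assert min(weights) >= cutoff

    def test_edge_signs_follow_correlation(self, rng):
        tom, cor = self._small(rng)
        net = sn.export_edges(tom, cor, cutoff=0.0)
        for u, v, d in net.edges(data=True):
            i, j = tom.gene_ids.index(u), tom.gene_ids.index(v)
            assert d["sign"] == ("+" if cor.values[i, j] >= 0 else "-")

    def test_isolated_genes_excluded(self, default_sim):
        net, report, cor = sn.build_network(
            sn.ExpressionMatrix(default_sim.expr_a), beta=22
        )
        assert net.number_of_nodes() < len(cor.gene_ids)
        assert all(deg >= 1 for _, deg in net.degree())


class TestPipelineChain:
    def test_end_to_end_bounds(self, default_sim):
        # every intermediate stays within its documented element bounds
        cor = sn.correlation_matrix(sn.ExpressionMatrix(default_sim.expr_a))
        s = sn.signed_similarity(cor)
        assert ((s.values >= 0) & (s.values <= 1)).all()
        a = sn.soft_adjacency(s, 6)
        assert ((a.values >= 0) & (a.values <= 1)).all()
        t = sn.signed_tom(a)
        assert ((t.values >= 0) & (t.values <= 1)).all()
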