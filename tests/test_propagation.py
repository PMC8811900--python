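"""Seed selection, random walk with restart, and TRS normalization."""
import numpy as np
import pytest
import scipy.sparse as sp

import traitprop as tp
from conftest import random_embedding


def _scores(z):
    z = np.asarray(z, dtype=float)
    return tp.TraitScores(deviation=np.zeros_like(z), zscore=z, trait="t",
                          n_background=50, rng_seed=0)


def _graph_from_adjacency(adj):
    return tp.CellGraph(adjacency=sp.csr_matrix(np.asarray(adj)), k=0)


def _path_graph(n):
    adj = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return _graph_from_adjacency(adj)


class TestSelectSeeds:
    def test_one_tailed_normal_threshold(self):
        """Z=2 (P~0.0228) is a seed; Z=1 (P~0.159) is not."""
        seeds = tp.select_seeds(_scores([2.0, 1.0] + [-1.0] * 38))
        assert seeds.indices.tolist() == [0]

    def test_five_percent_cap_keeps_highest_z(self):
        rng = np.random.default_rng(0)
        z = np.full(1000, -2.0)
        passing = rng.choice(1000, 100, replace=False)
        z[passing] = rng.uniform(2.0, 6.0, 100)  # 100 cells pass P<0.05
        seeds = tp.select_seeds(_scores(z))
        assert len(seeds) == 50  # ceil(0.05 * 1000)
        expected = set(np.argsort(-z)[:50].tolist())
        assert set(seeds.indices.tolist()) == expected

    def test_empty_fallback_takes_top_cells(self):
        z = np.linspace(-3.0, -1.0, 200)  # nothing passes P<0.05
        seeds = tp.select_seeds(_scores(z))
        assert seeds.fallback_used
        assert len(seeds) == 10  # max(10, ceil(0.01*200)) = 10
        assert seeds.indices.tolist() == list(range(190, 200))

    def test_empty_can_hard_error(self):
        with pytest.raises(ValueError, match="passes"):
            tp.select_seeds(_scores([-1.0] * 20), on_empty="error")

    def test_nan_scores_never_selected(self):
        z = np.array([np.nan, 3.0, np.nan, 2.5])
        seeds = tp.select_seeds(_scores(z))
        assert set(seeds.indices.tolist()) <= {1, 3}


class TestRandomWalk:
    def test_two_node_closed_form(self):
        """v = (1/(2-gamma), (1-gamma)/(2-gamma)) for a single edge, one seed."""
        g = _graph_from_adjacency([[0, 1], [1, 0]])
        seeds = tp.SeedSet(indices=np.array([0]), zscores=np.array([3.0]))
        res = tp.random_walk(g, seeds, gamma=0.05, alpha=1e-12)
        np.testing.assert_allclose(res.np_score, [1 / 1.95, 0.95 / 1.95], atol=1e-6)
        np.testing.assert_allclose(res.np_score, [0.512821, 0.487179], atol=1e-6)

    def test_gamma_one_returns_restart_state(self):
        g = _path_graph(5)
        seeds = tp.SeedSet(indices=np.array([1, 3]), zscores=np.zeros(2))
        res = tp.random_walk(g, seeds, gamma=1.0)
        np.testing.assert_allclose(res.np_score, [0, 0.5, 0, 0.5, 0])
        assert res.iterations == 1

    def test_complete_graph_all_seeded_is_uniform(self):
        n = 6
        g = _graph_from_adjacency(np.ones((n, n), dtype=int) - np.eye(n, dtype=int))
        seeds = tp.SeedSet(indices=np.arange(n), zscores=np.zeros(n))
        res = tp.random_walk(g, seeds)
        np.testing.assert_allclose(res.np_score, 1.0 / n, atol=1e-12)

    def test_mass_conserved_and_nonnegative(self):
        emb = random_embedding(100, 5, seed=3)
        g = tp.build_mknn_graph(emb, k=8)
        seeds = tp.SeedSet(indices=np.arange(5), zscores=np.zeros(5))
        res = tp.random_walk(g, seeds)
        assert res.np_score.sum() == pytest.approx(1.0, abs=1e-8)
        assert (res.np_score >= 0).all()
        assert res.converged

    @pytest.mark.parametrize("seed", range(5))
    def test_iteration_matches_direct_linear_solve(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        emb = random_embedding(n, 4, seed=seed + 100)
        g = tp.build_mknn_graph(emb, k=int(rng.integers(3, 10)))
        idx = np.sort(rng.choice(n, size=max(1, n // 20), replace=False))
        seeds = tp.SeedSet(indices=idx, zscores=np.zeros(idx.size))
        res = tp.random_walk(g, seeds, alpha=1e-10)
        exact = tp.solve_stationary(g, seeds, gamma=0.05)
        assert np.abs(res.np_score - exact).max() < 1e-6

    def test_component_without_seed_scores_exactly_zero(self):
        adj = np.zeros((5, 5), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        adj[2, 3] = adj[3, 2] = adj[3, 4] = adj[4, 3] = 1
        g = _graph_from_adjacency(adj)
        seeds = tp.SeedSet(indices=np.array([0]), zscores=np.array([1.0]))
        res = tp.random_walk(g, seeds)
        assert (res.np_score[2:] == 0.0).all()
        assert res.np_score[:2].sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [5, 10, 20])
    def test_path_graph_scores_decay_with_distance_from_seed(self, n):
        """Seeded at one end of a path, scores decay monotonically with distance
        beyond the seed's neighbor.  (The neighbor itself outranks the seed:
        under column normalization the degree-1 endpoint forwards its entire
        mass, so exact monotonicity starts one hop out.)"""
        g = _path_graph(n)
        seeds = tp.SeedSet(indices=np.array([0]), zscores=np.array([1.0]))
        res = tp.random_walk(g, seeds, alpha=1e-10)
        assert (np.diff(res.np_score[1:]) < 0).all()

    def test_gamma_zero_rejected(self):
        g = _path_graph(3)
        seeds = tp.SeedSet(indices=np.array([0]), zscores=np.array([1.0]))
        with pytest.raises(ValueError, match="gamma"):
            tp.random_walk(g, seeds, gamma=0.0)


class TestComputeTrs:
    def test_degenerate_equal_scores_give_zero(self):
        trs, factor = tp.compute_trs(np.full(50, 0.02), np.linspace(0, 5, 50))
        assert (trs == 0).all()

    def test_hand_evaluated_scaling(self):
        """N=200 linear NP ramp; top-2 Z = {4, 3} so factor 3.5 = max TRS."""
        np_scores = np.arange(1, 201, dtype=float)
        np_scores /= np_scores.sum()
        z = np.zeros(200)
        z[10], z[20] = 4.0, 3.0
        trs, factor = tp.compute_trs(np_scores, z)
        assert factor == pytest.approx(3.5)
        assert trs.max() == pytest.approx(3.5)
        assert trs.min() == pytest.approx(0.0)

    def test_ceiling_pools_top_cells_at_max(self):
        np_scores = np.concatenate([np.linspace(0.001, 0.01, 197), [0.2, 0.3, 0.4]])
        trs, _ = tp.compute_trs(np_scores, np.linspace(0, 2, 200))
        top = np.argsort(-np_scores)[:2]
        assert trs[top[0]] == pytest.approx(trs[top[1]])  # both above the ceiling

    def test_order_preserved_below_ceiling(self):
        rng = np.random.default_rng(1)
        np_scores = rng.dirichlet(np.ones(300))
        z = rng.standard_normal(300)
        trs, _ = tp.compute_trs(np_scores, z)
        ceiling = np.percentile(np_scores, 99)
        below = np_scores < ceiling
        order_np = np.argsort(np_scores[below])
        order_trs = np.argsort(trs[below], kind="stable")
        np.testing.assert_array_equal(order_np, order_trs)

    def test_mean_np_variant(self):
        np_scores = np.array([0.1, 0.2, 0.3, 0.4])
        z = np.array([0.0, 0.0, 0.0, 5.0])
        _, factor = tp.compute_trs(np_scores, z, scaling_mode="mean_np")
        assert factor == pytest.approx(0.4)  # NP of the single top-Z cell
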