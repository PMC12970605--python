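import itertools

import numpy as np
import pytest

from otalign._exceptions import ParameterError, ValidationError
from otalign.cocluster import (
    CoClustering,
    bipartite_modularity,
    cocluster,
    prune_small,
    select_k_elbow,
)
from otalign.metrics import clustering_scores


def block_plan(sizes_r, sizes_c, on=1.0, off=0.0, rng=None, noise=0.0):
    T = np.full((sum(sizes_r), sum(sizes_c)), off)
    r0 = 0
    c0 = 0
    for sr, sc in zip(sizes_r, sizes_c):
        T[r0 : r0 + sr, c0 : c0 + sc] = on
        r0 += sr
        c0 += sc
    if noise and rng is not None:
        T += noise * rng.random(T.shape)
    return T


def exhaustive_best_modularity(T, k):
    n_r, n_c = T.shape
    best = -np.inf
    for ra in itertools.product(range(k), repeat=n_r):
        for ca in itertools.product(range(k), repeat=n_c):
            best = max(best, bipartite_modularity(T, np.array(ra), np.array(ca)))
    return best


class TestModularity:
    def test_single_cluster_is_zero(self, rng):
        T = rng.random((5, 6))
        q = bipartite_modularity(T, np.zeros(5, int), np.zeros(6, int))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_blocks_closed_form(self):
        T = block_plan([3, 3], [3, 3])
        ra = np.array([0] * 3 + [1] * 3)
        ca = np.array([0] * 3 + [1] * 3)
        # Q = 1 - sum_b (mass_b / m)^2 = 1 - 2 * (1/2)^2 = 1/2
        assert bipartite_modularity(T, ra, ca) == pytest.approx(0.5)

    def test_random_assignment_below_exhaustive_optimum(self, rng):
        T = rng.random((4, 4))
        q_best = exhaustive_best_modularity(T, 2)
        for _ in range(5):
            ra = rng.integers(0, 2, 4)
            ca = rng.integers(0, 2, 4)
            assert bipartite_modularity(T, ra, ca) <= q_best + 1e-12

    def test_empty_plan_rejected(self):
        with pytest.raises(ValidationError):
            bipartite_modularity(np.zeros((3, 3)), np.zeros(3, int), np.zeros(3, int))


class TestCocluster:
    def test_recovers_two_blocks_exactly(self):
        T = block_plan([4, 5], [6, 3], on=1.0, off=0.01)
        cc = cocluster(T, 2, seed=0)
        truth_r = np.array([0] * 4 + [1] * 5)
        truth_c = np.array([0] * 6 + [1] * 3)
        assert clustering_scores(cc.row_assignments, truth_r)["ari"] == 1.0
        assert clustering_scores(cc.col_assignments, truth_c)["ari"] == 1.0

    def test_row_permutation_equivariance(self, rng):
        T = block_plan([4, 4], [4, 4], on=1.0, off=0.05, rng=rng, noise=0.02)
        cc = cocluster(T, 2, seed=1)
        perm = rng.permutation(8)
        cc_p = cocluster(T[perm], 2, seed=1)
        assert np.array_equal(cc_p.row_assignments, cc.row_assignments[perm])

    def test_noisy_three_blocks(self, rng):
        T = block_plan([10, 12, 8], [9, 11, 10], on=1.0, rng=rng, noise=0.05)
        cc = cocluster(T, 3, seed=0)
        truth = np.array([0] * 10 + [1] * 12 + [2] * 8)
        assert clustering_scores(cc.row_assignments, truth)["ari"] >= 0.9

    def test_sweeps_reach_near_exhaustive_optimum(self, rng):
        """Across 20 seeded restarts of random 4x4 plans, the converged
        modularity reaches >= 95% of the exhaustive-search optimum."""
        for seed in range(20):
            local = np.random.default_rng(seed)
            T = local.random((4, 4))
            q_best = exhaustive_best_modularity(T, 2)
            cc = cocluster(T, 2, seed=seed, n_restarts=20)
            if q_best > 0:
                assert cc.modularity >= 0.95 * q_best
            else:
                assert cc.modularity >= q_best - 1e-9

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ParameterError):
            cocluster(rng.random((3, 5)), 4)

    def test_modularity_nondecreasing_per_sweep(self, rng):
        """Each alternating sweep reassigns one side optimally given the
        other, so Q never decreases sweep over sweep."""
        from otalign.cocluster import _sweep

        T = rng.random((12, 14))
        ra = rng.integers(0, 3, 12)
        ca = rng.integers(0, 3, 14)
        prev_q = bipartite_modularity(T, ra, ca)
        for _ in range(8):
            ra, ca = _sweep(T, ra, ca, 3, max_sweeps=1)
            q = bipartite_modularity(T, ra, ca)
            assert q >= prev_q - 1e-12
            prev_q = q


class TestElbow:
    def test_exact_three_blocks_zero_error(self, rng):
        T = block_plan([6, 7, 5], [5, 6, 7], on=1.0, off=0.1)
        k_star, curve = select_k_elbow(T, range(2, 7), seed=0)
        assert curve[3] == pytest.approx(0.0, abs=1e-9)
        assert k_star == 3

    def test_curve_monotone_nonincreasing(self, rng):
        T = rng.random((20, 18))
        _, curve = select_k_elbow(T, range(2, 8), seed=0)
        errs = list(curve.values())
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_flat_curve_warns_and_returns_smallest(self):
        T = np.ones((8, 8))  # constant plan: every k reconstructs exactly
        with pytest.warns(UserWarning, match="elbow"):
            k_star, _ = select_k_elbow(T, range(2, 6), seed=0)
        assert k_star == 2

    def test_short_range_rejected(self, rng):
        with pytest.raises(ParameterError):
            select_k_elbow(rng.random((6, 6)), [2, 3])


class TestEndToEnd:
    def test_beats_or_matches_louvain_on_joint_embedding(self, counts_fit):
        """Transport-plan co-clustering scores at least as well as (or
        within 0.05 of) Louvain community detection on the concatenated
        embedding, per-modality, against the true cell types."""
        import igraph
        from sklearn.neighbors import kneighbors_graph
        from otalign.sinkhorn import extract_plan

        pair, x, y, model = counts_fit
        plan = extract_plan(model)
        cc = cocluster(plan, 3, seed=0)
        ours_rows = clustering_scores(cc.row_assignments, x.labels)

        joint = np.vstack([model.embedding_x, model.embedding_y])
        adj = kneighbors_graph(joint, 15, mode="connectivity")
        adj = adj.maximum(adj.T).tocoo()
        g = igraph.Graph(
            n=joint.shape[0], edges=list(zip(adj.row, adj.col)), directed=False
        )
        member = np.array(g.community_multilevel().membership)
        louvain_rows = clustering_scores(member[: len(x.labels)], x.labels)
        for key in ("ari", "nmi", "purity"):
            assert ours_rows[key] >= louvain_rows[key] - 0.05


class TestPrune:
    def _cc(self, ra, ca):
        return CoClustering(
            row_assignments=np.asarray(ra), col_assignments=np.asarray(ca),
            n_clusters=len(set(ra) | set(ca)), modularity=0.0,
        )

    def test_small_cluster_pruned_at_19(self):
        ra = [0] * 10 + [1] * 10
        ca = [0] * 9 + [1] * 10  # cluster 0 has 19 members total
        out = prune_small(self._cc(ra, ca), min_cells=20)
        assert 0 in out.pruned
        assert np.all(out.row_assignments[:10] == -1)

    def test_cluster_of_20_kept(self):
        ra = [0] * 10 + [1] * 10
        ca = [0] * 10 + [1] * 10
        out = prune_small(self._cc(ra, ca), min_cells=20)
        assert out.pruned == set()
        assert out.n_clusters == 2

    def test_identity_when_all_large(self):
        ra = [0] * 30 + [1] * 25
        ca = [0] * 20 + [1] * 30
        cc = self._cc(ra, ca)
        out = prune_small(cc, min_cells=20)
        assert np.array_equal(out.row_assignments, cc.row_assignments)
        assert np.array_equal(out.col_assignments, cc.col_assignments)

    def test_survivors_reindexed_densely(self):
        ra = [0] * 2 + [1] * 30 + [2] * 30
        ca = [1] * 30 + [2] * 30
        out = prune_small(self._cc(ra, ca), min_cells=20)
        assert set(np.unique(out.row_assignments)) == {-1, 0, 1}
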