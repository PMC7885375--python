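"""Edge statistics, cluster construction and the permutation test."""

import numpy as np
import pytest

from tactconn.cluster import (
    EdgeStatMap,
    build_edge_clusters,
    edge_stats,
    hl_degree,
    hl_degree_display,
    permutation_test,
    topography_summary,
)

from conftest import grid_montage


def fc_stack(rng, n_subjects, n_ch, planted=None, effect=0.0, sd=0.05):
    """Per-subject symmetric FC matrices with optional planted pairs."""
    mats = rng.normal(0.3, sd, size=(n_subjects, n_ch, n_ch))
    for k in range(n_subjects):
        mats[k] = (mats[k] + mats[k].T) / 2
        np.fill_diagonal(mats[k], 0)
    if planted:
        for (i, j) in planted:
            mats[:, i, j] += effect
            mats[:, j, i] += effect
    return mats


class TestEdgeStats:
    def test_identical_conditions_are_a_clean_null(self):
        rng = np.random.default_rng(0)
        a = fc_stack(rng, 4, 5)
        stats = edge_stats(a, a.copy())
        assert np.allclose(stats.t_values, 0.0)
        assert np.allclose(stats.p_values, 1.0)

    def test_consistent_positive_differences_give_large_t(self):
        rng = np.random.default_rng(1)
        a = fc_stack(rng, 6, 4)
        b = a - 0.1 + rng.normal(0, 1e-4, a.shape)
        stats = edge_stats(a, b)
        assert (stats.t_values > 10).all()

    def test_matches_textbook_paired_t(self):
        """Oracle: explicit mean/sd formula on hand-entered differences."""
        rng = np.random.default_rng(2)
        diffs = np.array([0.43, -0.12, 0.55, 0.98, 0.31, -0.40, 0.77, 0.05])
        b = fc_stack(rng, 8, 3)
        a = b.copy()
        a[:, 0, 1] += diffs
        a[:, 1, 0] += diffs
        stats = edge_stats(a, b)
        expected_t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(8))
        k = np.nonzero((stats.pairs[:, 0] == 0) & (stats.pairs[:, 1] == 1))[0][0]
        assert stats.t_values[k] == pytest.approx(expected_t, abs=1e-9)
        assert stats.df == 7

    def test_constant_nonzero_difference_rejected(self):
        rng = np.random.default_rng(3)
        b = fc_stack(rng, 4, 3)
        a = b + 0.5
        with pytest.raises(ValueError, match="zero variance"):
            edge_stats(a, b)

    def test_single_subject_rejected(self):
        rng = np.random.default_rng(4)
        a = fc_stack(rng, 1, 3)
        with pytest.raises(ValueError, match="2 subjects"):
            edge_stats(a, a)


class TestClusterConstruction:
    def _stat_map(self, montage, sig_pairs, t_value=5.0, t_signs=None):
        n = montage.n_channels
        iu = np.triu_indices(n, 1)
        pairs = np.column_stack(iu)
        t = np.zeros(len(pairs))
        p = np.ones(len(pairs))
        for k, (a, b) in enumerate(sig_pairs):
            i, j = sorted((montage.index(a), montage.index(b)))
            idx = np.nonzero((pairs[:, 0] == i) & (pairs[:, 1] == j))[0][0]
            sign = 1 if t_signs is None else t_signs[k]
            t[idx] = sign * t_value
            p[idx] = 1e-4
        return EdgeStatMap(t, p, 7, pairs, montage.channel_names)

    def test_shared_endpoint_edges_cluster(self, grid16):
        stats = self._stat_map(grid16, [("G00", "G01"), ("G01", "G02")])
        clusters = build_edge_clusters(stats, grid16)
        assert len(clusters) == 1
        assert len(clusters[0].edges) == 2
        assert clusters[0].cluster_stat == pytest.approx(10.0)

    def test_isolated_edges_discarded(self, grid16):
        stats = self._stat_map(grid16, [("G00", "G01"), ("G32", "G33")])
        assert build_edge_clusters(stats, grid16) == []

    def test_opposite_signs_never_merge(self, grid16):
        stats = self._stat_map(
            grid16, [("G00", "G01"), ("G01", "G02")], t_signs=[1, -1]
        )
        assert build_edge_clusters(stats, grid16) == []
        # each sign group needs its own adjacent companion
        stats = self._stat_map(
            grid16,
            [("G00", "G01"), ("G01", "G02"), ("G20", "G21"), ("G21", "G22")],
            t_signs=[1, 1, -1, -1],
        )
        clusters = build_edge_clusters(stats, grid16)
        assert len(clusters) == 2
        assert {np.sign(c.cluster_stat) for c in clusters} == {1.0, -1.0}

    def test_neighbor_rule_joins_nearby_edges(self, small_montage):
        stats = self._stat_map(small_montage, [("L1", "L2"), ("Z1", "Z2")])
        assert build_edge_clusters(stats, small_montage, adjacency_rule="shared") == []
        clusters = build_edge_clusters(
            stats, small_montage, adjacency_rule="neighbors"
        )
        assert len(clusters) == 1  # L1 and Z1 are montage neighbours


class TestPermutationTest:
    def test_pure_noise_yields_no_clusters(self, grid16):
        rng = np.random.default_rng(5)
        a = fc_stack(rng, 8, 16)
        b = fc_stack(rng, 8, 16)
        res = permutation_test(a, b, grid16, n_perm=200, seed=0)
        assert res.clusters == []
        assert res.node_sum.sum() == 0

    def test_planted_block_detected(self, grid16):
        """Power check: a coherent planted edge cluster survives."""
        rng = np.random.default_rng(6)
        planted = [(0, 1), (1, 2), (2, 3)]
        a = fc_stack(rng, 8, 16, planted=planted, effect=0.3)
        b = fc_stack(rng, 8, 16)
        res = permutation_test(a, b, grid16, n_perm=200, seed=0)
        assert len(res.clusters) >= 1
        retained_pairs = {tuple(res.stats.pairs[e]) for e in res.retained_edges}
        assert set(planted) <= retained_pairs
        assert all(c.perm_p < 0.05 for c in res.clusters)

    def test_deterministic_given_seed(self, grid16):
        rng = np.random.default_rng(7)
        a = fc_stack(rng, 8, 16, planted=[(0, 1), (1, 2)], effect=0.25)
        b = fc_stack(rng, 8, 16)
        r1 = permutation_test(a, b, grid16, n_perm=150, seed=3)
        r2 = permutation_test(a, b, grid16, n_perm=150, seed=3)
        assert [c.perm_p for c in r1.clusters] == [c.perm_p for c in r2.clusters]
        assert np.array_equal(r1.node_sum, r2.node_sum)

    def test_exhaustive_enumeration_small_n(self, grid16, caplog):
        rng = np.random.default_rng(8)
        a = fc_stack(rng, 5, 16, planted=[(0, 1), (1, 2)], effect=0.4)
        b = fc_stack(rng, 5, 16)
        import logging

        with caplog.at_level(logging.INFO, logger="tactconn.cluster"):
            res = permutation_test(a, b, grid16, n_perm=100, seed=0)
        assert res.exhaustive
        assert res.n_permutations == 2**4  # mirror classes of 5 subjects
        assert "exhaustive" in caplog.text

    def test_normalized_t_and_node_sums(self, grid16):
        rng = np.random.default_rng(9)
        a = fc_stack(rng, 8, 16, planted=[(0, 1), (1, 2)], effect=0.35)
        b = fc_stack(rng, 8, 16)
        res = permutation_test(a, b, grid16, n_perm=200, seed=1)
        assert res.clusters
        norm = np.array(list(res.normalized_t.values()))
        assert np.abs(norm).max() == pytest.approx(1.0)
        # node sums recompute from the retained edges
        expected = np.zeros(16)
        for e, nt in res.normalized_t.items():
            i, j = res.stats.pairs[e]
            expected[i] += nt
            expected[j] += nt
        assert np.allclose(res.node_sum, expected)

    def test_retained_set_invariant_to_channel_order(self):
        m = grid_montage(4)
        rng = np.random.default_rng(10)
        a = fc_stack(rng, 8, 16, planted=[(0, 1), (1, 2)], effect=0.35)
        b = fc_stack(rng, 8, 16)
        res = permutation_test(a, b, m, n_perm=120, seed=2)
        perm = np.random.default_rng(0).permutation(16)
        import numpy as _np
        from tactconn.montage import Montage

        m2 = Montage(
            name="perm",
            channel_names=tuple(m.channel_names[i] for i in perm),
            positions=m.positions[perm],
            hemisphere=tuple(m.hemisphere[i] for i in perm),
            flip_map=m.flip_map,
        )
        a2 = a[:, perm][:, :, perm]
        b2 = b[:, perm][:, :, perm]
        res2 = permutation_test(a2, b2, m2, n_perm=120, seed=2)
        named = lambda r, mm: {
            frozenset((mm.channel_names[i], mm.channel_names[j]))
            for i, j in (r.stats.pairs[e] for e in r.retained_edges)
        }
        assert named(res, m) == named(res2, m2)


class TestTopography:
    def test_hl_degree_worked_examples(self):
        assert hl_degree_display(hl_degree(9, 13)) == 69
        assert hl_degree_display(hl_degree(4, 28)) == 14
        assert hl_degree(13, 13) == 100.0

    def test_empty_topography_rejected(self):
        with pytest.raises(ValueError):
            hl_degree(0, 0)

    def test_summary_counts_and_intensities(self, grid16):
        rng = np.random.default_rng(11)
        # plant a right-hemisphere cluster (columns 2-3 are "right")
        right = [(2, 3), (3, 7)]  # G02-G03, G03-G13: all right channels
        a = fc_stack(rng, 8, 16, planted=right, effect=0.4)
        b = fc_stack(rng, 8, 16)
        res = permutation_test(a, b, grid16, n_perm=200, seed=4)
        assert res.clusters
        summ = topography_summary(res, grid16, stimulated_side="left")
        assert summ["n_total"] >= 3
        assert summ["hl_degree"] == pytest.approx(
            100 * summ["n_contra"] / summ["n_total"]
        )
        assert summ["mean_intensity_contra"] > 0

    def test_all_contralateral_is_100(self, grid16):
        rng = np.random.default_rng(12)
        a = fc_stack(rng, 8, 16, planted=[(2, 3), (3, 7), (7, 11)], effect=0.5)
        b = fc_stack(rng, 8, 16)
        res = permutation_test(a, b, grid16, n_perm=200, seed=5)
        summ = topography_summary(res, grid16, stimulated_side="left")
        if summ["n_contra"] == summ["n_total"]:
            assert summ["hl_degree"] == 100.0
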