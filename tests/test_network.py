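"""Graph indices against brute-force and networkx oracles."""

import numpy as np
import networkx as nx
import pytest

from tactconn.montage import Montage
from tactconn.network import (
    BinaryNetwork,
    binarize_subject_network,
    compute_indices,
    global_efficiency,
    inter_intra_degree,
    inter_intra_density,
    local_efficiency,
    smallworldness,
)

from conftest import grid_montage


# -- independent brute-force oracle -------------------------------------

def brute_distances(adj):
    """Shortest paths by explicit adjacency-power enumeration."""
    n = len(adj)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    reach = np.eye(n, dtype=bool)
    power = np.eye(n, dtype=int)
    for length in range(1, n):
        power = power @ adj
        newly = (power > 0) & ~reach
        d[newly] = length
        reach |= newly
    return d


def brute_global_efficiency(adj):
    n = len(adj)
    if n < 2:
        return 0.0
    d = brute_distances(np.asarray(adj))
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_local_efficiency(adj):
    adj = np.asarray(adj)
    n = len(adj)
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += brute_global_efficiency(sub)
    return total / n


def adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


def random_adj(rng, n, p=0.4):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T


class TestEfficiencyFixtures:
    def test_complete_graph_is_fully_efficient(self):
        a = 1 - np.eye(5, dtype=int)
        assert global_efficiency(a) == pytest.approx(1.0)
        assert local_efficiency(a) == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        a = np.zeros((4, 4), dtype=int)
        assert global_efficiency(a) == 0.0
        assert local_efficiency(a) == 0.0

    def test_path_graph_global_efficiency(self):
        # distances (1,2,3,1,2,1) -> E_glo = 13/18
        a = adj_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert global_efficiency(a) == pytest.approx(13 / 18)
        assert global_efficiency(a) == pytest.approx(
            brute_global_efficiency(a)
        )

    def test_star_graph_local_efficiency_is_zero(self):
        a = adj_from_edges(5, [(0, k) for k in range(1, 5)])
        assert local_efficiency(a) == 0.0

    def test_triangle_with_pendant_local_efficiency(self):
        # per-node neighbour subgraph efficiencies: 1/3, 1, 1, 0
        a = adj_from_edges(4, [(0, 1), (1, 2), (0, 2), (0, 3)])
        assert local_efficiency(a) == pytest.approx(7 / 12)
        assert local_efficiency(a) == pytest.approx(brute_local_efficiency(a))

    def test_disconnected_pairs_contribute_zero(self):
        a = adj_from_edges(4, [(0, 1), (2, 3)])
        # within components distance 1; across, nothing
        assert global_efficiency(a) == pytest.approx(4 / 12)


class TestOracleEquivalence:
    def test_efficiencies_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            a = random_adj(rng, n, p=float(rng.uniform(0.1, 0.9)))
            assert global_efficiency(a) == pytest.approx(
                brute_global_efficiency(a), abs=1e-12
            )
            assert local_efficiency(a) == pytest.approx(
                brute_local_efficiency(a), abs=1e-12
            )

    def test_efficiencies_match_networkx(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(3, 12))
            a = random_adj(rng, n, p=0.35)
            g = nx.from_numpy_array(a)
            assert global_efficiency(a) == pytest.approx(
                nx.global_efficiency(g), abs=1e-12
            )
            assert local_efficiency(a) == pytest.approx(
                nx.local_efficiency(g), abs=1e-12
            )


def toy_net(adj):
    """Binary network on a 6-channel montage: 2 left, 2 right, 2 midline."""
    return BinaryNetwork(
        adjacency=adj,
        channels=("L1", "L2", "R1", "R2", "Z1", "Z2"),
        hemisphere=("left", "left", "right", "right", "midline", "midline"),
    )


class TestDensities:
    def test_complete_bipartite_across_hemispheres(self):
        a = np.zeros((6, 6), dtype=int)
        for i in (0, 1):
            for j in (2, 3):
                a[i, j] = a[j, i] = 1
        d = inter_intra_density(toy_net(a))
        assert d["k_inter"] == 1.0
        assert d["k_intra_left"] == 0.0 and d["k_intra_right"] == 0.0

    def test_two_inter_links_among_three_per_side(self):
        m = Montage(
            name="h3",
            channel_names=("L1", "L2", "L3", "R1", "R2", "R3"),
            positions=np.array([[-1, 0], [-1, 1], [-1, -1],
                                [1, 0], [1, 1], [1, -1]], dtype=float),
            hemisphere=("left",) * 3 + ("right",) * 3,
            flip_map={"L1": "R1", "R1": "L1", "L2": "R2", "R2": "L2",
                      "L3": "R3", "R3": "L3"},
        )
        a = np.zeros((6, 6), dtype=int)
        a[0, 3] = a[3, 0] = 1
        a[1, 4] = a[4, 1] = 1
        net = BinaryNetwork.from_montage(a, m)
        assert inter_intra_density(net)["k_inter"] == pytest.approx(2 / 9)

    def test_complete_left_hemisphere_only(self):
        a = np.zeros((6, 6), dtype=int)
        a[0, 1] = a[1, 0] = 1  # the only left-left pair
        d = inter_intra_density(toy_net(a))
        assert d["k_intra_left"] == 1.0
        assert d["k_intra_right"] == 0.0
        assert d["k_inter"] == 0.0

    def test_unequal_hemispheres_rejected(self):
        net = BinaryNetwork(
            adjacency=np.zeros((3, 3), dtype=int),
            channels=("L1", "L2", "R1"),
            hemisphere=("left", "left", "right"),
        )
        with pytest.raises(ValueError, match="equal-sized"):
            inter_intra_density(net)

    def test_midline_links_do_not_count(self):
        a = np.zeros((6, 6), dtype=int)
        a[4, 5] = a[5, 4] = 1  # midline-midline
        a[0, 4] = a[4, 0] = 1  # left-midline
        d = inter_intra_density(toy_net(a))
        assert d["k_inter"] == 0.0
        assert d["k_intra_left"] == 0.0


class TestDegrees:
    def test_single_inter_link(self):
        a = np.zeros((6, 6), dtype=int)
        a[0, 2] = a[2, 0] = 1  # L1 - R1
        deg = inter_intra_degree(toy_net(a))
        assert deg["d_inter"][0] == 1 and deg["d_inter"][2] == 1
        assert deg["d_intra"].sum() == 0

    def test_intra_triangle_degrees(self):
        m = Montage(
            name="h3",
            channel_names=("L1", "L2", "L3", "R1", "R2", "R3"),
            positions=np.array([[-1, 0], [-1, 1], [-1, -1],
                                [1, 0], [1, 1], [1, -1]], dtype=float),
            hemisphere=("left",) * 3 + ("right",) * 3,
            flip_map={"L1": "R1", "R1": "L1", "L2": "R2", "R2": "L2",
                      "L3": "R3", "R3": "L3"},
        )
        a = adj_from_edges(6, [(0, 1), (1, 2), (0, 2)])
        deg = inter_intra_degree(BinaryNetwork.from_montage(a, m))
        assert list(deg["d_intra"][:3]) == [2, 2, 2]
        assert deg["d_inter"].sum() == 0

    def test_midline_reports_zero_by_convention(self):
        a = np.zeros((6, 6), dtype=int)
        a[4, 0] = a[0, 4] = 1  # Z1 - L1
        deg = inter_intra_degree(toy_net(a))
        assert deg["d_inter"][4] == 0 and deg["d_intra"][4] == 0

    def test_degree_sums_match_link_counts_on_random_graphs(self, grid16):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = random_adj(rng, 16, p=0.3)
            net = BinaryNetwork.from_montage(a, grid16)
            deg = inter_intra_degree(net)
            dens = inter_intra_density(net)
            left = net.hemi_indices("left")
            right = net.hemi_indices("right")
            inter_links = a[np.ix_(left, right)].sum()
            assert deg["d_inter"].sum() == 2 * inter_links
            ns = len(left)
            # consistency identities between densities and degrees
            assert dens["k_inter"] == pytest.approx(
                deg["d_inter"].sum() / (2 * ns**2)
            )
            assert dens["k_intra_left"] == pytest.approx(
                deg["d_intra"][left].sum() / (ns * (ns - 1))
            )
            # brute per-node recount
            for i in left:
                assert deg["d_inter"][i] == a[i, right].sum()
                assert deg["d_intra"][i] == a[i, left].sum()


class TestMonotonicityAndRange:
    def test_adding_a_link_never_decreases_indices(self, grid16):
        rng = np.random.default_rng(3)
        a = random_adj(rng, 16, p=0.2)
        net = BinaryNetwork.from_montage(a, grid16)
        base_eg = global_efficiency(net)
        zeros = np.argwhere(np.triu(a == 0, 1))
        i, j = zeros[rng.integers(len(zeros))]
        a2 = a.copy()
        a2[i, j] = a2[j, i] = 1
        net2 = BinaryNetwork.from_montage(a2, grid16)
        assert global_efficiency(net2) >= base_eg
        deg, deg2 = inter_intra_degree(net), inter_intra_degree(net2)
        assert (deg2["d_inter"] >= deg["d_inter"]).all()
        assert (deg2["d_intra"] >= deg["d_intra"]).all()

    def test_indices_within_declared_bounds(self, grid16):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a = random_adj(rng, 16, p=float(rng.uniform(0.05, 0.9)))
            net = BinaryNetwork.from_montage(a, grid16)
            dens = inter_intra_density(net)
            deg = inter_intra_degree(net)
            assert 0 <= global_efficiency(net) <= 1
            assert 0 <= local_efficiency(net) <= 1
            assert all(0 <= v <= 1 for v in dens.values())
            assert (deg["d_inter"] <= 16).all()
            assert (deg["d_intra"] <= 15).all()


class TestSmallworldness:
    def test_er_like_network_brackets_unity(self, grid16):
        rng = np.random.default_rng(5)
        sws = []
        for k in range(12):
            a = random_adj(np.random.default_rng(100 + k), 16, p=0.35)
            net = BinaryNetwork.from_montage(a, grid16)
            sws.append(smallworldness(net, n_refs=40, seed=k)["sw"])
        assert min(sws) < 1 < max(sws) or abs(np.mean(sws) - 1) < 0.15

    def test_rewired_ring_lattice_is_small_world(self, montage):
        g = nx.connected_watts_strogatz_graph(62, 6, 0.1, seed=1)
        a = nx.to_numpy_array(g, dtype=int)
        net = BinaryNetwork.from_montage(a, montage)
        out = smallworldness(net, n_refs=50, seed=0)
        assert out["sw"] > 1.0

    def test_deterministic_given_seed(self, grid16):
        a = random_adj(np.random.default_rng(6), 16, p=0.3)
        net = BinaryNetwork.from_montage(a, grid16)
        r1 = smallworldness(net, n_refs=30, seed=9)
        r2 = smallworldness(net, n_refs=30, seed=9)
        assert r1 == r2

    def test_sparse_reference_flags_nan(self, grid16):
        a = np.zeros((16, 16), dtype=int)
        a[0, 1] = a[1, 0] = 1
        net = BinaryNetwork.from_montage(a, grid16)
        with pytest.warns(RuntimeWarning, match="undefined"):
            out = smallworldness(net, n_refs=10, seed=0)
        assert np.isnan(out["sw"])


class TestBinarize:
    def _trial_stacks(self, rng, n_trials=9, n_ch=8, planted=None, effect=0.3):
        base = rng.normal(0.3, 0.05, (n_trials, n_ch, n_ch))
        stim = rng.normal(0.3, 0.05, (n_trials, n_ch, n_ch))
        for m in (base, stim):
            for k in range(n_trials):
                m[k] = (m[k] + m[k].T) / 2
                np.fill_diagonal(m[k], 0)
        if planted:
            for i, j in planted:
                stim[:, i, j] += effect
                stim[:, j, i] += effect
        return stim, base

    @pytest.fixture()
    def montage8(self):
        return grid_montage(4)

    def test_identical_conditions_give_empty_network(self, grid16):
        rng = np.random.default_rng(7)
        stim, _ = self._trial_stacks(rng, n_ch=16)
        net = binarize_subject_network(stim, stim.copy(), grid16)
        assert net.n_links == 0

    def test_planted_edge_survives_fdr(self, grid16):
        rng = np.random.default_rng(8)
        stim, base = self._trial_stacks(rng, n_ch=16, planted=[(0, 1)], effect=0.4)
        net = binarize_subject_network(stim, base, grid16)
        assert net.adjacency[0, 1] == 1
        assert net.n_links <= 3  # essentially only the planted pair

    def test_bh_step_up_rule_by_hand(self):
        """Sorted p {0.01, 0.02, 0.03, 0.04, 0.2}, q = 0.05: the step-up
        rule accepts i <= 4 since p_(4) = 0.04 <= (4/5) 0.05."""
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.04, 0.2])
        reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert reject.sum() == 4
        assert not reject[-1]

    def test_unequal_trial_counts_rejected(self, grid16):
        rng = np.random.default_rng(9)
        stim, base = self._trial_stacks(rng, n_ch=16)
        with pytest.raises(ValueError, match="equal trial counts"):
            binarize_subject_network(stim[:5], base, grid16)


class TestComputeIndices:
    def test_all_fields_populated(self, grid16):
        a = random_adj(np.random.default_rng(10), 16, p=0.4)
        net = BinaryNetwork.from_montage(a, grid16)
        idx = compute_indices(net, n_random_refs=20, seed=0)
        assert 0 < idx.e_glo <= 1
        assert 0 <= idx.e_loc <= 1
        assert np.isfinite(idx.sw)
        assert idx.d_inter.shape == (16,)
        assert idx.n_random_refs == 20


class TestAdjacencyIO:
    def test_round_trip(self, grid16, tmp_path):
        from tactconn.network import read_adjacency, write_adjacency

        a = random_adj(np.random.default_rng(11), 16, p=0.3)
        net = BinaryNetwork.from_montage(a, grid16)
        path = tmp_path / "adj.tsv"
        write_adjacency(net, path)
        back = read_adjacency(path, grid16)
        assert np.array_equal(back.adjacency, net.adjacency)
        assert back.channels == net.channels
        assert back.hemisphere == net.hemisphere
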